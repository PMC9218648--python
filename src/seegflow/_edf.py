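"""Minimal EDF (European Data Format) writer.

Writes plain 16-bit EDF with one-second data records, which is sufficient
for the synthetic cohorts produced by :mod:`seegflow.synthetic` and is read
back through MNE's native EDF reader (:func:`mne.io.read_raw_edf`).
Physical units are microvolts.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_edf"]

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _phys_bound(v: float) -> str:
    """Format a physical min/max so it survives an 8-char ASCII round trip."""
    s = f"{v:.8g}"
    if len(s) > 8:
        s = f"{v:.3g}"
    if len(s) > 8:
        raise ValueError(f"physical bound {v} does not fit EDF field")
    return s


def write_edf(
    path,
    signal: np.ndarray,
    labels: list[str],
    fs: float,
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write ``signal`` (channels x samples, microvolts) to ``path``.

    ``fs`` must be a positive integer (one data record per second).
    Trailing samples beyond the last whole second are dropped.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError("signal must be channels x samples")
    n_ch, n_samp = signal.shape
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("fs must be a positive integer for EDF records of 1 s")
    fs_i = int(round(fs))
    n_rec = n_samp // fs_i
    if n_rec < 1:
        raise ValueError("signal shorter than one data record")

    # Physical bounds: pad so max/min are representable after truncation.
    pmins, pmaxs, gains = [], [], []
    for c in range(n_ch):
        lo = float(np.min(signal[c, : n_rec * fs_i]))
        hi = float(np.max(signal[c, : n_rec * fs_i]))
        span = max(hi - lo, 1e-6)
        lo -= 0.01 * span
        hi += 0.01 * span
        # parse back the written strings so scaling matches the header exactly
        lo_s, hi_s = _phys_bound(lo), _phys_bound(hi)
        lo_p, hi_p = float(lo_s), float(hi_s)
        if hi_p <= lo_p:
            hi_p = lo_p + 1.0
            hi_s = _phys_bound(hi_p)
        pmins.append(lo_s)
        pmaxs.append(hi_s)
        gains.append((hi_p - lo_p) / (_DIG_MAX - _DIG_MIN))

    header = bytearray()
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field(recording_id, 80)
    header += _field("01.01.01", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)
    header += _field(str(n_ch), 4)
    for lab in labels:
        header += _field(lab, 16)
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(s, 8) for s in pmins)
    header += b"".join(_field(s, 8) for s in pmaxs)
    header += b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field(str(fs_i), 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    # digital conversion per channel
    dig = np.empty((n_ch, n_rec * fs_i), dtype="<i2")
    for c in range(n_ch):
        lo = float(pmins[c])
        d = np.round((signal[c, : n_rec * fs_i] - lo) / gains[c]) + _DIG_MIN
        dig[c] = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            sl = slice(r * fs_i, (r + 1) * fs_i)
            for c in range(n_ch):
                fh.write(dig[c, sl].tobytes())
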