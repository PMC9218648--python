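"""Recordings, channel metadata and the preprocessing chain.

SEEG analyses here operate on a :class:`Recording` (channels x samples in
microvolts) carrying per-channel metadata (:class:`ChannelInfo`), and on
non-overlapping fixed-length epochs (:class:`EpochedData`).  Preprocessing
follows the conventional interictal resting-state recipe: bipolar
re-referencing along electrode shafts, 60 Hz notch filtering, exclusion of
white-matter contacts, automated artifact-free segment selection and 1 s
epoching.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelInfo",
    "Recording",
    "EpochedData",
    "PatientEntry",
    "CohortManifest",
    "read_channel_table",
    "read_recording",
    "apply_bipolar_montage",
    "notch_filter",
    "resample_recording",
    "select_interictal_segments",
    "epoch",
    "exclude_white_matter",
]


@dataclass(frozen=True)
class ChannelInfo:
    """One (possibly bipolar) SEEG channel.

    position is in scanner RAS millimetres; ``soz`` marks clinically
    annotated seizure-onset-zone contacts; ``white_matter`` contacts are
    excluded from analysis.
    """

    label: str
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    white_matter: bool = False
    soz: bool = False
    region: str | None = None


@dataclass
class Recording:
    """Multichannel signal in microvolts with channel metadata."""

    channels: list[ChannelInfo]
    signal: np.ndarray  # channels x samples, float64
    fs: float
    montage: str = "referential"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError("signal must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    @property
    def soz_mask(self) -> np.ndarray:
        return np.array([c.soz for c in self.channels], dtype=bool)


@dataclass
class EpochedData:
    """Non-overlapping fixed-length epochs: (n_epochs, n_channels, n_samples)."""

    data: np.ndarray
    fs: float
    epoch_length: float
    channels: list[ChannelInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        want = int(round(self.fs * self.epoch_length))
        if self.data.shape[2] != want:
            raise ValueError("samples per epoch must equal round(fs*epoch_length)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class PatientEntry:
    id: str
    recording_paths: list[str]
    channel_table: str
    engel: str  # I, II, III, IV
    fs: float
    lesional: str = "none"  # none | focal | diffuse

    @property
    def seizure_free(self) -> bool:
        return self.engel == "I"


@dataclass
class CohortManifest:
    patients: list[PatientEntry]

    def __post_init__(self) -> None:
        for p in self.patients:
            if p.engel not in ("I", "II", "III", "IV"):
                raise ValueError(f"invalid Engel class {p.engel!r} for {p.id}")

    def save(self, path) -> None:
        payload = [
            {
                "id": p.id,
                "recording_paths": p.recording_paths,
                "channel_table": p.channel_table,
                "engel": p.engel,
                "seizure_free": p.seizure_free,
                "lesional": p.lesional,
                "fs": p.fs,
            }
            for p in self.patients
        ]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "CohortManifest":
        payload = json.loads(Path(path).read_text())
        patients = []
        for row in payload:
            entry = PatientEntry(
                id=row["id"],
                recording_paths=list(row["recording_paths"]),
                channel_table=row["channel_table"],
                engel=row["engel"],
                fs=float(row["fs"]),
                lesional=row.get("lesional", "none"),
            )
            if bool(row.get("seizure_free", entry.seizure_free)) != entry.seizure_free:
                raise ValueError(
                    f"manifest inconsistency for {entry.id}: seizure_free must equal (engel == I)"
                )
            patients.append(entry)
        return cls(patients)


def read_channel_table(path) -> pd.DataFrame:
    """Read the tab-separated channel table (label, x, y, z, white_matter, soz, region)."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    required = {"label", "x", "y", "z", "white_matter", "soz", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"channel table {path} missing columns: {sorted(missing)}")
    return df


def _channels_from_table(df: pd.DataFrame) -> dict[str, ChannelInfo]:
    out = {}
    for row in df.itertuples(index=False):
        region = None if pd.isna(row.region) else str(row.region)
        out[str(row.label)] = ChannelInfo(
            label=str(row.label),
            position=(float(row.x), float(row.y), float(row.z)),
            white_matter=bool(int(row.white_matter)),
            soz=bool(int(row.soz)),
            region=region,
        )
    return out


def read_recording(path, channel_table, expected_fs: float | None = None) -> Recording:
    """Read an EDF recording plus its channel metadata table.

    Channels present in the EDF but absent from the table are dropped with a
    warning.  A sampling-rate mismatch against ``expected_fs`` (e.g. from a
    cohort manifest) is a validation error.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise ValueError(
            f"sampling rate mismatch for {path}: EDF has {fs} Hz, manifest says {expected_fs} Hz"
        )
    table = _channels_from_table(read_channel_table(channel_table))
    keep_idx, channels = [], []
    for i, lab in enumerate(raw.ch_names):
        if lab in table:
            keep_idx.append(i)
            channels.append(table[lab])
        else:
            logger.warning("channel %s absent from channel table; dropped", lab)
    if not keep_idx:
        raise ValueError(f"no EDF channel matched the channel table {channel_table}")
    data = raw.get_data(picks=keep_idx) * 1e6  # volts -> microvolts
    return Recording(channels=channels, signal=data, fs=fs, montage="referential")


def apply_bipolar_montage(rec: Recording, pairs: list[tuple[str, str]]) -> Recording:
    """Re-reference to a bipolar montage: each output channel = anode - cathode.

    The bipolar contact position is the midpoint of the two contacts; the
    channel counts as white matter only if both contacts are, and as SOZ if
    either contact is.
    """
    index = {c.label: i for i, c in enumerate(rec.channels)}
    sigs, chans = [], []
    for anode, cathode in pairs:
        if anode not in index or cathode not in index:
            raise KeyError(f"unknown channel in bipolar pair ({anode}, {cathode})")
        a, c = rec.channels[index[anode]], rec.channels[index[cathode]]
        sigs.append(rec.signal[index[anode]] - rec.signal[index[cathode]])
        pos = tuple((np.asarray(a.position) + np.asarray(c.position)) / 2.0)
        chans.append(
            ChannelInfo(
                label=f"{anode}-{cathode}",
                position=pos,
                white_matter=a.white_matter and c.white_matter,
                soz=a.soz or c.soz,
                region=a.region,
            )
        )
    return Recording(channels=chans, signal=np.array(sigs), fs=rec.fs, montage="bipolar")


def exclude_white_matter(rec: Recording) -> Recording:
    keep = [i for i, c in enumerate(rec.channels) if not c.white_matter]
    return replace(
        rec,
        channels=[rec.channels[i] for i in keep],
        signal=rec.signal[keep],
    )


def notch_filter(rec: Recording, line_freq: float = 60.0, harmonics: int = 1, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at the line frequency and requested harmonics.

    Each harmonic below Nyquist gets a second-order notch (quality factor
    ``q``) applied forward-backward, preserving phase relations needed by
    the directionality estimators.
    """
    nyq = rec.fs / 2.0
    if line_freq >= nyq:
        raise ValueError(f"line frequency {line_freq} Hz is at/above Nyquist {nyq} Hz")
    out = rec.signal.copy()
    for h in range(1, harmonics + 1):
        f0 = h * line_freq
        if f0 >= nyq:
            break
        b, a = sps.iirnotch(f0, q, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=-1)
    return replace(rec, signal=out)


def resample_recording(rec: Recording, target_fs: float = 500.0) -> Recording:
    """Polyphase zero-phase resampling to a common analysis rate."""
    if abs(rec.fs - target_fs) < 1e-9:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=-1)
    return replace(rec, signal=out, fs=target_fs)


def select_interictal_segments(
    rec: Recording,
    segment_length: float = 180.0,
    total_length: float = 600.0,
    artifact_z: float = 6.0,
) -> Recording:
    """Concatenate clean non-overlapping segments up to ``total_length`` seconds.

    A sample is artifactual when any channel's robust amplitude z-score
    (median/MAD scale) exceeds ``artifact_z`` — an automated stand-in for
    visual epileptiform screening.  Segments of ``segment_length`` seconds
    containing no artifactual sample are taken greedily (1 s scan step)
    until the requested total duration is reached.
    """
    if rec.duration < total_length:
        raise ValueError(
            f"recording of {rec.duration:.1f} s shorter than requested {total_length} s"
        )
    med = np.median(rec.signal, axis=1, keepdims=True)
    mad = np.median(np.abs(rec.signal - med), axis=1, keepdims=True)
    scale = np.maximum(1.4826 * mad, 1e-12)
    clean = np.all(np.abs(rec.signal - med) / scale <= artifact_z, axis=0)

    fs = rec.fs
    seg_n = int(round(segment_length * fs))
    step = max(int(round(fs)), 1)
    need = int(round(total_length * fs))
    pieces, got = [], 0
    t = 0
    while t + seg_n <= rec.n_samples and got < need:
        if clean[t : t + seg_n].all():
            pieces.append(rec.signal[:, t : t + seg_n])
            got += seg_n
            t += seg_n
        else:
            t += step
    if got < need:
        raise ValueError(
            f"insufficient clean data: found {got / fs:.1f} clean seconds, "
            f"requested {total_length} s"
        )
    out = np.concatenate(pieces, axis=1)[:, :need]
    return replace(rec, signal=out)


def epoch(rec: Recording, length: float = 1.0) -> EpochedData:
    """Cut into non-overlapping epochs of ``length`` seconds; the tail is discarded."""
    n = int(round(length * rec.fs))
    n_ep = rec.n_samples // n
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    data = rec.signal[:, : n_ep * n].reshape(rec.n_channels, n_ep, n).transpose(1, 0, 2)
    return EpochedData(data=data.copy(), fs=rec.fs, epoch_length=length, channels=list(rec.channels))
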