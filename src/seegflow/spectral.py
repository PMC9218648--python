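"""Power spectra and the aperiodic 1/f model.

Per-channel spectra are Hanning-tapered FFT periodograms of 1 s epochs,
averaged across epochs and sampled on the 1-250 Hz grid in 1 Hz steps.
The aperiodic model is fit in semilog-power space,

    log10 P(f) = b - chi * log10 f + sum_g h_g * exp(-(f - c_g)^2 / (2 w_g^2)),

iterating between a robust aperiodic (offset/exponent) fit and Gaussian
modelling of oscillatory peaks, in the spirit of spectral parameterization
("FOOOF-style") algorithms.  The reported power slope is -chi, used
downstream as a proxy for the excitation:inhibition ratio (more negative
slope, higher E:I imbalance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core_io import ChannelInfo, EpochedData

__all__ = [
    "PowerSpectrum",
    "AperiodicFit",
    "FitSettings",
    "compute_psd",
    "fit_aperiodic",
    "fit_aperiodic_spectrum",
    "slope_table",
]

DEFAULT_FREQS = np.arange(1.0, 251.0)
# line-noise notch regions excluded from the fit loss
DEFAULT_EXCLUDE = ((58.0, 62.0), (118.0, 122.0))


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs), uV^2/Hz
    n_epochs: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[1] != self.freqs.size:
            raise ValueError("power/freqs length mismatch")
        if np.any(self.power <= 0):
            raise ValueError("power must be strictly positive")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class FitSettings:
    mode: str = "fixed"  # "fixed" (no knee); knee mode is out of scope
    max_peaks: int = 6
    peak_threshold: float = 2.0  # in sd of the flattened residual
    min_peak_height: float = 0.05  # log10-power floor; guards noise-free spectra
    width_limits: tuple[float, float] = (1.0, 12.0)
    exclude_bands: tuple = DEFAULT_EXCLUDE
    n_outer: int = 3


@dataclass
class AperiodicFit:
    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]]  # (center Hz, height log10, width Hz)
    fit_error: float  # mean |residual| in log10-power
    r2: float
    error_history: list[float] = field(default_factory=list)

    @property
    def slope(self) -> float:
        return -self.exponent


def compute_psd(ep: EpochedData, freqs: np.ndarray | None = None) -> PowerSpectrum:
    """Hanning-tapered per-epoch FFT power, averaged over epochs.

    Requires fs >= 500 Hz so the 250 Hz bin exists below Nyquist.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    if ep.fs < 2 * freqs[-1]:
        raise ValueError(f"fs={ep.fs} Hz too low to reach {freqs[-1]:g} Hz")
    n = ep.data.shape[2]
    win = np.hanning(n)
    scale = 2.0 / (ep.fs * np.sum(win**2))
    spec = np.fft.rfft(ep.data * win[None, None, :], axis=2)
    psd = (np.abs(spec) ** 2) * scale
    psd = psd.mean(axis=0)  # (n_channels, n_rfft)
    fft_freqs = np.fft.rfftfreq(n, d=1.0 / ep.fs)
    idx = np.searchsorted(fft_freqs, freqs)
    idx = np.clip(idx, 0, fft_freqs.size - 1)
    # snap to nearest available bin (exact when fs * epoch_length is integer)
    for k, f in enumerate(freqs):
        if idx[k] > 0 and abs(fft_freqs[idx[k] - 1] - f) < abs(fft_freqs[idx[k]] - f):
            idx[k] -= 1
    return PowerSpectrum(freqs=np.asarray(freqs, float), power=psd[:, idx], n_epochs=ep.n_epochs)


def _gaussians(f: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f)
    for c, h, w in params.reshape(-1, 3):
        out += h * np.exp(-((f - c) ** 2) / (2 * w**2))
    return out


def _fit_line(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares b - chi*logf with chi clipped to >= 0."""
    A = np.vstack([np.ones_like(logf), -logf]).T
    (b, chi), *_ = np.linalg.lstsq(A, y, rcond=None)
    if chi < 0:
        return float(np.mean(y + 0 * logf)), 0.0
    return float(b), float(chi)


def _prune_peaks(params: np.ndarray, min_height: float) -> np.ndarray:
    """Drop sub-threshold peaks and weaker peaks overlapping a stronger one
    (center within 1.5 standard deviations of the stronger peak)."""
    peaks = [p for p in params.reshape(-1, 3) if p[1] >= min_height]
    peaks.sort(key=lambda p: -p[1])
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(abs(p[0] - q[0]) > 1.5 * q[2] for q in kept):
            kept.append(p)
    return np.concatenate(kept) if kept else np.empty(0)


def _robust_aperiodic(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Line fit that down-weights oscillatory peaks: refit on the points whose
    residual lies below its 60th percentile (peaks only push power up)."""
    b, chi = _fit_line(logf, y)
    resid = y - (b - chi * logf)
    keep = resid <= np.percentile(resid, 60.0)
    if keep.sum() >= 3:
        b, chi = _fit_line(logf[keep], y[keep])
    return b, chi


def fit_aperiodic_spectrum(
    freqs: np.ndarray, power: np.ndarray, settings: FitSettings | None = None
) -> AperiodicFit:
    """Fit one channel's spectrum; see module docstring for the model."""
    settings = settings or FitSettings()
    if settings.mode != "fixed":
        raise NotImplementedError("only the fixed (no-knee) aperiodic mode is supported")
    freqs = np.asarray(freqs, dtype=float)
    y_full = np.log10(np.asarray(power, dtype=float))
    include = np.ones(freqs.size, dtype=bool)
    for lo, hi in settings.exclude_bands:
        include &= ~((freqs >= lo) & (freqs <= hi))
    f, y = freqs[include], y_full[include]
    logf = np.log10(f)

    b, chi = _robust_aperiodic(logf, y)
    peak_params = np.empty(0)
    wlo, whi = settings.width_limits
    history: list[float] = []
    best: tuple[float, AperiodicFit | None] = (np.inf, None)

    for _ in range(settings.n_outer):
        flat = y - (b - chi * logf)
        # iterative peak detection, largest residual first
        guesses = [g for g in peak_params.reshape(-1, 3)]
        work = flat - _gaussians(f, peak_params) if peak_params.size else flat.copy()
        while len(guesses) < settings.max_peaks:
            i = int(np.argmax(work))
            height = work[i]
            if height < max(settings.peak_threshold * np.std(work), settings.min_peak_height):
                break
            # half-height width guess from the local residual shape
            half = height / 2
            li = i
            while li > 0 and work[li] > half:
                li -= 1
            ri = i
            while ri < work.size - 1 and work[ri] > half:
                ri += 1
            w_guess = np.clip((f[ri] - f[li]) / 2.355, wlo, whi)
            guesses.append(np.array([f[i], height, w_guess]))
            work = work - _gaussians(f, np.asarray(guesses[-1]))
        if guesses:
            p0 = np.concatenate(guesses)
            n_g = len(guesses)
            lb = np.tile([f[0], 0.0, wlo], n_g)
            ub = np.tile([f[-1], np.inf, whi], n_g)
            p0 = np.clip(p0, lb + 1e-9, ub - 1e-9 if np.all(np.isfinite(ub)) else p0)
            p0 = np.minimum(np.maximum(p0, lb), np.where(np.isfinite(ub), ub, p0))
            res = least_squares(
                lambda p: _gaussians(f, p) - flat, p0, bounds=(lb, ub), xtol=1e-8, ftol=1e-8
            )
            peak_params = _prune_peaks(res.x, settings.min_peak_height)
        else:
            peak_params = np.empty(0)
        # refit aperiodic on the peak-subtracted spectrum
        y_ap = y - (_gaussians(f, peak_params) if peak_params.size else 0.0)
        b, chi = _fit_line(logf, y_ap)
        model = b - chi * logf + (_gaussians(f, peak_params) if peak_params.size else 0.0)
        err = float(np.mean(np.abs(y - model)))
        history.append(err)
        if err < best[0] - 1e-12:
            ss_res = float(np.sum((y - model) ** 2))
            ss_tot = float(np.sum((y - np.mean(y)) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            peaks = [
                (float(c), float(h), float(w))
                for c, h, w in peak_params.reshape(-1, 3)
                if h > 1e-3
            ]
            best = (err, AperiodicFit(float(b), float(chi), peaks, err, r2))
        else:
            break
    fit = best[1]
    if fit is None:
        raise RuntimeError("aperiodic fit failed to produce an iterate")
    fit.error_history = history[: history.index(fit.fit_error) + 1] if fit.fit_error in history else history
    return fit


def fit_aperiodic(ps: PowerSpectrum, settings: FitSettings | None = None) -> list[AperiodicFit]:
    """Fit every channel of a PowerSpectrum; returns one AperiodicFit per channel."""
    return [fit_aperiodic_spectrum(ps.freqs, ps.power[c], settings) for c in range(ps.power.shape[0])]


def slope_table(
    fits: list[AperiodicFit],
    channels: list[ChannelInfo],
    patient: str = "",
) -> pd.DataFrame:
    """Tidy per-channel table of (patient, channel, slope, offset, r2, soz)."""
    if len(fits) != len(channels):
        raise ValueError("one fit per channel required")
    return pd.DataFrame(
        {
            "patient": [patient] * len(fits),
            "channel": [c.label for c in channels],
            "slope": [f.slope for f in fits],
            "offset": [f.offset for f in fits],
            "r2": [f.r2 for f in fits],
            "soz": [bool(c.soz) for c in channels],
        }
    )
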