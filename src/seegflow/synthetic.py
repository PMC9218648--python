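"""Synthetic SEEG cohorts with known directed coupling and spectral structure.

The study conditions emulated here are those of a 27-patient drug-resistant
focal epilepsy cohort: stationary multichannel interictal recordings, a
directed MVAR coupling graph in which non-SOZ -> SOZ coupling exceeds
SOZ -> non-SOZ coupling by a configurable excess Delta (larger in the
seizure-free outcome class), per-channel 1/f^chi aperiodic backgrounds with
SOZ exponents drawn at 2.23 +/- 0.33 and non-SOZ at 2.08 +/- 0.44,
directional low-phase/high-amplitude cross-frequency coupling, and an
SOZ:non-SOZ electrode imbalance of 116:573.

Every generated MVAR is checked for stability (companion spectral radius
< 1); all randomness flows from one root seed through named substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._edf import write_edf
from .core_io import ChannelInfo, CohortManifest, PatientEntry, Recording
from .dtf import companion_spectral_radius

__all__ = [
    "CfcSpec",
    "GroundTruth",
    "simulate_mvar_network",
    "add_aperiodic_background",
    "inject_cross_frequency_coupling",
    "build_coupling",
    "simulate_patient",
    "simulate_cohort",
]

# Cohort-scale defaults (composition of the emulated clinical cohort)
DEFAULT_N_PATIENTS = 27
DEFAULT_OUTCOME_MIX = (19, 8)  # seizure-free (Engel I), non-seizure-free (II-IV)
DEFAULT_SOZ_FRACTION = 116 / 689
SOZ_EXPONENT = (2.23, 0.33)  # mean, sd of chi for SOZ channels
NON_SOZ_EXPONENT = (2.08, 0.44)
# Coupling scale: no quantitative coupling strength is available for real
# cohorts; these are the generator's declared effect sizes, fixed once from
# a calibration of the generator itself (see docs/methods.md).
DEFAULT_BASE_COUPLING = 0.20
DEFAULT_DELTA_FREE = 0.25
DEFAULT_DELTA_NONFREE = 0.08
# Common causal AR(1) tilt (pole) given to the network component so the
# composite spectrum is 1/f-like across 1-250 Hz: the filtered process is
# still a finite-order VAR and a scalar causal filter shared by all channels
# cancels exactly in the inflow-normalized DTF.
NETWORK_POLE = 0.85
DEFAULT_APERIODIC_WEIGHT = 1.0


@dataclass(frozen=True)
class CfcSpec:
    """One injected phase->amplitude coupling: the fp-band phase of ``source``
    modulates an fa carrier added to ``target``; positive ``lag`` (seconds)
    means the low-frequency phase leads the high-frequency amplitude."""

    source: int
    target: int
    phase_freq: float
    amp_freq: float
    lag: float
    depth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must be in [0, 1]")


@dataclass
class GroundTruth:
    coupling: np.ndarray  # (p, n, n) MVAR coefficients
    exponents: np.ndarray  # per-channel chi >= 0
    cfc_specs: list[CfcSpec] = field(default_factory=list)
    soz_labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    asymmetry: float = 0.0
    seed: int = 0


def _default_channels(n: int, labels: list[str] | None = None) -> list[ChannelInfo]:
    labels = labels or [f"C{i:02d}" for i in range(n)]
    return [ChannelInfo(label=lab) for lab in labels]


def simulate_mvar_network(
    coeffs: np.ndarray,
    noise_cov: np.ndarray | None,
    duration: float,
    fs: float,
    seed,
    burn_in: int = 500,
    channels: list[ChannelInfo] | None = None,
) -> Recording:
    """Realize X(t) = sum_k A_k X(t-k) + E(t) with Gaussian innovations.

    Raises if the coefficient set is unstable (companion spectral radius >= 1).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    rho = companion_spectral_radius(coeffs)
    if rho >= 1.0:
        raise ValueError(f"unstable MVAR coefficients (spectral radius {rho:.4f})")
    if noise_cov is None:
        noise_cov = np.eye(n)
    rng = np.random.default_rng(seed)
    T = int(round(duration * fs)) + burn_in
    L = np.linalg.cholesky(np.asarray(noise_cov, dtype=float))
    E = rng.standard_normal((T, n)) @ L.T
    X = np.zeros((T, n))
    X[:p] = E[:p]
    for t in range(p, T):
        acc = E[t]
        for k in range(1, p + 1):
            acc = acc + coeffs[k - 1] @ X[t - k]
        X[t] = acc
    sig = X[burn_in:].T
    return Recording(
        channels=channels or _default_channels(n),
        signal=sig,
        fs=fs,
        montage="referential",
    )


def _powerlaw_noise(n_ch: int, n_samp: int, exponents: np.ndarray, fs: float, rng) -> np.ndarray:
    """Unit-RMS noise with expected PSD proportional to 1/f^chi per channel."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    f = f.copy()
    f[0] = f[1]  # avoid DC blow-up; treated like the lowest bin
    shaped = spec * f[None, :] ** (-np.asarray(exponents)[:, None] / 2.0)
    x = np.fft.irfft(shaped, n=n_samp, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def add_aperiodic_background(
    rec: Recording, exponents, weight: float = 1.0, seed=0
) -> Recording:
    """Add spectrally shaped 1/f^chi noise, scaled to ``weight`` x channel RMS."""
    exponents = np.broadcast_to(np.asarray(exponents, dtype=float), (rec.n_channels,))
    if np.any(exponents < 0):
        raise ValueError("exponents must be >= 0")
    rng = np.random.default_rng(seed)
    noise = _powerlaw_noise(rec.n_channels, rec.n_samples, exponents, rec.fs, rng)
    rms = np.sqrt(np.mean(rec.signal**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    out = rec.signal + weight * rms * noise
    from dataclasses import replace

    return replace(rec, signal=out)


def inject_cross_frequency_coupling(
    rec: Recording, spec: CfcSpec, seed=0, amplitude: float | None = None
) -> Recording:
    """Add a high-frequency carrier to the target channel whose amplitude
    envelope follows the (lagged) low-frequency phase of the source channel.

    envelope(t) = (1 + depth * cos(phi_src(t - lag))) / 2; lag > 0 means the
    low-frequency phase leads the high-frequency amplitude.
    """
    fp, fa = spec.phase_freq, spec.amp_freq
    if not (fp < 30.0 < fa < rec.fs / 2):
        raise ValueError("require phase_freq < 30 < amp_freq < fs/2")
    rng = np.random.default_rng(seed)
    lo, hi = max(0.5, 0.7 * fp), 1.3 * fp
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    narrow = sps.sosfiltfilt(sos, rec.signal[spec.source])
    phase = np.angle(sps.hilbert(narrow))
    shift = int(round(spec.lag * rec.fs))
    phase_lagged = np.roll(phase, shift)  # phi_src(t - lag)
    env = (1.0 + spec.depth * np.cos(phase_lagged)) / 2.0
    t = np.arange(rec.n_samples) / rec.fs
    carrier = np.cos(2 * np.pi * fa * t + rng.uniform(0, 2 * np.pi))
    if amplitude is None:
        amplitude = float(np.sqrt(np.mean(rec.signal[spec.target] ** 2))) or 1.0
    out = rec.signal.copy()
    out[spec.target] = out[spec.target] + amplitude * env * carrier
    from dataclasses import replace

    return replace(rec, signal=out)


def phase_randomized_surrogate(signal: np.ndarray, rng) -> np.ndarray:
    """Phase-randomized surrogate of each channel (independent random phases):
    preserves every channel's power spectrum, destroys cross-channel coupling."""
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    rng = np.random.default_rng(rng)
    n = signal.shape[1]
    spec = np.fft.rfft(signal, axis=1)
    phases = np.exp(2j * np.pi * rng.random(spec.shape))
    phases[:, 0] = 1.0
    if n % 2 == 0:
        phases[:, -1] = 1.0
    return np.fft.irfft(spec * phases, n=n, axis=1)


def build_coupling(
    n: int,
    soz_mask: np.ndarray,
    base: float = DEFAULT_BASE_COUPLING,
    delta: float = DEFAULT_DELTA_FREE,
    rng=None,
    reverse: bool = False,
) -> np.ndarray:
    """Directed lag-1/lag-2 MVAR coefficient set with group-asymmetric coupling.

    ``base`` and ``base + delta`` are per-pair coupling scales (divided by
    n - 1 to keep the network stable as it grows): every non-SOZ -> SOZ pair
    couples at (base + delta) / (n - 1), every SOZ -> non-SOZ pair at
    base / (n - 1), and non-SOZ -> non-SOZ background pairs at a quarter of
    the base scale, each jittered by U(0.5, 1.5).  ``reverse=True`` swaps
    the direction of the excess (an "ictal-like" graph).  Coefficients are
    scaled down if needed so the companion spectral radius stays below 0.97.
    """
    rng = np.random.default_rng(rng)
    soz_mask = np.asarray(soz_mask, dtype=bool)
    soz = np.where(soz_mask)[0]
    non = np.where(~soz_mask)[0]
    if soz.size == 0 or non.size == 0:
        raise ValueError("coupling graph needs at least one SOZ and one non-SOZ channel")
    w_n2s, w_s2n = (base + delta) / (n - 1), base / (n - 1)
    if reverse:
        w_n2s, w_s2n = w_s2n, w_n2s
    A1 = np.zeros((n, n))
    for i in non:  # weak non-SOZ background network
        others = non[non != i]
        A1[i, others] = 0.25 * base / (n - 1) * rng.uniform(0.5, 1.5, size=others.size)
    for i in soz:
        A1[i, non] = w_n2s * rng.uniform(0.5, 1.5, size=non.size)
    for i in non:
        A1[i, soz] = w_s2n * rng.uniform(0.5, 1.5, size=soz.size)
    np.fill_diagonal(A1, 0.55)
    A2 = np.diag(np.full(n, -0.12))
    coeffs = np.stack([A1, A2])
    rho = companion_spectral_radius(coeffs)
    if rho >= 0.97:
        off = ~np.eye(n, dtype=bool)
        scale = 1.0
        while rho >= 0.97 and scale > 1e-3:
            scale *= 0.9
            A1s = A1.copy()
            A1s[off] *= scale
            coeffs = np.stack([A1s, A2])
            rho = companion_spectral_radius(coeffs)
    assert companion_spectral_radius(coeffs) < 1.0
    return coeffs


def _apply_common_tilt(rec: Recording, pole: float) -> Recording:
    """Causal leaky-integrator filter y(t) = pole*y(t-1) + x(t) on every
    channel, RMS-preserving.  A causal scalar filter shared by all channels
    keeps the process a finite-order VAR and cancels in normalized DTF;
    (a zero-phase filter would scramble the causal structure instead.)"""
    if not 0.0 < pole < 1.0:
        raise ValueError("network pole must lie in (0, 1)")
    out = sps.lfilter([1.0], [1.0, -pole], rec.signal, axis=1)
    rms_old = np.sqrt(np.mean(rec.signal**2, axis=1, keepdims=True))
    rms_new = np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    out = out * rms_old / np.maximum(rms_new, 1e-30)
    from dataclasses import replace

    return replace(rec, signal=out)


def _shaft_positions(n: int, rng) -> tuple[list[str], np.ndarray]:
    """Place contacts on depth-electrode shafts (3.5 mm pitch) inside a
    sphere of cortex-scale radius; returns labels and (n, 3) positions in mm."""
    contacts_per_shaft = 8
    n_shafts = int(np.ceil(n / contacts_per_shaft))
    labels, pos = [], []
    shaft_letters = "ABCDEFGHJKLMNPQRSTUVWXYZ"
    for s in range(n_shafts):
        entry = rng.normal(size=3)
        entry = 55.0 * entry / np.linalg.norm(entry)
        direction = -entry / np.linalg.norm(entry) + 0.3 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for c in range(contacts_per_shaft):
            if len(labels) >= n:
                break
            labels.append(f"{shaft_letters[s % len(shaft_letters)]}{c + 1}")
            pos.append(entry + 3.5 * c * direction)
    return labels, np.asarray(pos)


def simulate_patient(
    n_channels: int,
    soz_fraction: float = DEFAULT_SOZ_FRACTION,
    base: float = DEFAULT_BASE_COUPLING,
    delta: float = DEFAULT_DELTA_FREE,
    duration: float = 600.0,
    fs: float = 500.0,
    seed=0,
    aperiodic_weight: float = DEFAULT_APERIODIC_WEIGHT,
    network_pole: float = NETWORK_POLE,
    n_cfc: int = 1,
    cfc_lag: float = -0.03,
    cfc_depth: float = 0.6,
    reverse: bool = False,
) -> tuple[Recording, GroundTruth]:
    """One synthetic patient: MVAR network + 1/f background + CFC injection.

    The MVAR realization is tilted by a common causal AR(1) filter with the
    given pole (which leaves the normalized DTF of the coupling graph
    unchanged) and per-channel aperiodic noise with the configured exponents
    is added at ``aperiodic_weight`` x channel RMS, so the measured
    power-spectral slope of each electrode reflects its own chi.
    """
    if not 0.0 < soz_fraction < 1.0:
        raise ValueError("soz_fraction must be in (0, 1)")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_graph, s_sig, s_noise, s_cfc = ss.spawn(4)
    rng = np.random.default_rng(s_graph)
    n_soz = max(1, int(round(soz_fraction * n_channels)))
    if n_soz >= n_channels:
        raise ValueError("soz_fraction leaves no non-SOZ channel")
    soz_mask = np.zeros(n_channels, dtype=bool)
    soz_mask[rng.choice(n_channels, size=n_soz, replace=False)] = True

    coeffs = build_coupling(n_channels, soz_mask, base=base, delta=delta, rng=rng, reverse=reverse)
    labels, pos = _shaft_positions(n_channels, rng)
    channels = [
        ChannelInfo(label=labels[i], position=tuple(pos[i]), soz=bool(soz_mask[i]))
        for i in range(n_channels)
    ]
    rec = simulate_mvar_network(coeffs, None, duration, fs, s_sig, channels=channels)
    if network_pole > 0:
        rec = _apply_common_tilt(rec, network_pole)

    chi = np.where(
        soz_mask,
        rng.normal(*SOZ_EXPONENT, size=n_channels),
        rng.normal(*NON_SOZ_EXPONENT, size=n_channels),
    )
    chi = np.clip(chi, 0.5, 3.5)
    rec = add_aperiodic_background(rec, chi, weight=aperiodic_weight, seed=s_noise)

    specs: list[CfcSpec] = []
    cfc_rng = np.random.default_rng(s_cfc)
    soz_idx, non_idx = np.where(soz_mask)[0], np.where(~soz_mask)[0]
    for _ in range(n_cfc):
        spec = CfcSpec(
            source=int(cfc_rng.choice(soz_idx)),
            target=int(cfc_rng.choice(non_idx)),
            phase_freq=3.0,
            amp_freq=100.0,
            lag=cfc_lag,
            depth=cfc_depth,
        )
        rec = inject_cross_frequency_coupling(rec, spec, seed=cfc_rng.integers(2**31))
        specs.append(spec)

    truth = GroundTruth(
        coupling=coeffs,
        exponents=chi,
        cfc_specs=specs,
        soz_labels=soz_mask,
        asymmetry=delta,
        seed=int(np.random.default_rng(seed).integers(2**31)),
    )
    return rec, truth


def simulate_cohort(
    out_dir,
    n_patients: int = DEFAULT_N_PATIENTS,
    electrodes_per_patient: int = 24,
    soz_fraction: float = DEFAULT_SOZ_FRACTION,
    delta_free: float = DEFAULT_DELTA_FREE,
    delta_nonfree: float = DEFAULT_DELTA_NONFREE,
    base: float = DEFAULT_BASE_COUPLING,
    outcome_mix: tuple[int, int] = DEFAULT_OUTCOME_MIX,
    duration: float = 600.0,
    fs: float = 500.0,
    seed=0,
    reverse: bool = False,
    **patient_kwargs,
) -> tuple[CohortManifest, dict[str, GroundTruth]]:
    """Write a full cohort (EDF + channel tables + JSON manifest) to ``out_dir``.

    The outcome mix defaults to 19 seizure-free (Engel I) and 8 non-seizure-free
    patients (4 Engel II, 3 III, 1 IV); the non-SOZ -> SOZ coupling excess is
    ``delta_free`` for the seizure-free class and ``delta_nonfree`` otherwise.
    """
    if sum(outcome_mix) != n_patients:
        raise ValueError("outcome_mix must sum to n_patients")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    pat_seeds = ss.spawn(n_patients)
    n_free, n_not = outcome_mix
    engel_classes = ["I"] * n_free + ["II"] * min(4, n_not)
    rest = n_not - min(4, n_not)
    engel_classes += ["III"] * min(3, rest)
    engel_classes += ["IV"] * (rest - min(3, rest))
    lesional = (["none"] * 15 + ["focal"] * 9 + ["diffuse"] * 3) * (n_patients // 27 + 1)

    patients, truths = [], {}
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        seizure_free = i < n_free
        delta = delta_free if seizure_free else delta_nonfree
        rec, truth = simulate_patient(
            electrodes_per_patient,
            soz_fraction=soz_fraction,
            base=base,
            delta=delta,
            duration=duration,
            fs=fs,
            seed=pat_seeds[i],
            reverse=reverse,
            **patient_kwargs,
        )
        edf_path = out_dir / f"{pid}.edf"
        table_path = out_dir / f"{pid}_channels.tsv"
        write_edf(edf_path, rec.signal, rec.labels, fs, patient_id=pid)
        pd.DataFrame(
            {
                "label": rec.labels,
                "x": [c.position[0] for c in rec.channels],
                "y": [c.position[1] for c in rec.channels],
                "z": [c.position[2] for c in rec.channels],
                "white_matter": [int(c.white_matter) for c in rec.channels],
                "soz": [int(c.soz) for c in rec.channels],
                "region": ["" for _ in rec.channels],
            }
        ).to_csv(table_path, sep="\t", index=False, float_format="%.3f")
        patients.append(
            PatientEntry(
                id=pid,
                recording_paths=[edf_path.name],
                channel_table=table_path.name,
                engel=engel_classes[i],
                fs=fs,
                lesional=lesional[i],
            )
        )
        truths[pid] = truth
    manifest = CohortManifest(patients)
    manifest.save(out_dir / "manifest.json")
    (out_dir / "ground_truth.json").write_text(
        json.dumps(
            {
                pid: {
                    "soz": truths[pid].soz_labels.astype(int).tolist(),
                    "exponents": np.round(truths[pid].exponents, 4).tolist(),
                    "asymmetry": truths[pid].asymmetry,
                }
                for pid in truths
            },
            indent=1,
            sort_keys=True,
        )
    )
    return manifest, truths
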