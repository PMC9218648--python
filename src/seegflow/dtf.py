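"""Multivariate autoregressive modelling and the directed transfer function.

An MVAR model X(t) = sum_k A_k X(t-k) + E(t) fitted across 1 s epochs
yields the spectral transfer matrix H(f) = (I - sum_k A_k e^{-i2πfk/fs})^{-1}.
The (squared, inflow-normalized) directed transfer function

    gamma2[i, j, f] = |H_ij(f)|^2 / sum_m |H_im(f)|^2

measures the directed information flow j -> i at frequency f; each target's
row over sources sums to one.  Flow summaries follow the resting-state SEEG
convention: group-to-group mean flow between SOZ and non-SOZ channels,
per-channel inward/outward strength, and distance-stratified flow with
short (<33 mm), mid (33-60 mm) and long (>60 mm) range connections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .core_io import ChannelInfo, EpochedData

logger = logging.getLogger(__name__)

__all__ = [
    "MvarModel",
    "DtfTensor",
    "FlowSummary",
    "DistanceStrata",
    "companion_spectral_radius",
    "select_order",
    "fit_mvar",
    "dtf",
    "flow_between_groups",
    "distance_stratified_flow",
    "save_dtf",
    "load_dtf",
]

DEFAULT_FREQS = np.arange(1.0, 251.0)


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of A_1..A_p (stacked (p, n, n))."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class MvarModel:
    """Fitted MVAR coefficients A_1..A_p with residual covariance."""

    coeffs: np.ndarray  # (p, n, n)
    noise_cov: np.ndarray  # (n, n)
    fs: float
    stable: bool = True

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must be (p, n, n)")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-8):
            raise ValueError("noise covariance must be symmetric")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class DtfTensor:
    """Normalized squared DTF gamma2 (target x source x frequency)."""

    gamma2: np.ndarray
    freqs: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma2 = np.asarray(self.gamma2, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.gamma2.ndim != 3 or self.gamma2.shape[0] != self.gamma2.shape[1]:
            raise ValueError("gamma2 must be (n, n, n_freq)")
        if self.gamma2.shape[2] != self.freqs.size:
            raise ValueError("frequency axis mismatch")
        rows = self.gamma2.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(
                f"DTF normalization violated: max |row sum - 1| = {np.abs(rows - 1).max():.3e}"
            )

    @property
    def n_channels(self) -> int:
        return self.gamma2.shape[0]


@dataclass
class FlowSummary:
    freqs: np.ndarray
    soz_to_non: np.ndarray  # mean spectrum over (target in non-SOZ, source in SOZ)
    non_to_soz: np.ndarray
    inward: np.ndarray  # (n, n_freq)
    outward: np.ndarray  # (n, n_freq)


@dataclass
class DistanceStrata:
    edges: tuple[float, float]
    counts: dict[str, int]
    soz_to_non: dict[str, np.ndarray | None]
    non_to_soz: dict[str, np.ndarray | None]
    freqs: np.ndarray | None = None


def _design(ep: EpochedData, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled lagged design matrix; regressions never cross epoch boundaries."""
    data = ep.data  # (E, n, T)
    n_ep, n, T = data.shape
    if T <= p:
        raise ValueError("epoch shorter than model order")
    rows = n_ep * (T - p)
    X = np.empty((rows, n * p))
    Y = np.empty((rows, n))
    r = 0
    for e in range(n_ep):
        seg = data[e]
        m = T - p
        Y[r : r + m] = seg[:, p:].T
        for k in range(1, p + 1):
            X[r : r + m, (k - 1) * n : k * n] = seg[:, p - k : T - k].T
        r += m
    return X, Y


def fit_mvar(ep: EpochedData, p: int, ridge: float | None = None) -> MvarModel:
    """Pooled least-squares MVAR fit across epochs.

    ``ridge=None`` applies a small ridge penalty (1e-3 x mean diagonal of
    the normal equations) only when the design is data-poor (fewer than
    5 x n x p rows); pass ``ridge=0`` to force plain least squares.
    """
    n = ep.n_channels
    X, Y = _design(ep, p)
    if X.shape[0] <= n * p:
        raise ValueError("not enough data for the requested order")
    G = X.T @ X
    if ridge is None:
        ridge = 1e-3 * np.trace(G) / G.shape[0] if X.shape[0] < 5 * n * p else 0.0
        if ridge > 0:
            logger.info("ridge regularization applied (lambda=%.3g)", ridge)
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    try:
        B = np.linalg.solve(G, X.T @ Y)  # (n*p, n)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "ill-conditioned MVAR normal equations; reduce channels or order"
        ) from err
    coeffs = np.stack([B[(k - 1) * n : k * n].T for k in range(1, p + 1)])
    resid = Y - X @ B
    dof = max(X.shape[0] - n * p, 1)
    sigma = resid.T @ resid / dof
    rho = companion_spectral_radius(coeffs)
    stable = rho < 1.0
    if not stable:
        warnings.warn(f"fitted MVAR is unstable (spectral radius {rho:.3f})", RuntimeWarning)
    return MvarModel(coeffs=coeffs, noise_cov=sigma, fs=ep.fs, stable=stable)


def select_order(
    ep: EpochedData, p_max: int = 20, criterion: str = "aic"
) -> int:
    """Model order minimizing AIC or BIC on the pooled residual covariance.

    Ties and near-ties break toward the smallest order.
    """
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    n = ep.n_channels
    T = ep.data.shape[2]
    if p_max * n >= T:
        raise ValueError(f"p_max={p_max} too large for {T}-sample epochs with {n} channels")
    best_p, best_val = None, np.inf
    for p in range(1, p_max + 1):
        model = fit_mvar(ep, p, ridge=0.0)
        rows = ep.n_epochs * (T - p)
        sign, logdet = np.linalg.slogdet(model.noise_cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular residual covariance; reduce channels")
        k = p * n * n
        val = logdet + (2.0 * k / rows if criterion == "aic" else np.log(rows) * k / rows)
        if val < best_val - 1e-12:
            best_val, best_p = val, p
    return int(best_p)


def transfer_matrix(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    """Spectral transfer matrix H(f), shape (n_freq, n, n)."""
    p, n, _ = model.coeffs.shape
    freqs = np.asarray(freqs, dtype=float)
    k = np.arange(1, p + 1)
    # phase factors: (n_freq, p)
    z = np.exp(-2j * np.pi * np.outer(freqs, k) / model.fs)
    A = np.eye(n)[None, :, :] - np.einsum("fk,kij->fij", z, model.coeffs)
    H = np.empty_like(A)
    for fi in range(freqs.size):
        try:
            H[fi] = np.linalg.inv(A[fi])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular spectral matrix at f={freqs[fi]:g} Hz"
            ) from err
    return H


def dtf(model: MvarModel, freqs: np.ndarray | None = None, labels: list[str] | None = None) -> DtfTensor:
    """Squared inflow-normalized DTF on the given frequency grid (default 1-250 Hz)."""
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    if not model.stable:
        warnings.warn("computing DTF from an unstable MVAR model", RuntimeWarning)
    H = transfer_matrix(model, freqs)  # (F, n, n)
    power = np.abs(H) ** 2
    gamma2 = power / power.sum(axis=2, keepdims=True)
    return DtfTensor(
        gamma2=np.moveaxis(gamma2, 0, 2),
        freqs=freqs,
        labels=labels or [f"C{i:02d}" for i in range(model.n_channels)],
    )


def inward_strength(t: DtfTensor) -> np.ndarray:
    """Per-channel mean flow received from all other channels, (n, n_freq)."""
    n = t.n_channels
    off = ~np.eye(n, dtype=bool)
    out = np.empty((n, t.freqs.size))
    for i in range(n):
        out[i] = t.gamma2[i, off[i]].mean(axis=0)
    return out


def outward_strength(t: DtfTensor) -> np.ndarray:
    """Per-channel mean flow sent to all other channels, (n, n_freq)."""
    n = t.n_channels
    off = ~np.eye(n, dtype=bool)
    out = np.empty((n, t.freqs.size))
    for j in range(n):
        out[j] = t.gamma2[off[:, j], j].mean(axis=0)
    return out


def flow_between_groups(t: DtfTensor, soz_mask: np.ndarray) -> FlowSummary:
    """Mean bidirectional flow between SOZ and non-SOZ plus inward/outward strength."""
    soz_mask = np.asarray(soz_mask, dtype=bool)
    if soz_mask.size != t.n_channels:
        raise ValueError("mask length mismatch")
    if soz_mask.all() or not soz_mask.any():
        raise ValueError("both SOZ and non-SOZ groups must be non-empty")
    soz = np.where(soz_mask)[0]
    non = np.where(~soz_mask)[0]
    # soz_to_non: flow from SOZ sources into non-SOZ targets
    soz_to_non = t.gamma2[np.ix_(non, soz)].mean(axis=(0, 1))
    non_to_soz = t.gamma2[np.ix_(soz, non)].mean(axis=(0, 1))
    return FlowSummary(
        freqs=t.freqs,
        soz_to_non=soz_to_non,
        non_to_soz=non_to_soz,
        inward=inward_strength(t),
        outward=outward_strength(t),
    )


def distance_stratified_flow(
    t: DtfTensor,
    channels: list[ChannelInfo],
    edges: tuple[float, float] = (33.0, 60.0),
) -> DistanceStrata:
    """Directional SOZ/non-SOZ flow split by inter-electrode distance.

    Strata: short d < edges[0]; mid edges[0] <= d <= edges[1]; long d > edges[1]
    (both cut-offs in mm, Euclidean between contact midpoints).
    """
    if len(channels) != t.n_channels:
        raise ValueError("channel metadata length mismatch")
    pos = np.array([c.position for c in channels], dtype=float)
    soz = np.array([c.soz for c in channels], dtype=bool)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    lo, hi = edges
    strata_masks = {
        "short": d < lo,
        "mid": (d >= lo) & (d <= hi),
        "long": d > hi,
    }
    counts: dict[str, int] = {}
    s2n: dict[str, np.ndarray | None] = {}
    n2s: dict[str, np.ndarray | None] = {}
    for name, mask in strata_masks.items():
        sel_s2n = [
            (i, j) for i in np.where(~soz)[0] for j in np.where(soz)[0] if i != j and mask[i, j]
        ]
        sel_n2s = [
            (i, j) for i in np.where(soz)[0] for j in np.where(~soz)[0] if i != j and mask[i, j]
        ]
        counts[name] = len(sel_s2n) + len(sel_n2s)
        s2n[name] = (
            np.mean([t.gamma2[i, j] for i, j in sel_s2n], axis=0) if sel_s2n else None
        )
        n2s[name] = (
            np.mean([t.gamma2[i, j] for i, j in sel_n2s], axis=0) if sel_n2s else None
        )
    return DistanceStrata(edges=edges, counts=counts, soz_to_non=s2n, non_to_soz=n2s, freqs=t.freqs)


def save_dtf(path, t: DtfTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gamma2", data=t.gamma2)
        f.create_dataset("freqs", data=t.freqs)
        f.create_dataset("channels", data=np.array(t.labels, dtype="S"))


def load_dtf(path) -> DtfTensor:
    with h5py.File(path, "r") as f:
        return DtfTensor(
            gamma2=f["gamma2"][()],
            freqs=f["freqs"][()],
            labels=[s.decode() for s in f["channels"][()]],
        )
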