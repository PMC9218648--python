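"""Frequency-wise and group-level statistics.

Group comparisons of flow spectra use Welch (unequal-variance) two-sample
t-tests at each of the 250 frequency bins with Benjamini-Hochberg FDR
control across bins.  The per-patient flow-asymmetry statistic is the
broadband (1-250 Hz mean) difference between non-SOZ -> SOZ and
SOZ -> non-SOZ flow; a larger asymmetry in the seizure-free class is the
outcome association of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .dtf import FlowSummary

__all__ = [
    "FrequencyTestResult",
    "AsymmetryStat",
    "per_frequency_test",
    "fdr_correct",
    "flow_asymmetry",
    "slope_group_test",
]


@dataclass
class FrequencyTestResult:
    freqs: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    rejected: np.ndarray
    method: str = "BH-FDR"
    alpha: float = 0.05


@dataclass
class AsymmetryStat:
    """Per-patient broadband flow means and their difference."""

    non_to_soz: float
    soz_to_non: float

    @property
    def delta(self) -> float:
        return self.non_to_soz - self.soz_to_non


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def per_frequency_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.01,
    method: str = "BH-FDR",
) -> FrequencyTestResult:
    """Welch t-test at every frequency bin, BH-FDR corrected across bins.

    ``group_a``/``group_b`` are (n_observations, n_freqs).  Bins with zero
    variance in both groups get p = 1 with a warning.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 observations per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("frequency axes differ between groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sstats.ttest_ind(A, B, axis=0, equal_var=False)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(f"{bad.sum()} zero-variance frequency bins; p set to 1", RuntimeWarning)
        p = np.where(bad, 1.0, p)
        t = np.where(bad, 0.0, t)
    rejected = fdr_correct(p, q=alpha)
    freqs = np.arange(1, A.shape[1] + 1, dtype=float)
    return FrequencyTestResult(
        freqs=freqs, t_values=t, p_values=p, rejected=rejected, method=method, alpha=alpha
    )


def flow_asymmetry(flow: FlowSummary) -> AsymmetryStat:
    """Broadband (mean over the frequency grid) flow means and their delta."""
    return AsymmetryStat(
        non_to_soz=float(np.mean(flow.non_to_soz)),
        soz_to_non=float(np.mean(flow.soz_to_non)),
    )


def slope_group_test(table: pd.DataFrame) -> dict:
    """SOZ vs non-SOZ slope comparison.

    Electrode level: Welch two-sample t pooling electrodes across patients.
    Patient level: number of patients whose mean SOZ slope is more negative
    than their mean non-SOZ slope.
    """
    soz = table.loc[table["soz"], "slope"].to_numpy(dtype=float)
    non = table.loc[~table["soz"], "slope"].to_numpy(dtype=float)
    if soz.size < 2 or non.size < 2:
        raise ValueError("each group needs at least 2 electrodes for the t-test")
    t, p = sstats.ttest_ind(soz, non, equal_var=False)
    sign_count, n_pat = 0, 0
    for _, g in table.groupby("patient"):
        if g["soz"].any() and (~g["soz"]).any():
            n_pat += 1
            if g.loc[g["soz"], "slope"].mean() < g.loc[~g["soz"], "slope"].mean():
                sign_count += 1
    return {
        "t": float(t),
        "p": float(p),
        "n_soz": int(soz.size),
        "n_non_soz": int(non.size),
        "patients_more_negative_soz": int(sign_count),
        "n_patients": int(n_pat),
    }
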