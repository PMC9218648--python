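"""Balanced random-forest prediction of SOZ electrodes and seizure outcome.

Electrode-level features are the 250 inward-flow values (mean DTF received
from all other electrodes, 1-250 Hz in 1 Hz steps); patient-level features
are the 250-bin mean non-SOZ -> SOZ flow spectrum.  Class imbalance (SOZ
electrodes are the rare class, roughly 116:573) is handled by SMOTE
oversampling fitted inside each training fold plus inverse-class-frequency
tree weighting.  Evaluation uses stratified five-fold cross-validation with
pooled held-out ROC/AUC, accuracy and per-class precision/recall.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold
from sklearn.neighbors import NearestNeighbors

from .dtf import DtfTensor, inward_strength

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "electrode_features",
    "patient_features",
    "smote_resample",
    "train_balanced_rf",
    "crossvalidate",
    "predicted_soz_masks",
    "two_stage_outcome",
]


@dataclass
class FeatureTable:
    """Feature matrix with binary labels; feature k is the flow value at (k+1) Hz."""

    X: np.ndarray  # (n, n_features)
    y: np.ndarray  # (n,) 0/1; 1 is the positive class
    ids: list[str] = field(default_factory=list)  # patient id per row
    channels: list[str] = field(default_factory=list)
    level: str = "electrode"  # or "patient"
    positive_label: str = "SOZ"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, d) with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not self.ids:
            self.ids = [""] * self.y.size

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class ClassifierReport:
    auc: float
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    roc_points: np.ndarray  # (n_points, 2): fpr, tpr
    probs: np.ndarray  # pooled held-out P(positive), row order of the table
    labels: np.ndarray
    fold_test_indices: list[np.ndarray]
    fold_train_indices: list[np.ndarray]
    smote_provenance: list[list[tuple[int, int, float]]]
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "config": self.config,
            "seed": self.seed,
        }
        s = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(s)
        return s


def electrode_features(t: DtfTensor, patient: str = "") -> FeatureTable:
    """Per-electrode inward-flow features: feature k = mean over sources j != i
    of gamma2[i, j, k]."""
    soz = np.zeros(t.n_channels, dtype=int)
    return FeatureTable(
        X=inward_strength(t),
        y=soz,
        ids=[patient] * t.n_channels,
        channels=list(t.labels),
        level="electrode",
    )


def patient_features(
    t: DtfTensor, soz_mask: np.ndarray, include_reverse: bool = False
) -> np.ndarray:
    """Patient feature vector: mean non-SOZ -> SOZ flow spectrum
    (targets in SOZ, sources in non-SOZ); optionally append the reverse
    direction as extra features."""
    soz_mask = np.asarray(soz_mask, dtype=bool)
    if soz_mask.all() or not soz_mask.any():
        raise ValueError("both SOZ and non-SOZ groups must be non-empty")
    soz = np.where(soz_mask)[0]
    non = np.where(~soz_mask)[0]
    feat = t.gamma2[np.ix_(soz, non)].mean(axis=(0, 1))
    if include_reverse:
        feat = np.concatenate([feat, t.gamma2[np.ix_(non, soz)].mean(axis=(0, 1))])
    return feat


def smote_resample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    over_ratio: float = 1.0,
    under_ratio: float = 1.0,
    seed=0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, float]]]:
    """SMOTE oversampling of the minority class plus optional undersampling.

    Synthetic minority rows are uniform interpolations between a minority
    sample and one of its ``k_neighbors`` nearest minority neighbors.  With
    the default ratios the minority is oversampled to parity and the
    majority left intact, so the returned class counts are equal.  Returns
    (X_res, y_res, provenance) where provenance lists (i, j, lam) giving
    each synthetic row as (1-lam)*X[i] + lam*X[j].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj and over_ratio == 1.0 and under_ratio == 1.0:
        return X.copy(), y.copy(), []
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples <= k_neighbors={k_neighbors}; lower k"
        )
    min_idx = np.where(y == minority)[0]
    maj_idx = np.where(y != minority)[0]
    target_min = int(round(over_ratio * n_maj))
    n_syn = max(target_min - n_min, 0)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X[min_idx])
    _, neigh = nn.kneighbors(X[min_idx])  # first column is the point itself
    provenance: list[tuple[int, int, float]] = []
    syn_rows = []
    for _ in range(n_syn):
        a = int(rng.integers(n_min))
        b = int(neigh[a, 1 + rng.integers(k_neighbors)])
        lam = float(rng.uniform())
        syn_rows.append((1 - lam) * X[min_idx[a]] + lam * X[min_idx[b]])
        provenance.append((int(min_idx[a]), int(min_idx[b]), lam))

    new_min_count = n_min + n_syn
    target_maj = int(round(new_min_count / under_ratio))
    if target_maj < maj_idx.size:
        maj_idx = rng.choice(maj_idx, size=target_maj, replace=False)

    X_res = np.concatenate([X[min_idx], np.asarray(syn_rows).reshape(n_syn, X.shape[1]), X[maj_idx]])
    y_res = np.concatenate(
        [np.full(n_min, minority), np.full(n_syn, minority), y[maj_idx]]
    )
    return X_res, y_res, provenance


def train_balanced_rf(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    max_features: str | int = "sqrt",
    class_cost="balanced",
    seed=0,
) -> RandomForestClassifier:
    """Random forest with inverse-class-frequency misclassification weighting."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        class_weight=class_cost,
        random_state=int(np.random.default_rng(seed).integers(2**31)),
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def _metrics(labels: np.ndarray, probs: np.ndarray, positive_label: str) -> dict:
    pred = (probs >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    prec_pos = tp / (tp + fp) if tp + fp else 0.0
    rec_pos = tp / (tp + fn) if tp + fn else 0.0
    prec_neg = tn / (tn + fn) if tn + fn else 0.0
    rec_neg = tn / (tn + fp) if tn + fp else 0.0
    neg = f"non-{positive_label}"
    return {
        "accuracy": (tp + tn) / labels.size,
        "precision": {positive_label: prec_pos, neg: prec_neg},
        "recall": {positive_label: rec_pos, neg: rec_neg},
    }


def crossvalidate(
    table: FeatureTable,
    folds: int = 5,
    seed=0,
    use_smote: bool = True,
    k_neighbors: int = 5,
    n_trees: int = 500,
    grouped: bool = False,
) -> ClassifierReport:
    """Stratified k-fold cross-validation with in-fold SMOTE resampling.

    Resampling statistics are computed from training folds only; held-out
    rows are never interpolation endpoints.  ``grouped=True`` switches to
    stratified group k-fold on patient ids (no patient straddles folds).
    """
    y = table.y
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"smallest class has {counts.min()} samples < {folds} folds")
    rs = int(np.random.default_rng(seed).integers(2**31))
    if grouped:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=rs)
        splits = splitter.split(table.X, y, groups=table.ids)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        splits = splitter.split(table.X, y)

    probs = np.full(table.n, np.nan)
    fold_test, fold_train, provenance = [], [], []
    for f, (tr, te) in enumerate(splits):
        Xtr, ytr = table.X[tr], y[tr]
        prov: list[tuple[int, int, float]] = []
        if use_smote and np.unique(ytr).size == 2:
            # shrink k on small training folds rather than fail
            n_min_tr = int(np.unique(ytr, return_counts=True)[1].min())
            k_eff = min(k_neighbors, n_min_tr - 1)
            if k_eff >= 1:
                Xtr, ytr, prov_local = smote_resample(
                    Xtr, ytr, k_neighbors=k_eff, seed=rs + f
                )
                # map provenance back to row indices of the full table
                prov = [(int(tr[i]), int(tr[j]), lam) for i, j, lam in prov_local]
            else:
                logger.info("fold %d: minority too small for SMOTE; skipped", f)
        rf = train_balanced_rf(Xtr, ytr, n_trees=n_trees, seed=rs + 1000 + f)
        pos_col = int(np.where(rf.classes_ == 1)[0][0])
        probs[te] = rf.predict_proba(table.X[te])[:, pos_col]
        fold_test.append(np.asarray(te))
        fold_train.append(np.asarray(tr))
        provenance.append(prov)

    assert not np.any(np.isnan(probs))
    auc = float(roc_auc_score(y, probs)) if np.unique(y).size == 2 else float("nan")
    fpr, tpr, _ = roc_curve(y, probs)
    m = _metrics(y, probs, table.positive_label)
    return ClassifierReport(
        auc=auc,
        accuracy=float(m["accuracy"]),
        precision=m["precision"],
        recall=m["recall"],
        roc_points=np.column_stack([fpr, tpr]),
        probs=probs,
        labels=y.copy(),
        fold_test_indices=fold_test,
        fold_train_indices=fold_train,
        smote_provenance=provenance,
        config={
            "folds": folds,
            "use_smote": use_smote,
            "k_neighbors": k_neighbors,
            "n_trees": n_trees,
            "grouped": grouped,
            "level": table.level,
        },
        seed=int(seed) if np.isscalar(seed) else 0,
    )


def predicted_soz_masks(
    table: FeatureTable, report: ClassifierReport, threshold: float = 0.5
) -> dict[str, np.ndarray]:
    """Per-patient SOZ masks from out-of-fold probabilities.

    A patient whose electrodes all fall below threshold gets the top-1
    probability electrode as SOZ (logged fallback).
    """
    masks: dict[str, np.ndarray] = {}
    ids = np.asarray(table.ids)
    for pid in dict.fromkeys(table.ids):
        rows = np.where(ids == pid)[0]
        m = report.probs[rows] >= threshold
        if not m.any():
            m[np.argmax(report.probs[rows])] = True
            logger.info("patient %s: no electrode above threshold, top-1 fallback", pid)
        masks[pid] = m
    return masks


def two_stage_outcome(
    tensors: dict[str, DtfTensor],
    clinical_masks: dict[str, np.ndarray],
    outcomes: dict[str, bool],
    soz_source: str = "clinical",
    folds: int = 5,
    seed=0,
    n_trees: int = 500,
    include_reverse: bool = False,
) -> ClassifierReport:
    """Outcome prediction from patient-level flow features.

    ``soz_source='clinical'`` uses the annotated SOZ masks;
    ``soz_source='model'`` first cross-validates the electrode-level SOZ
    classifier and derives each patient's mask from its out-of-fold
    predicted probabilities (threshold 0.5, top-1 fallback).
    """
    pids = list(tensors)
    if soz_source == "model":
        rows_X, rows_y, rows_id = [], [], []
        for pid in pids:
            ft = electrode_features(tensors[pid], patient=pid)
            rows_X.append(ft.X)
            rows_y.append(np.asarray(clinical_masks[pid], dtype=int))
            rows_id += [pid] * ft.n
        etable = FeatureTable(
            X=np.concatenate(rows_X),
            y=np.concatenate(rows_y),
            ids=rows_id,
            level="electrode",
        )
        ereport = crossvalidate(etable, folds=folds, seed=seed, n_trees=n_trees)
        masks = predicted_soz_masks(etable, ereport)
    elif soz_source == "clinical":
        masks = {pid: np.asarray(clinical_masks[pid], dtype=bool) for pid in pids}
    else:
        raise ValueError("soz_source must be 'clinical' or 'model'")

    X = np.stack(
        [patient_features(tensors[pid], masks[pid], include_reverse) for pid in pids]
    )
    y = np.array([int(outcomes[pid]) for pid in pids])
    ptable = FeatureTable(X=X, y=y, ids=pids, level="patient", positive_label="seizure-free")
    return crossvalidate(ptable, folds=folds, seed=seed, n_trees=n_trees)
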