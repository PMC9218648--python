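"""Feature construction, SMOTE, balanced random forest and cross-validation."""

import numpy as np
import pytest

from seegflow import classify, dtf


def _random_tensor(n, n_freq=250, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.random((n, n, n_freq))
    g /= g.sum(axis=1, keepdims=True)
    return dtf.DtfTensor(gamma2=g, freqs=np.arange(1.0, n_freq + 1.0))


def _gaussian_table(n_pos=116, n_neg=573, sep=0.0, d=250, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate(
        [rng.standard_normal((n_pos, d)) + sep, rng.standard_normal((n_neg, d))]
    )
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    ids = [f"P{i % 20}" for i in range(n_pos + n_neg)]
    return classify.FeatureTable(X=X, y=y, ids=ids)


class TestFeatures:
    def test_electrode_features_250_per_electrode(self):
        t = _random_tensor(5)
        ft = classify.electrode_features(t)
        assert ft.X.shape == (5, 250)

    def test_two_channel_features_equal_cross_spectrum(self):
        t = _random_tensor(2)
        ft = classify.electrode_features(t)
        assert np.array_equal(ft.X[0], t.gamma2[0, 1])
        assert np.array_equal(ft.X[1], t.gamma2[1, 0])

    def test_uniform_tensor_constant_features(self):
        g = np.full((4, 4, 10), 0.25)
        t = dtf.DtfTensor(gamma2=g, freqs=np.arange(1.0, 11.0))
        ft = classify.electrode_features(t)
        assert np.allclose(ft.X, 0.25)

    def test_patient_features_single_pair(self):
        t = _random_tensor(2)
        feat = classify.patient_features(t, np.array([True, False]))
        assert np.array_equal(feat, t.gamma2[0, 1])

    def test_patient_features_empty_group_fatal(self):
        with pytest.raises(ValueError):
            classify.patient_features(_random_tensor(3), np.ones(3, dtype=bool))


class TestSmote:
    def test_balanced_table_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        y = np.array([0, 1] * 10)
        Xr, yr, prov = classify.smote_resample(X, y)
        assert np.array_equal(Xr, X) and np.array_equal(yr, y) and prov == []

    def test_synthetic_rows_on_minority_segments(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.standard_normal((12, 4)) + 3, rng.standard_normal((40, 4))])
        y = np.array([1] * 12 + [0] * 40)
        Xr, yr, prov = classify.smote_resample(X, y, k_neighbors=5, seed=2)
        minority_rows = X[y == 1]
        n_syn = len(prov)
        syn = Xr[12 : 12 + n_syn]  # synthetic block follows original minority
        # exhaustive geometric check: each synthetic row is on a segment
        # between some minority pair
        for z in syn:
            on_segment = False
            for i in range(12):
                for j in range(12):
                    if i == j:
                        continue
                    d = minority_rows[j] - minority_rows[i]
                    denom = np.dot(d, d)
                    lam = np.dot(z - minority_rows[i], d) / denom
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                        z, minority_rows[i] + lam * d, atol=1e-9
                    ):
                        on_segment = True
            assert on_segment

    def test_neighbor_constraint_in_provenance(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.standard_normal((10, 3)), 5 + rng.standard_normal((30, 3))])
        y = np.array([1] * 10 + [0] * 30)
        _, _, prov = classify.smote_resample(X, y, k_neighbors=3, seed=4)
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=4).fit(X[:10])
        _, neigh = nn.kneighbors(X[:10])
        for i, j, lam in prov:
            assert j in neigh[i, 1:]
            assert 0.0 <= lam <= 1.0

    def test_imbalanced_counts_equalized(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((116 + 573, 10))
        y = np.array([1] * 116 + [0] * 573)
        _, yr, _ = classify.smote_resample(X, y, seed=6)
        assert (yr == 1).sum() == (yr == 0).sum() == 573

    def test_minority_smaller_than_k_fatal(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        y = np.array([1] * 4 + [0] * 16)
        with pytest.raises(ValueError, match="k"):
            classify.smote_resample(X, y, k_neighbors=5)


class TestBalancedRf:
    def test_separable_classes_high_training_auc(self):
        table = _gaussian_table(n_pos=40, n_neg=60, sep=5.0, d=10)
        rf = classify.train_balanced_rf(table.X, table.y, n_trees=50, seed=0)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(table.y, rf.predict_proba(table.X)[:, 1]) > 0.99

    def test_single_class_fatal(self):
        with pytest.raises(ValueError):
            classify.train_balanced_rf(np.ones((10, 3)), np.ones(10, dtype=int))

    def test_seed_determinism(self):
        table = _gaussian_table(n_pos=30, n_neg=70, sep=0.5, d=8)
        r1 = classify.crossvalidate(table, seed=11, n_trees=50)
        r2 = classify.crossvalidate(table, seed=11, n_trees=50)
        assert np.array_equal(r1.probs, r2.probs)
        assert r1.auc == r2.auc


class TestCrossvalidate:
    def test_null_features_chance_auc(self):
        table = _gaussian_table(n_pos=80, n_neg=120, sep=0.0, d=20, seed=7)
        rep = classify.crossvalidate(table, seed=0, n_trees=100)
        assert 0.3 < rep.auc < 0.7

    def test_stratified_fold_proportions(self):
        table = _gaussian_table(n_pos=116, n_neg=573, sep=0.0, d=5, seed=8)
        rep = classify.crossvalidate(table, seed=1, n_trees=20)
        global_frac = table.y.mean()
        for te in rep.fold_test_indices:
            n_pos = table.y[te].sum()
            expected = global_frac * te.size
            assert abs(n_pos - expected) <= 1.0

    def test_accuracy_matches_brute_force_confusion(self):
        table = _gaussian_table(n_pos=50, n_neg=80, sep=1.0, d=10, seed=9)
        rep = classify.crossvalidate(table, seed=2, n_trees=50)
        pred = (rep.probs >= 0.5).astype(int)
        assert rep.accuracy == pytest.approx(np.mean(pred == rep.labels))
        tp = np.sum((pred == 1) & (rep.labels == 1))
        fp = np.sum((pred == 1) & (rep.labels == 0))
        if tp + fp:
            assert rep.precision["SOZ"] == pytest.approx(tp / (tp + fp))

    def test_auc_invariant_to_monotone_transform(self):
        table = _gaussian_table(n_pos=40, n_neg=60, sep=1.0, d=10, seed=10)
        rep = classify.crossvalidate(table, seed=3, n_trees=50)
        from sklearn.metrics import roc_auc_score

        transformed = 1 / (1 + np.exp(-5 * (rep.probs - 0.2)))
        assert roc_auc_score(rep.labels, transformed) == pytest.approx(rep.auc)

    def test_no_leakage_heldout_never_endpoints(self):
        table = _gaussian_table(n_pos=30, n_neg=120, sep=0.5, d=10, seed=11)
        rep = classify.crossvalidate(table, seed=4, n_trees=20)
        for tr, te, prov in zip(
            rep.fold_train_indices, rep.fold_test_indices, rep.smote_provenance
        ):
            held = set(te.tolist())
            for i, j, _ in prov:
                assert i not in held and j not in held
                assert i in set(tr.tolist()) and j in set(tr.tolist())

    def test_class_smaller_than_folds_fatal(self):
        table = _gaussian_table(n_pos=3, n_neg=50, d=4, seed=12)
        with pytest.raises(ValueError):
            classify.crossvalidate(table, folds=5)


class TestTwoStage:
    def _cohort(self, sep, n_pat=12, seed=0):
        rng = np.random.default_rng(seed)
        tensors, masks, outcomes = {}, {}, {}
        for i in range(n_pat):
            pid = f"P{i:02d}"
            t = _random_tensor(8, n_freq=50, seed=seed * 100 + i)
            g = t.gamma2.copy()
            mask = np.zeros(8, dtype=bool)
            mask[:2] = True
            free = i < n_pat // 2
            if free:  # boost non-SOZ -> SOZ flow for seizure-free patients
                g[np.ix_(np.where(mask)[0], np.where(~mask)[0])] *= 1 + sep
                g /= g.sum(axis=1, keepdims=True)
            tensors[pid] = dtf.DtfTensor(gamma2=g, freqs=t.freqs)
            masks[pid] = mask
            outcomes[pid] = free
        return tensors, masks, outcomes

    def test_clinical_source_deterministic(self):
        tensors, masks, outcomes = self._cohort(sep=0.8)
        r1 = classify.two_stage_outcome(tensors, masks, outcomes, folds=3, seed=5, n_trees=50)
        r2 = classify.two_stage_outcome(tensors, masks, outcomes, folds=3, seed=5, n_trees=50)
        assert r1.auc == r2.auc and np.array_equal(r1.probs, r2.probs)

    def test_separated_cohort_predicts_outcome(self):
        tensors, masks, outcomes = self._cohort(sep=1.0)
        rep = classify.two_stage_outcome(tensors, masks, outcomes, folds=3, seed=6, n_trees=100)
        assert rep.auc > 0.8

    def test_model_source_runs_and_reports(self):
        tensors, masks, outcomes = self._cohort(sep=1.0)
        rep = classify.two_stage_outcome(
            tensors, masks, outcomes, soz_source="model", folds=3, seed=7, n_trees=50
        )
        assert 0.0 <= rep.auc <= 1.0

    def test_fallback_single_soz_electrode(self):
        table = classify.FeatureTable(
            X=np.random.default_rng(0).standard_normal((6, 4)),
            y=np.array([0, 0, 0, 1, 1, 1]),
            ids=["A"] * 3 + ["B"] * 3,
        )
        report = classify.ClassifierReport(
            auc=0.5, accuracy=0.5, precision={}, recall={},
            roc_points=np.zeros((1, 2)),
            probs=np.array([0.1, 0.2, 0.3, 0.9, 0.8, 0.7]),
            labels=table.y, fold_test_indices=[], fold_train_indices=[],
            smote_provenance=[],
        )
        masks = classify.predicted_soz_masks(table, report, threshold=0.5)
        assert masks["A"].sum() == 1 and masks["A"][2]  # top-1 fallback
        assert masks["B"].sum() == 3
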