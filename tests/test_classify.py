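"""Feature assembly, control matching, nested CV, ROC/PR, DeLong."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from megnets.classify import (
    FeatureTable,
    assemble_features,
    delong_ci,
    mann_whitney_auc,
    match_controls,
    nested_cv_classify,
    roc_pr_confusion,
)


def synthetic_tables(n_subjects=6, n_parcels=52, n_modes=6, seed=0):
    rng = np.random.default_rng(seed)
    subjects = [f"s{i:02d}" for i in range(n_subjects)]
    bands = ["delta", "theta", "alpha", "beta", "low_gamma", "high_gamma"]
    power = pd.DataFrame(
        [
            {"subject": s, "band": b, "parcel": p, "power": rng.random()}
            for s in subjects
            for b in bands
            for p in range(n_parcels)
        ]
    )
    shape = pd.DataFrame(
        [
            {
                "subject": s,
                "parcel": p,
                "offset": rng.random(),
                "exponent": rng.random(),
                "coe": rng.random(),
            }
            for s in subjects
            for p in range(n_parcels)
        ]
    )
    dyn_summary = pd.DataFrame(
        [
            {
                "subject": s,
                "mode": k,
                "strength": rng.random(),
                "variability": rng.random(),
                "concentration": rng.random(),
                "coactivation_mean": rng.random(),
            }
            for s in subjects
            for k in range(n_modes)
        ]
    )
    dyn_pairs = pd.DataFrame(
        [
            {"subject": s, "mode_a": a, "mode_b": b, "coactivation": rng.random()}
            for s in subjects
            for a in range(n_modes)
            for b in range(a + 1, n_modes)
        ]
    )
    dyn_conn = pd.DataFrame(
        [
            {"subject": s, "mode": k, "parcel": p, "connectedness": rng.random()}
            for s in subjects
            for k in range(n_modes)
            for p in range(n_parcels)
        ]
    )
    labels = pd.Series([0, 0, 0, 1, 1, 1], index=subjects)
    return power, shape, dyn_summary, dyn_pairs, dyn_conn, labels


class TestAssembleFeatures:
    def test_full_feature_count(self):
        """52*6 powers + 52*2 shape + 6*52 dconn + 15 + 6 coact + 6*3 summary = 767."""
        power, shape, dsum, dpairs, dconn, labels = synthetic_tables()
        ft = assemble_features(power, shape, dsum, dpairs, dconn, labels)
        assert len(ft.feature_names) == 52 * 6 + 52 * 2 + 6 * 52 + 15 + 6 + 18 == 767

    def test_label_column_never_a_feature(self):
        power, shape, dsum, dpairs, dconn, labels = synthetic_tables()
        ft = assemble_features(power, shape, dsum, dpairs, dconn, labels)
        assert not any(n in {"label", "labels", "subject"} for n in ft.feature_names)

    def test_column_order_deterministic(self):
        power, shape, dsum, dpairs, dconn, labels = synthetic_tables()
        a = assemble_features(power, shape, dsum, dpairs, dconn, labels)
        b = assemble_features(power, shape, dsum, dpairs, dconn, labels)
        assert a.feature_names == b.feature_names
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_missing_subject_rejected(self):
        power, shape, dsum, dpairs, dconn, labels = synthetic_tables()
        with pytest.raises(ValueError, match="missing"):
            assemble_features(
                power[power.subject != "s02"], shape, dsum, dpairs, dconn, labels
            )


class TestMatchControls:
    def test_identical_pools_give_zero_difference(self):
        ages = np.array([40.0, 45.0, 50.0, 55.0])
        idx, diff = match_controls(ages, ages, n_controls=4, seed=0)
        assert diff == pytest.approx(0.0, abs=1e-12)

    def test_printed_design_sizes(self):
        rng = np.random.default_rng(0)
        hc = rng.normal(57, 16, 84)
        risk = rng.normal(47.5, 13, 28)
        idx, diff = match_controls(hc, risk, n_controls=40, seed=0)
        assert idx.size == 40
        assert abs(diff) < 3.0

    def test_greedy_close_to_exhaustive_optimum(self):
        rng = np.random.default_rng(1)
        hc = rng.uniform(30, 70, 8)
        risk = rng.uniform(35, 65, 3)
        n_pick = 4
        idx, diff = match_controls(hc, risk, n_controls=n_pick, seed=0)
        best = min(
            abs(np.mean(hc[list(c)]) - risk.mean())
            for c in combinations(range(8), n_pick)
        )
        assert abs(diff) <= best + 0.5

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            match_controls(np.arange(5.0), np.arange(3.0), n_controls=6)


class TestNestedCV:
    def _table(self, X, y):
        return FeatureTable(
            matrix=X,
            feature_names=[f"f{i}" for i in range(X.shape[1])],
            labels=y,
            subject_ids=[f"s{i}" for i in range(X.shape[0])],
        )

    def test_perfectly_separable_feature(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 5))
        y = (np.arange(30) % 2).astype(int)
        X[:, 2] = y * 4 + rng.standard_normal(30) * 0.01
        rep = nested_cv_classify(
            self._table(X, y), seed=0, n_search_iter=2, feature_k=(2, None),
            param_space={"n_estimators": [50], "max_depth": [None]},
        )
        assert rep.roc_auc == 1.0
        assert np.all(np.isfinite(rep.oof_probabilities))

    def test_fold_hashes_exclude_test_subjects(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 5))
        y = (np.arange(30) % 2).astype(int)
        rep = nested_cv_classify(
            self._table(X, y), seed=1, n_search_iter=2, feature_k=(3,),
            param_space={"n_estimators": [50], "max_depth": [4]},
        )
        assert len(set(rep.train_index_hashes)) == 5

    def test_selected_features_are_namespaced_columns(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 6))
        y = (np.arange(30) % 2).astype(int)
        rep = nested_cv_classify(
            self._table(X, y), seed=2, n_search_iter=2, feature_k=(2,),
            param_space={"n_estimators": [50], "max_depth": [4]},
        )
        names = {f"f{i}" for i in range(6)}
        for fold_feats in rep.selected_features:
            assert set(fold_feats) <= names


class TestRocPr:
    def test_perfect_scores(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        rep = roc_pr_confusion(s, y)
        assert rep.roc_auc == 1.0
        assert rep.pr_auc == pytest.approx(1.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        np.testing.assert_array_equal(rep.confusion, [[3, 0], [0, 3]])

    def test_auc_equals_mann_whitney_everywhere(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            s = rng.standard_normal(60)
            s[rng.random(60) < 0.3] = 0.5  # inject ties
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            rep = roc_pr_confusion(s, y)
            assert rep.roc_auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
            assert rep.roc_auc == pytest.approx(mann_whitney_auc(s, y), abs=1e-12)

    def test_negated_scores_flip_auc(self):
        rng = np.random.default_rng(6)
        s = rng.standard_normal(50)
        y = rng.integers(0, 2, 50)
        a = roc_pr_confusion(s, y).roc_auc
        b = roc_pr_confusion(-s, y).roc_auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_pr_confusion(np.array([0.1, 0.9]), np.array([1, 1]))


class TestDeLong:
    def test_point_estimate_is_mann_whitney(self):
        rng = np.random.default_rng(7)
        s = rng.standard_normal(80)
        y = rng.integers(0, 2, 80)
        auc, lo, hi = delong_ci(s, y)
        assert auc == pytest.approx(mann_whitney_auc(s, y), abs=1e-15)
        assert lo <= auc <= hi

    def test_separated_classes_boundary(self):
        s = np.concatenate([np.zeros(10), np.ones(10)])
        y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        auc, lo, hi = delong_ci(s, y)
        assert auc == 1.0
        assert hi == 1.0

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            delong_ci(np.array([0.1, 0.5, 0.9]), np.array([1, 0, 1]))
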