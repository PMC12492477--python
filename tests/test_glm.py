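"""Design construction, OLS contrasts, max-t permutation, age trajectories."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from megnets.glm import (
    beta_age_trajectory,
    build_design,
    fit_glm,
    maxt_permutation,
)


def make_metadata(groups, seed=0, **extra):
    rng = np.random.default_rng(seed)
    labels = [g for g, n in groups for _ in range(n)]
    n = len(labels)
    base = {
        "id": [f"s{i:03d}" for i in range(n)],
        "group": labels,
        "age": rng.normal(55, 12, n),
        "sex": rng.integers(0, 2, n),
        "riluzole": rng.integers(0, 2, n),
        "missing_mri": rng.integers(0, 2, n),
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestDesign:
    def test_group_columns_partition_subjects(self):
        meta = make_metadata([("HC", 10), ("symALS", 7), ("aC9", 4), ("aSOD", 3)])
        d = build_design(meta)
        for g, n in [("HC", 10), ("symALS", 7), ("aC9", 4), ("aSOD", 3)]:
            col = d.X[:, d.regressor_names.index(g)]
            assert set(col) <= {0.0, 1.0}
            assert col.sum() == n
        ind = d.X[:, :4]
        np.testing.assert_allclose(ind.sum(axis=1), 1.0)

    def test_confounds_standardized(self):
        meta = make_metadata([("HC", 12), ("symALS", 8)])
        d = build_design(meta)
        for c in ("age", "sex"):
            col = d.X[:, d.regressor_names.index(c)]
            assert abs(col.mean()) < 1e-10
            assert abs(col.var() - 1) < 1e-10

    def test_default_contrasts_match_printed_comparisons(self):
        meta = make_metadata([("HC", 5), ("symALS", 5), ("aC9", 5), ("aSOD", 5)])
        d = build_design(meta)
        assert list(d.contrasts) == ["symALS-HC", "aC9-HC", "aSOD-HC", "aC9-aSOD"]

    def test_constant_confound_dropped_with_warning(self):
        meta = make_metadata([("HC", 6), ("symALS", 6)], riluzole=0)
        with pytest.warns(UserWarning, match="riluzole"):
            d = build_design(meta)
        assert "riluzole" not in d.regressor_names


class TestFitGlm:
    def test_matches_pooled_two_sample_t(self):
        rng = np.random.default_rng(1)
        meta = make_metadata([("HC", 12), ("symALS", 10)])
        d = build_design(meta, confounds=())
        y = rng.standard_normal(22)
        cope, t, dof = fit_glm(y, d, d.contrasts["symALS-HC"])
        ref = stats.ttest_ind(y[12:], y[:12], equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert dof == 20

    def test_identical_outcomes_give_zero(self):
        meta = make_metadata([("HC", 5), ("symALS", 5)])
        d = build_design(meta)
        cope, t, _ = fit_glm(np.full(10, 3.3), d, d.contrasts["symALS-HC"])
        assert cope == pytest.approx(0.0, abs=1e-12)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_confound_absorbs_linear_signal(self):
        meta = make_metadata([("HC", 20), ("symALS", 20)], seed=2)
        d = build_design(meta, confounds=("age",))
        y = 0.5 * meta["age"].to_numpy()
        cope, _, _ = fit_glm(y, d, d.contrasts["symALS-HC"])
        assert cope == pytest.approx(0.0, abs=1e-8)

    def test_non_finite_outcome_rejected(self):
        meta = make_metadata([("HC", 4), ("symALS", 4)])
        d = build_design(meta)
        y = np.ones(8)
        y[3] = np.nan
        with pytest.raises(ValueError, match=r"\[3\]"):
            fit_glm(y, d, d.contrasts["symALS-HC"])


class TestMaxT:
    def test_exact_enumeration_matches_oracle(self):
        meta = make_metadata([("HC", 3), ("symALS", 3)], age=0.0, sex=0, riluzole=0,
                             missing_mri=0)
        d = build_design(meta, confounds=())
        y = np.array([0.1, -0.2, 0.05, 1.1, 0.9, 1.3])
        res = maxt_permutation(y[:, None], d, d.contrasts["symALS-HC"], exact=True)
        assert res.n_perm == 20
        t_obs = stats.ttest_ind(y[3:], y[:3], equal_var=True).statistic
        null = []
        for comb in combinations(range(6), 3):
            grp = np.zeros(6, dtype=bool)
            grp[list(comb)] = True
            null.append(stats.ttest_ind(y[grp], y[~grp], equal_var=True).statistic)
        p_oracle = (1 + sum(t >= t_obs for t in null)) / 21
        assert res.p_corrected[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_no_signal_no_rejection(self):
        meta = make_metadata([("HC", 8), ("symALS", 8)])
        d = build_design(meta)
        Y = np.tile(np.linspace(0, 1, 5), (16, 1))
        res = maxt_permutation(Y, d, d.contrasts["symALS-HC"], n_perm=200, seed=0)
        assert np.all(res.p_corrected > 0.05)

    def test_p_monotone_in_t(self):
        rng = np.random.default_rng(3)
        meta = make_metadata([("HC", 15), ("symALS", 15)])
        d = build_design(meta, confounds=())
        Y = rng.standard_normal((30, 20))
        Y[15:, 0] += 2.0
        Y[15:, 1] += 0.5
        res = maxt_permutation(Y, d, d.contrasts["symALS-HC"], n_perm=500, seed=1)
        order = np.argsort(res.tstat)
        p_sorted = res.p_corrected[order]
        assert np.all(np.diff(p_sorted) <= 1e-12)

    def test_single_feature_agrees_with_parametric_t(self):
        rng = np.random.default_rng(4)
        meta = make_metadata([("HC", 20), ("symALS", 20)], seed=4)
        d = build_design(meta, confounds=())
        y = rng.standard_normal(40)
        y[20:] += 0.6
        res = maxt_permutation(y[:, None], d, d.contrasts["symALS-HC"], n_perm=5000, seed=2)
        t_ref = stats.ttest_ind(y[20:], y[:20], equal_var=True)
        p_param = stats.t.sf(t_ref.statistic, 38)
        assert res.p_corrected[0] == pytest.approx(p_param, abs=0.01)

    def test_pure_confound_signal_does_not_inflate_fwe(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_runs = 50
        for i in range(n_runs):
            meta = make_metadata([("HC", 15), ("symALS", 15)], seed=100 + i)
            d = build_design(meta, confounds=("age",))
            zage = meta["age"].to_numpy()
            Y = rng.standard_normal((30, 10)) + 0.1 * zage[:, None]
            res = maxt_permutation(Y, d, d.contrasts["symALS-HC"], n_perm=200, seed=i)
            rejections += int(np.any(res.p_corrected <= 0.05))
        # nominal 5%: tolerate up to the upper 99% binomial bound
        assert rejections <= stats.binom.ppf(0.99, n_runs, 0.05)


class TestAgeTrajectory:
    def _betapower(self, meta, slopes, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        n, P = len(meta), len(slopes)
        age = meta["age"].to_numpy()
        Y = 1.0 + np.outer(age - 55, slopes) + noise * rng.standard_normal((n, P))
        return pd.DataFrame(Y, index=meta["id"])

    def test_null_slope_selects_nothing(self):
        meta = make_metadata([("HC", 40)], seed=6)
        bp = self._betapower(meta, np.zeros(8))
        with pytest.warns(UserWarning, match="no parcels"):
            res = beta_age_trajectory(bp, meta)
        assert res.selected_parcels.size == 0

    def test_selection_recovers_injected_parcels(self):
        meta = make_metadata([("HC", 500)], seed=7)
        slopes = np.zeros(20)
        slopes[5:15] = 0.02
        bp = self._betapower(meta, slopes, noise=0.05, seed=7)
        res = beta_age_trajectory(bp, meta)
        np.testing.assert_array_equal(res.selected_parcels, np.arange(5, 15))

    def test_group_regression_matches_pearson_oracle(self):
        meta = make_metadata([("HC", 60), ("symALS", 40)], seed=8)
        slopes = np.full(6, 0.02)
        bp = self._betapower(meta, slopes, noise=0.03, seed=8)
        res = beta_age_trajectory(bp, meta)
        mean_beta = bp.iloc[:, res.selected_parcels].mean(axis=1)
        hc_mask = (meta["group"] == "HC").to_numpy()
        r_oracle = stats.pearsonr(
            meta["age"].to_numpy()[hc_mask], mean_beta.to_numpy()[hc_mask]
        ).statistic
        assert res.group_regressions["HC"][1] == pytest.approx(r_oracle, abs=1e-10)
        assert "symALS" in res.interaction_t
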