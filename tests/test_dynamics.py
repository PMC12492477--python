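"""TDE+PCA preparation, surrogate mode inference, mode spectra, summaries."""


import numpy as np
import pytest
from scipy.stats import kurtosis


from megnets.dynamics import (
    ModeSpectra,
    ModeTimeCourses,
    dynamic_parcel_connectedness,
    infer_mode_mixing,
    match_modes,
    mode_spectra,
    mode_summary,
    tde_pca_prepare,
)
from megnets.simulate import simulate_mode_timecourses, _bandlimited_source
from megnets.spectral import welch_psd

from conftest import make_ts

FS = 250.0


class TestTdePca:
    def test_embedded_dimension_contract(self):
        rng = np.random.default_rng(0)
        ts = make_ts(rng.standard_normal((52, int(10 * FS))))
        prep = tde_pca_prepare(ts, n_lags=15, n_components=100)
        assert prep.projection.shape == (52 * 15, 100)
        assert prep.components.shape[0] == 100

    def test_components_mutually_uncorrelated(self):
        rng = np.random.default_rng(1)
        ts = make_ts(rng.standard_normal((6, 4000)))
        prep = tde_pca_prepare(ts, n_lags=15, n_components=10)
        c = prep.components - prep.components.mean(axis=1, keepdims=True)
        gram = c @ c.T
        off = gram[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) / np.max(np.abs(np.diag(gram))) < 1e-8

    def test_explained_variance_sorted_and_bounded(self):
        rng = np.random.default_rng(2)
        ts = make_ts(rng.standard_normal((4, 3000)))
        prep = tde_pca_prepare(ts, n_lags=15, n_components=20)
        evr = prep.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_too_many_components_rejected(self):
        ts = make_ts(np.random.default_rng(3).standard_normal((4, 3000)))
        with pytest.raises(ValueError, match="exceeds"):
            tde_pca_prepare(ts, n_lags=15, n_components=100)


class TestInference:
    def test_single_template_gives_constant_alpha(self):
        rng = np.random.default_rng(4)
        ts = make_ts(rng.standard_normal((4, int(30 * FS))))
        prep = tde_pca_prepare(ts, n_components=20)
        modes = infer_mode_mixing(prep, K=1, seed=0)
        assert np.array_equal(modes.alpha, np.ones_like(modes.alpha))

    def test_columns_on_simplex(self):
        rng = np.random.default_rng(5)
        ts = make_ts(rng.standard_normal((4, int(30 * FS))))
        prep = tde_pca_prepare(ts, n_components=20)
        modes = infer_mode_mixing(prep, K=3, seed=1)
        assert np.all(modes.alpha >= -1e-12)
        assert np.max(np.abs(modes.alpha.sum(axis=0) - 1)) < 1e-9

    def test_two_regime_switching_recovered(self):
        rng = np.random.default_rng(6)
        P, T = 6, int(60 * FS)
        A1, A2 = rng.standard_normal((P, P)), rng.standard_normal((P, P))
        L1 = np.linalg.cholesky(A1 @ A1.T / P + np.eye(P))
        L2 = np.linalg.cholesky(A2 @ A2.T / P + np.eye(P))
        regime = (np.arange(T) // int(5 * FS)) % 2
        W = rng.standard_normal((P, T))
        X = np.where(regime == 0, L1 @ W, L2 @ W)
        ts = make_ts(X)
        prep = tde_pca_prepare(ts, n_components=min(60, P * 15))
        modes = infer_mode_mixing(prep, K=2, seed=0)
        true_alpha = np.vstack([1.0 - regime, regime.astype(float)])
        off = (T - modes.alpha.shape[1]) // 2
        _, mc = match_modes(modes.alpha, true_alpha[:, off : off + modes.alpha.shape[1]])
        assert mc >= 0.9

    def test_too_many_modes_rejected(self):
        rng = np.random.default_rng(7)
        ts = make_ts(rng.standard_normal((4, int(6 * FS))))
        prep = tde_pca_prepare(ts, n_components=10)
        with pytest.raises(ValueError, match="exceeds the number of windows"):
            infer_mode_mixing(prep, K=50, seed=0)


class TestModeSpectra:
    def test_single_mode_reduces_to_welch(self):
        rng = np.random.default_rng(8)
        ts = make_ts(rng.standard_normal((3, int(60 * FS))))
        modes = ModeTimeCourses(np.ones((1, ts.n_samples)), FS)
        ms = mode_spectra(ts, modes)
        ps = welch_psd(ts)
        sel = ms.freqs > 0
        rel = np.abs(ms.psd[0][:, sel] - ps.psd[:, sel]) / ps.psd[:, sel]
        assert np.max(rel) < 0.02

    def test_two_modes_localize_spectral_peaks(self):
        rng = np.random.default_rng(9)
        T = int(120 * FS)
        alpha = simulate_mode_timecourses(2, T, FS, 1.0, None, seed=3)
        s1 = _bandlimited_source(T, FS, 10.0, 1.5, rng)
        s2 = _bandlimited_source(T, FS, 25.0, 1.5, rng)
        maps = np.array([[1, 1, 0.1, 0.1], [0.1, 0.1, 1, 1.0]])
        data = (
            maps[0][:, None] * (alpha[0] * s1)
            + maps[1][:, None] * (alpha[1] * s2)
            + 0.05 * rng.standard_normal((4, T))
        )
        ms = mode_spectra(make_ts(data), ModeTimeCourses(alpha, FS))
        peak0 = ms.freqs[np.argmax(ms.psd[0].mean(axis=0))]
        peak1 = ms.freqs[np.argmax(ms.psd[1].mean(axis=0))]
        assert peak0 == pytest.approx(10.0, abs=1.0)
        assert peak1 == pytest.approx(25.0, abs=1.0)

    def test_coherence_contract(self):
        rng = np.random.default_rng(10)
        ts = make_ts(rng.standard_normal((3, int(20 * FS))))
        alpha = simulate_mode_timecourses(2, ts.n_samples, FS, 0.5, None, seed=1)
        ms = mode_spectra(ts, ModeTimeCourses(alpha, FS))
        assert np.all(ms.coherence >= 0) and np.all(ms.coherence <= 1)
        for p in range(3):
            np.testing.assert_allclose(ms.coherence[:, p, p, :], 1.0)


class TestDynamicConnectedness:
    def _ms(self, coh):
        K, P, _, F = coh.shape
        return ModeSpectra(psd=np.ones((K, P, F)), coherence=coh, freqs=np.arange(F, dtype=float))

    def test_all_ones_coherence(self):
        coh = np.ones((2, 4, 4, 5))
        np.testing.assert_allclose(dynamic_parcel_connectedness(self._ms(coh)), 1.0)

    def test_identity_coherence(self):
        coh = np.zeros((2, 4, 4, 5))
        for p in range(4):
            coh[:, p, p, :] = 1.0
        np.testing.assert_allclose(dynamic_parcel_connectedness(self._ms(coh)), 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        raw = rng.uniform(0, 1, (2, 4, 4, 6))
        coh = (raw + raw.transpose(0, 2, 1, 3)) / 2
        for p in range(4):
            coh[:, p, p, :] = 1.0
        got = dynamic_parcel_connectedness(self._ms(coh))
        oracle = np.zeros((2, 4))
        for k in range(2):
            for p in range(4):
                vals = [coh[k, p, q, f] for q in range(4) if q != p for f in range(6)]
                oracle[k, p] = np.mean(vals)
        np.testing.assert_allclose(got, oracle, atol=1e-12)


class TestModeSummary:
    def test_complementary_modes_anticorrelated(self):
        a1 = simulate_mode_timecourses(2, 5000, FS, 0.2, None, seed=6)
        summ = mode_summary(ModeTimeCourses(a1, FS))
        assert summ.coactivation[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert summ.coactivation_per_mode[0] == pytest.approx(
            summ.coactivation_per_mode[1], abs=1e-12
        )

    def test_moments_match_direct_formula_oracle(self):
        rng = np.random.default_rng(12)
        K, T = 3, 4000
        alpha = simulate_mode_timecourses(K, T, FS, 0.3, None, seed=7)
        summ = mode_summary(ModeTimeCourses(alpha, FS))
        for k in range(K):
            x = alpha[k]
            assert summ.strength[k] == pytest.approx(x.mean(), abs=1e-10)
            assert summ.variability[k] == pytest.approx(x.std(), abs=1e-10)
            m2 = np.mean((x - x.mean()) ** 2)
            m4 = np.mean((x - x.mean()) ** 4)
            assert summ.concentration[k] == pytest.approx(m4 / m2**2 - 3, abs=1e-10)
            assert summ.concentration[k] == pytest.approx(
                kurtosis(x, fisher=True, bias=True), abs=1e-12
            )
        assert summ.strength.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_mode_flagged(self):
        alpha = np.vstack([np.full(100, 0.4), np.full(100, 0.6)])
        with pytest.warns(RuntimeWarning, match="constant"):
            summ = mode_summary(ModeTimeCourses(alpha, FS))
        assert summ.variability[0] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(summ.coactivation[0, 1])

    def test_mode_matching_identity(self):
        alpha = simulate_mode_timecourses(4, 3000, FS, 0.3, None, seed=8)
        perm, mc = match_modes(alpha[[2, 0, 3, 1]], alpha)
        np.testing.assert_array_equal(perm, [1, 3, 0, 2])
        assert mc == pytest.approx(1.0, abs=1e-12)
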