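"""OD/MBLL conversions, design construction, GLM fitting, contrast tests."""

import numpy as np
import pytest
from scipy import stats

from nirsroi.contrast import ContrastVector
from nirsroi.glm import (
    BeerLambertParams,
    ChannelGLM,
    ChannelTimeSeries,
    build_design,
    canonical_hrf,
    fit_glm,
    group_combine,
    intensity_to_od,
    mbll,
    roi_t_statistic,
)
from nirsroi.simulate import ar_noise


class TestIntensityToOD:
    def test_constant_signal_gives_zero(self):
        ts = ChannelTimeSeries(np.full((50, 3), 2.5), fs=4.0)
        od = intensity_to_od(ts)
        np.testing.assert_allclose(od.data, 0.0, atol=1e-15)
        assert od.unit == "od"

    def test_one_over_e_gives_unity(self):
        data = np.full((10, 1), 1.0)
        data[4, 0] = np.exp(-1.0)
        od = intensity_to_od(ChannelTimeSeries(data, fs=1.0), baseline=np.array([1.0]))
        assert od.data[4, 0] == pytest.approx(1.0)

    def test_mean_baseline_small_fluctuations_near_zero_mean(self, rng):
        data = 1.0 + 0.01 * rng.standard_normal((2000, 4))
        od = intensity_to_od(ChannelTimeSeries(data, fs=4.0))
        assert np.abs(od.data.mean(axis=0)).max() < 1e-4

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            intensity_to_od(ChannelTimeSeries(np.array([[1.0], [-1.0]]), fs=1.0))


class TestMBLL:
    params = BeerLambertParams(
        distance=25.0,
        dpf=(6.0, 6.0),
        extinction=np.array([[1.4866, 3.8437], [2.5264, 1.7986]]) * 1e-3,
    )

    def test_zero_od_gives_zero_concentrations(self):
        zero = ChannelTimeSeries(np.zeros((20, 2)), fs=4.0, unit="od")
        hbo, hbr = mbll(zero, zero, self.params)
        np.testing.assert_allclose(hbo.data, 0.0)
        np.testing.assert_allclose(hbr.data, 0.0)

    def test_forward_inverse_roundtrip(self, rng):
        hbo_true = rng.standard_normal((30, 2))
        hbr_true = rng.standard_normal((30, 2))
        eps = np.asarray(self.params.extinction)
        lpath = self.params.distance * np.asarray(self.params.dpf)
        od1 = lpath[0] * (eps[0, 0] * hbo_true + eps[0, 1] * hbr_true)
        od2 = lpath[1] * (eps[1, 0] * hbo_true + eps[1, 1] * hbr_true)
        hbo, hbr = mbll(
            ChannelTimeSeries(od1, 4.0, unit="od"),
            ChannelTimeSeries(od2, 4.0, unit="od"),
            self.params,
        )
        np.testing.assert_allclose(hbo.data, hbo_true, rtol=1e-10)
        np.testing.assert_allclose(hbr.data, hbr_true, rtol=1e-10)

    def test_pathlength_scaling(self, rng):
        od = ChannelTimeSeries(rng.standard_normal((20, 1)), 4.0, unit="od")
        hbo1, _ = mbll(od, od, self.params)
        double = BeerLambertParams(
            distance=2 * self.params.distance,
            dpf=self.params.dpf,
            extinction=self.params.extinction,
        )
        hbo2, _ = mbll(od, od, double)
        np.testing.assert_allclose(hbo2.data, hbo1.data / 2.0, rtol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError):
            BeerLambertParams(
                distance=25.0, dpf=(6.0, 6.0), extinction=np.ones((2, 2))
            )


class TestDesign:
    def test_no_onsets_gives_intercept_only(self):
        X, names = build_design(np.array([]), 2.0, 100, 4.0)
        assert names == ["intercept"]
        np.testing.assert_allclose(X, 1.0)

    def test_single_impulse_reproduces_hrf(self):
        fs = 4.0
        X, names = build_design(np.array([10.0]), 1.0 / fs, 400, fs)
        hrf = canonical_hrf(np.arange(0, 32, 1.0 / fs))
        got = X[40 : 40 + len(hrf), 0]
        np.testing.assert_allclose(got, hrf[: len(got)], atol=1e-12)

    def test_superposition_of_two_events(self):
        fs = 4.0
        X2, _ = build_design(np.array([10.0, 60.0]), 0.25, 400, fs)
        Xa, _ = build_design(np.array([10.0]), 0.25, 400, fs)
        Xb, _ = build_design(np.array([60.0]), 0.25, 400, fs)
        np.testing.assert_allclose(X2[:, 0], Xa[:, 0] + Xb[:, 0], atol=1e-12)

    def test_multiple_conditions(self):
        X, names = build_design(
            {"a": np.array([5.0]), "b": np.array([20.0])}, 2.0, 200, 4.0
        )
        assert names == ["a", "b", "intercept"]
        assert X.shape == (200, 3)


class TestChannelGLM:
    def _design(self, n=400, fs=4.0):
        onsets = np.arange(10.0, n / fs - 20.0, 25.0)
        return build_design(onsets, 2.0, n, fs)

    def test_noiseless_exact_recovery(self):
        X, names = self._design()
        beta_true = np.array([[2.0, 0.3], [-1.0, 0.1], [0.0, -0.2]])  # (C, k)
        Y = X @ beta_true.T
        res = fit_glm(Y, X, noise_model="iid", design_names=names)
        np.testing.assert_allclose(res.beta, beta_true, atol=1e-10)

    def test_iid_covariance_closed_form(self, rng):
        X, names = self._design()
        Y = rng.standard_normal((X.shape[0], 2))
        res = fit_glm(Y, X, noise_model="iid", design_names=names)
        xtx_inv = np.linalg.inv(X.T @ X)
        for c in range(2):
            resid = Y[:, c] - X @ res.beta[c]
            s2 = resid @ resid / (X.shape[0] - X.shape[1])
            np.testing.assert_allclose(res.cov_beta[c], s2 * xtx_inv, rtol=1e-10)

    def test_prewhitening_beats_naive_ols_variance(self, rng):
        # AR(1) noise: prewhitened estimates have smaller sampling variance
        X, names = self._design(n=300)
        betas_ar, betas_ols = [], []
        for _ in range(400):
            noise = ar_noise(300, 1, np.array([0.7]), 1.0, rng)
            Y = noise
            betas_ar.append(
                fit_glm(Y, X, noise_model="ar", ar_order=1, design_names=names).beta[0, 0]
            )
            betas_ols.append(
                fit_glm(Y, X, noise_model="iid", design_names=names).beta[0, 0]
            )
        assert np.var(betas_ar) < np.var(betas_ols)

    def test_rank_deficient_rejected(self):
        X = np.ones((50, 2))
        with pytest.raises(ValueError):
            ChannelGLM(np.zeros((50, 1)), X)

    def test_summary_table_shape(self, rng):
        X, names = self._design()
        res = fit_glm(rng.standard_normal((400, 3)), X, design_names=names)
        table = res.summary()
        assert set(table.columns) >= {"channel", "condition", "beta", "se", "t", "p"}
        assert len(table) == 3  # 3 channels x 1 task condition


class TestContrastTest:
    channels = (("S1", "D1"), ("S2", "D1"), ("S2", "D2"))

    def _results(self, rng):
        onsets = np.arange(10.0, 80.0, 25.0)
        X, names = build_design(onsets, 2.0, 400, 4.0)
        Y = np.outer(X[:, 0], [1.0, 0.5, 0.0]) + 0.5 * rng.standard_normal((400, 3))
        return fit_glm(Y, X, noise_model="iid", design_names=names)

    def test_scale_invariance(self, rng):
        res = self._results(rng)
        c = ContrastVector(np.array([0.6, 0.3, 0.1]), self.channels)
        c2 = ContrastVector(np.array([6.0, 3.0, 1.0]), self.channels)
        a, b = res.t_contrast(c), res.t_contrast(c2)
        assert a.t == pytest.approx(b.t, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_one_hot_equals_single_channel_t(self, rng):
        res = self._results(rng)
        c = ContrastVector(np.array([0.0, 1.0, 0.0]), self.channels)
        got = res.t_contrast(c)
        beta = res.beta[1, 0]
        se = np.sqrt(res.cov_beta[1, 0, 0])
        assert got.t == pytest.approx(beta / se, rel=1e-12)

    def test_all_zero_contrast_gives_unity_p(self, rng):
        res = self._results(rng)
        c = ContrastVector(np.zeros(3), self.channels)
        out = roi_t_statistic(res, c)
        assert out.t == 0.0
        assert out.p == 1.0

    def test_dimension_mismatch_rejected(self, rng):
        res = self._results(rng)
        with pytest.raises(ValueError):
            res.t_contrast(np.ones(7))

    def test_null_pvalues_uniform(self, rng):
        # iid noise, zero effect: p-values over reps are Uniform(0, 1)
        onsets = np.arange(5.0, 40.0, 12.0)
        X, names = build_design(onsets, 2.0, 200, 4.0)
        c = ContrastVector(np.array([0.5, 0.3, 0.2]), self.channels)
        pvals = []
        for _ in range(1000):
            Y = rng.standard_normal((200, 3))
            res = fit_glm(Y, X, noise_model="iid", design_names=names)
            pvals.append(res.t_contrast(c).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGroupCombine:
    def test_single_subject_identity(self, rng):
        onsets = np.arange(10.0, 80.0, 25.0)
        X, names = build_design(onsets, 2.0, 300, 4.0)
        res = fit_glm(rng.standard_normal((300, 1)), X, noise_model="iid",
                      design_names=names)
        r = res.t_contrast(np.array([1.0]))
        g = group_combine([r])
        assert g.effect == pytest.approx(r.effect)
        assert g.se == pytest.approx(r.se)

    def test_identical_subjects_shrink_se(self):
        subj = [(2.0, 0.5, 100.0)] * 4
        g = group_combine(subj)
        assert g.effect == pytest.approx(2.0)
        assert g.se == pytest.approx(0.5 / 2.0)
        assert g.dof == pytest.approx(400.0)

    def test_matches_weighted_least_squares(self, rng):
        eff = rng.normal(1.0, 0.3, size=6)
        se = rng.uniform(0.2, 1.5, size=6)
        g = group_combine([(e, s, 50.0) for e, s in zip(eff, se)])
        # stacked WLS: minimize sum ((eff_i - mu) / se_i)^2
        w = 1.0 / se**2
        mu = np.sum(w * eff) / np.sum(w)
        assert g.effect == pytest.approx(mu, rel=1e-12)
        assert g.se == pytest.approx(1.0 / np.sqrt(np.sum(w)), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            group_combine([(1.0, 0.0, 10.0)])

    def test_random_effects_widens_se_under_heterogeneity(self):
        subj = [(0.0, 0.3, 50.0), (3.0, 0.3, 50.0), (-2.0, 0.3, 50.0)]
        fixed = group_combine(subj, method="fixed")
        random = group_combine(subj, method="random")
        assert random.se > fixed.se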