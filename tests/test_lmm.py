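"""Spatial LMM fitting: likelihood correctness, tests, model comparison."""

import numpy as np
import pytest
from scipy import stats

from geozinc import (MaternParams, compare_models, fit_lmm, loglik_at, lrt,
                     profile_kappa, variogram_of, wald)
from geozinc.matern import build_covariance
from conftest import simulate_gaussian_response


class TestLikelihoodOracle:
    def test_ml_loglik_equals_mvn_density_small_n(self):
        # on tiny data the ML objective must equal a generic multivariate
        # normal log-density with beta profiled out by explicit GLS
        rng = np.random.default_rng(12)
        for n in (6, 8, 10):
            locs = rng.uniform(0, 20, size=(n, 2))
            X = np.c_[np.ones(n), rng.normal(size=n)]
            y = rng.normal(size=n) * 2 + 5
            params = MaternParams(1.3, 2.2, 6.0, 1.0)
            C = build_covariance(locs, params)
            Ci = np.linalg.inv(C)
            beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
            oracle = stats.multivariate_normal(mean=X @ beta, cov=C).logpdf(y)
            ll, _, _ = loglik_at(locs, X, y, params, method="ML")
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_optimum_beats_random_admissible_points(self):
        # n=8 toy: the optimised ML loglik must top 50 random parameter draws
        rng = np.random.default_rng(3)
        n = 8
        locs = rng.uniform(0, 10, size=(n, 2))
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        fit = fit_lmm(locs, X, y, kappa=1.0, method="ML")
        for _ in range(50):
            params = MaternParams(tau2=rng.uniform(0.01, 5),
                                  sigma2=rng.uniform(0.01, 5),
                                  phi=rng.uniform(0.5, 30), kappa=1.0)
            C = build_covariance(locs, params)
            Ci = np.linalg.inv(C)
            beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
            ll = stats.multivariate_normal(mean=X @ beta, cov=C).logpdf(y)
            assert fit.loglik >= ll - 1e-6

    def test_gls_consistency_of_beta(self, small_survey):
        # beta-hat reported by the fit equals the closed-form GLS solution
        # at the fitted covariance
        locs, X, y = small_survey
        fit = fit_lmm(locs, X, y, kappa=1.0, method="ML")
        C = build_covariance(locs, fit.matern)
        Ci = np.linalg.inv(C)
        beta_gls = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert np.allclose(fit.beta, beta_gls, atol=1e-6)


class TestFitting:
    def test_pure_nugget_data_recovers_small_sigma2(self):
        rng = np.random.default_rng(21)
        n = 500
        locs = rng.uniform(0, 100, size=(n, 2))
        X = np.c_[np.ones(n)]
        y = 7.0 + 2.0 * rng.standard_normal(n)  # tau2 = 4, no spatial signal
        fit = fit_lmm(locs, X, y, kappa=1.0, method="ML")
        assert fit.matern.sigma2 < 0.1 * fit.matern.tau2
        se = fit.beta_se()[0]
        assert abs(fit.beta[0] - 7.0) < 2 * se

    def test_reml_and_ml_agree_at_large_n(self, survey_params):
        # with p = 2 fixed effects and n = 1000 the REML bias correction is
        # tiny: nugget estimates agree closely, and the fitted variograms
        # coincide over the sampled distance range.  (sigma2 and phi
        # individually sit on the well-known flat Matérn ridge, so they are
        # compared through the variogram they imply, not one-to-one.)
        rng = np.random.default_rng(31)
        n = 1000
        locs = np.c_[rng.uniform(0, 150, n), rng.uniform(0, 250, n)]
        X = np.c_[np.ones(n), locs[:, 0] - locs[:, 0].mean()]
        y = simulate_gaussian_response(locs, survey_params, rng, mean=X @ [10, 0.02])
        ml = fit_lmm(locs, X, y, kappa=1.0, method="ML")
        reml = fit_lmm(locs, X, y, kappa=1.0, method="REML")
        assert reml.matern.tau2 == pytest.approx(ml.matern.tau2, rel=0.05)
        h = np.linspace(1.0, 120.0, 60)
        _, g_ml = variogram_of(ml, distances=h)
        _, g_reml = variogram_of(reml, distances=h)
        assert np.max(np.abs(g_ml - g_reml)) / ml.matern.sill < 0.10

    def test_rank_deficient_design_rejected(self, small_survey):
        locs, X, y = small_survey
        X_bad = np.c_[X, X[:, 1]]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(locs, X_bad, y)


class TestKappaProfiling:
    def test_singleton_grid_returns_it(self, small_survey):
        locs, X, y = small_survey
        best, fits = profile_kappa(locs, X, y, kappa_grid=[1.5], method="ML")
        assert best == 1.5 and set(fits) == {1.5}

    def test_best_kappa_maximises_loglik_on_grid(self, small_survey):
        locs, X, y = small_survey
        best, fits = profile_kappa(locs, X, y, kappa_grid=[0.5, 1.0, 2.0])
        assert all(fits[best].loglik >= f.loglik for f in fits.values())

    def test_modal_selection_recovers_true_smoothness(self):
        # exponential-truth data should pick kappa=0.5 from a coarse grid in
        # most replicates
        truth = MaternParams(tau2=1.0, sigma2=4.0, phi=15.0, kappa=0.5)
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(400 + rep)
            n = 400
            locs = np.c_[rng.uniform(0, 90, n), rng.uniform(0, 160, n)]
            X = np.ones((n, 1))
            y = simulate_gaussian_response(locs, truth, rng, mean=12.0)
            best, _ = profile_kappa(locs, X, y, kappa_grid=[0.5, 1.5, 2.5])
            hits += best == 0.5
        assert hits > reps / 2

    def test_empty_grid_rejected(self, small_survey):
        locs, X, y = small_survey
        with pytest.raises(ValueError):
            profile_kappa(locs, X, y, kappa_grid=[])


class TestLRT:
    def test_identical_fits_give_zero(self, small_survey):
        locs, X, y = small_survey
        fit = fit_lmm(locs, X, y, fixed_effect_names=["intercept", "easting"])
        res = lrt(fit, fit)
        assert res.L == 0.0 and res.p_value == 1.0

    def test_chi2_quantile_identity(self):
        # L = 3.841 on 1 df sits exactly at p = 0.05
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_reml_fits_refused(self, small_survey):
        locs, X, y = small_survey
        f0 = fit_lmm(locs, X, y, fixed_effect_names=["i", "e"], method="REML")
        f1 = fit_lmm(locs, X, y, fixed_effect_names=["i", "e"], method="REML")
        with pytest.raises(ValueError, match="REML"):
            lrt(f0, f1)

    def test_type_i_error_calibration(self, survey_params):
        # appending a pure-noise covariate to the true model: P(p <= 0.05)
        # should sit near 0.05 over replicates
        reps = 200
        hits = 0
        for rep in range(reps):
            rng = np.random.default_rng(7000 + rep)
            n = 60
            locs = rng.uniform(0, 60, size=(n, 2))
            X0 = np.ones((n, 1))
            y = simulate_gaussian_response(locs, survey_params, rng, mean=10.0)
            X1 = np.c_[X0, rng.standard_normal(n)]
            f0 = fit_lmm(locs, X0, y, fixed_effect_names=["i"],
                         xatol=1e-3, fatol=1e-6)
            f1 = fit_lmm(locs, X1, y, fixed_effect_names=["i", "z"],
                         starts=[(f0.matern.tau2 / max(f0.matern.sigma2, 1e-6),
                                  f0.matern.phi)],
                         xatol=1e-3, fatol=1e-6)
            hits += lrt(f0, f1).p_value <= 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 3 * se
        assert rate >= 0.05 - 3 * se - 0.02  # mild undershoot tolerated


class TestWald:
    def test_zero_coefficient_gives_p_one(self, small_survey):
        locs, X, y = small_survey
        fit = fit_lmm(locs, X, y, fixed_effect_names=["intercept", "easting"])
        fit.beta[1] = 0.0
        W, p = wald(fit, "easting")
        assert W == 0.0 and p == 1.0

    def test_z_1_96_gives_p_05(self, small_survey):
        locs, X, y = small_survey
        fit = fit_lmm(locs, X, y, fixed_effect_names=["intercept", "easting"])
        se = fit.beta_se()[1]
        fit.beta[1] = 1.96 * se
        _, p = wald(fit, "easting")
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_agrees_with_lrt_within_factor_two(self, survey_params):
        rng = np.random.default_rng(55)
        n = 300
        locs = np.c_[rng.uniform(0, 90, n), rng.uniform(0, 150, n)]
        x = rng.standard_normal(n)
        X1 = np.c_[np.ones(n), x]
        y = simulate_gaussian_response(locs, survey_params, rng,
                                       mean=10 + 0.8 * x)
        f0 = fit_lmm(locs, X1[:, :1], y, fixed_effect_names=["i"])
        f1 = fit_lmm(locs, X1, y, fixed_effect_names=["i", "x"])
        p_lrt = lrt(f0, f1).p_value
        _, p_wald = wald(f1, "x")
        assert p_lrt == pytest.approx(p_wald, rel=1.0) or (p_lrt < 1e-4 and p_wald < 1e-4)

    def test_unknown_coefficient_rejected(self, small_survey):
        locs, X, y = small_survey
        fit = fit_lmm(locs, X, y, fixed_effect_names=["intercept", "easting"])
        with pytest.raises(KeyError):
            wald(fit, "nope")


class TestModelSummaries:
    def test_variogram_of_fit_endpoints(self, small_survey):
        locs, X, y = small_survey
        fit = fit_lmm(locs, X, y)
        h, g = variogram_of(fit, distances=np.array([1e-9, 1e5]))
        assert g[0] == pytest.approx(fit.matern.tau2, rel=1e-3)
        assert g[1] == pytest.approx(fit.matern.sill, rel=1e-9)

    def test_variogram_sill_arithmetic(self):
        # nugget 4.995 + partial sill 3.277 gives an 8.272 sill
        params = MaternParams(4.995, 3.277, 21.123, 1.01)
        h, g = variogram_of(
            type("F", (), {"matern": params})(), distances=np.array([1e5]))
        assert g[0] == pytest.approx(8.272, abs=1e-3)

    def test_identical_models_give_zero_r2(self):
        m = MaternParams(5.0, 3.3, 21.0, 1.0)
        c = compare_models(m, m)
        assert c.r2_adj == 0.0 and c.r2_adj_c == 0.0

    def test_r2_adj_c_reproduces_printed_precision(self):
        # variance components of the fitted soil and environmental models
        null = MaternParams(4.995, 3.277, 21.123, 1.01)
        soil = MaternParams(4.596, 3.051, 20.867, 1.01)
        env = MaternParams(5.008, 1.564, 15.592, 1.01)
        assert round(compare_models(null, soil).r2_adj_c, 3) == 0.069
        assert round(compare_models(null, env).r2_adj_c, 3) == 0.523

    def test_zero_null_sigma2_reports_missing(self):
        null = MaternParams(5.0, 0.0, 21.0, 1.0)
        other = MaternParams(4.0, 0.0, 21.0, 1.0)
        assert compare_models(null, other).r2_adj_c is None
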