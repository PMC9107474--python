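"""Kriging identities, the universal-kriging oracle, LOO calibration, median CI."""

import numpy as np
import pytest
from scipy import stats

from geozinc import MaternParams, SpatialLMMFit, eblup, loo_cross_validate, median_sspe_ci
from geozinc.matern import build_covariance, matern_correlation, pairwise_distances
from conftest import simulate_gaussian_response


def _fit_for(params, n, names=("i",)):
    return SpatialLMMFit(beta=np.zeros(len(names)), fixed_effect_names=list(names),
                         matern=params, loglik=0.0, method="REML", n=n)


class TestEblupIdentities:
    def test_exact_interpolation_without_nugget(self):
        rng = np.random.default_rng(2)
        n = 25
        locs = rng.uniform(0, 30, size=(n, 2))
        X = np.ones((n, 1))
        params = MaternParams(0.0, 3.0, 10.0, 1.0)
        y = simulate_gaussian_response(locs, params, rng, mean=4.0)
        fit = _fit_for(params, n)
        res = eblup(fit, locs, X, y, locs[:5], X[:5])
        assert np.allclose(res.eblup, y[:5], atol=1e-6)
        assert np.allclose(res.pev, 0.0, atol=1e-6)

    def test_pure_nugget_reduces_to_gls_surface(self):
        rng = np.random.default_rng(3)
        n = 60
        locs = rng.uniform(0, 50, size=(n, 2))
        x = rng.standard_normal(n)
        X = np.c_[np.ones(n), x]
        y = 2 + 3 * x + rng.standard_normal(n)
        params = MaternParams(1.0, 0.0, 10.0, 1.0)
        fit = _fit_for(params, n, names=("i", "x"))
        targets = rng.uniform(0, 50, size=(10, 2))
        X0 = np.c_[np.ones(10), rng.standard_normal(10)]
        res = eblup(fit, locs, X, y, targets, X0)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)  # GLS = OLS here
        assert np.allclose(res.eblup, X0 @ beta_ols, atol=1e-8)

    def test_six_point_toy_matches_explicit_kriging_algebra(self):
        # assemble the universal-kriging equations by hand and compare
        locs = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [2, 1], [1, 3]], float)
        X = np.c_[np.ones(6), locs[:, 0]]
        y = np.array([3.0, 5.0, 4.0, 6.5, 4.2, 3.8])
        params = MaternParams(0.8, 2.5, 3.0, 1.5)
        target = np.array([[2.0, 2.0]])
        x0 = np.array([[1.0, 2.0]])

        C = build_covariance(locs, params)
        h = np.hypot(*(locs - target[0]).T)
        c = params.sigma2 * matern_correlation(h, 3.0, 1.5)
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        pred_expect = x0[0] @ beta + c @ Ci @ (y - X @ beta)
        d = x0[0] - X.T @ Ci @ c
        pev_expect = (params.tau2 + params.sigma2 - c @ Ci @ c
                      + d @ np.linalg.solve(X.T @ Ci @ X, d))

        res = eblup(_fit_for(params, 6, names=("i", "e")), locs, X, y, target, x0)
        assert res.eblup[0] == pytest.approx(pred_expect, abs=1e-10)
        assert res.pev[0] == pytest.approx(pev_expect, abs=1e-10)

    def test_missing_target_covariates_rejected(self):
        locs = np.random.default_rng(0).uniform(0, 10, size=(30, 2))
        X = np.ones((30, 1))
        y = np.zeros(30)
        fit = _fit_for(MaternParams(1, 1, 5, 1), 30)
        with pytest.raises(ValueError, match="missing"):
            eblup(fit, locs, X, y, locs[:2], np.array([[1.0], [np.nan]]))

    def test_pev_scales_with_response_variance(self):
        rng = np.random.default_rng(9)
        n = 40
        locs = rng.uniform(0, 40, size=(n, 2))
        X = np.ones((n, 1))
        params = MaternParams(2.0, 3.0, 12.0, 1.0)
        y = simulate_gaussian_response(locs, params, rng)
        targets = rng.uniform(0, 40, size=(5, 2))
        X0 = np.ones((5, 1))
        base = eblup(_fit_for(params, n), locs, X, y, targets, X0)
        k = 4.0
        scaled_params = MaternParams(k * 2.0, k * 3.0, 12.0, 1.0)
        scaled = eblup(_fit_for(scaled_params, n), locs, X, np.sqrt(k) * y,
                       targets, X0)
        assert np.allclose(scaled.pev, k * base.pev, rtol=1e-8)
        # translation invariance of pev
        shifted = eblup(_fit_for(params, n), locs, X, y + 100, targets, X0)
        assert np.allclose(shifted.pev, base.pev, rtol=1e-10)

    def test_far_field_pev_approaches_total_variance_plus_drift(self):
        rng = np.random.default_rng(4)
        n = 50
        locs = rng.uniform(0, 20, size=(n, 2))
        X = np.ones((n, 1))
        params = MaternParams(2.0, 3.0, 5.0, 1.0)
        y = simulate_gaussian_response(locs, params, rng)
        res = eblup(_fit_for(params, n), locs, X, y,
                    np.array([[5000.0, 5000.0]]), np.ones((1, 1)))
        assert res.pev[0] >= params.sill  # sill plus drift uncertainty


class TestLooCrossValidation:
    def test_sspe_scaling_contract(self, survey_params):
        rng = np.random.default_rng(11)
        n = 60
        locs = rng.uniform(0, 60, size=(n, 2))
        X = np.c_[np.ones(n)]
        y = simulate_gaussian_response(locs, survey_params, rng, mean=10.0)
        rec, _ = loo_cross_validate(_fit_for(survey_params, n), locs, X, y)
        # inflating all variances 10x shrinks every SSPE 10x up to the small
        # change in kriging weights; check the dominant scaling on pev
        inflated = MaternParams(10 * survey_params.tau2, 10 * survey_params.sigma2,
                                survey_params.phi, survey_params.kappa)
        rec10, _ = loo_cross_validate(_fit_for(inflated, n), locs, X, y)
        assert np.allclose(rec10["loo_pev"], 10 * rec["loo_pev"], rtol=1e-8)
        assert np.allclose(rec10["sspe"], rec["sspe"] / 10, rtol=1e-8)

    def test_minimum_size_enforced(self, survey_params):
        with pytest.raises(ValueError):
            loo_cross_validate(_fit_for(survey_params, 5),
                               np.random.rand(5, 2), np.ones((5, 1)),
                               np.zeros(5))

    def test_mean_sspe_near_one_under_true_model(self, survey_params):
        # one small self-consistent replicate; the pooled acceptance check
        # runs the full-scale version
        rng = np.random.default_rng(14)
        n = 120
        locs = np.c_[rng.uniform(0, 70, n), rng.uniform(0, 120, n)]
        X = np.c_[np.ones(n), locs[:, 0] - locs[:, 0].mean()]
        y = simulate_gaussian_response(locs, survey_params, rng, mean=X @ [10, 0.02])
        _, s = loo_cross_validate(_fit_for(survey_params, n, names=("i", "e")),
                                  locs, X, y)
        assert s.mean_sspe == pytest.approx(1.0, abs=0.45)


class TestMedianSspeCI:
    def test_survey_size_interval_matches_reference(self):
        lo, hi = median_sspe_ci(1600)
        assert round(lo, 2) == 0.40
        assert round(hi, 2) == 0.51

    def test_limits_shrink_to_chi2_median(self):
        lo, hi = median_sspe_ci(10 ** 8)
        med = stats.chi2.ppf(0.5, 1)
        assert lo == pytest.approx(med, abs=1e-3)
        assert hi == pytest.approx(med, abs=1e-3)
        assert lo < med < hi

    def test_n100_matches_explicit_rank_computation(self):
        # exact binomial rank bounds mapped through the chi2_1 quantile
        n, level = 100, 0.95
        k = np.arange(n + 1)
        cdf = stats.binom.cdf(k, n, 0.5)
        lo_rank = int(np.searchsorted(cdf, 0.025))
        hi_rank = int(np.searchsorted(cdf, 0.975)) + 1
        lo_expect = stats.chi2.ppf(lo_rank / n, 1)
        hi_expect = stats.chi2.ppf(min(hi_rank, n) / n, 1)
        lo, hi = median_sspe_ci(n, exact=True)
        assert lo == pytest.approx(lo_expect, abs=1e-12)
        assert hi == pytest.approx(hi_expect, abs=1e-12)
        # the default normal approximation lands close to the exact answer
        lo_a, hi_a = median_sspe_ci(n)
        assert lo_a == pytest.approx(lo_expect, abs=0.06)
        assert hi_a == pytest.approx(hi_expect, abs=0.06)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            median_sspe_ci(10)
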