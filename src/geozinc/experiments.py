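"""Reusable simulation studies: calibration, error control, recovery.

These drivers exercise the whole stack under known truths and are what the
analysis scripts and the validation suite run.  Problem sizes default to
desk scale: cross-validation calibration pools ten n=400 surveys,
false-discovery control uses five hundred n=200 surveys, and parameter
recovery refits twenty n=400 surveys over a smoothness grid.  All
randomness flows from a single integer seed.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .lmm import SpatialLMMFit, fit_lmm, profile_kappa
from .matern import MaternParams, build_covariance, cholesky_lower
from .prediction import loo_cross_validate
from .selection import RankedPredictors, sequential_select
from .synthetic import DesignSpec, generate_design

# survey-scale random effects: nugget 5, partial sill 3.3, phi 21 km
SURVEY_TRUTH = MaternParams(tau2=5.0, sigma2=3.3, phi=21.0, kappa=1.0)

# a quarter-area version of the full survey domain, keeping the sampling
# density of ~1600 points over 180 x 620 km
QUARTER_EXTENT = (0.0, 90.0, 0.0, 310.0)


def _survey_draw(seed: int, n_main: int = 360, n_close_pairs: int = 40,
                 extent=QUARTER_EXTENT, truth: MaternParams = SURVEY_TRUTH,
                 beta=(10.0, 0.02)):
    """One coverage-design dataset with an easting trend and LMM noise."""
    locs = generate_design(DesignSpec(n_main=n_main, n_close_pairs=n_close_pairs,
                                      extent=extent, close_pair_offset=1.0,
                                      seed=seed))
    rng = np.random.default_rng(seed)
    n = len(locs)
    X = np.c_[np.ones(n), locs[:, 0] - locs[:, 0].mean()]
    L = cholesky_lower(build_covariance(locs, truth))
    y = X @ np.asarray(beta) + L @ rng.standard_normal(n)
    return locs, X, y


def xval_calibration(n_reps: int = 10, seed: int = 0,
                     truth: MaternParams = SURVEY_TRUTH, **draw_kw) -> dict:
    """SSPE calibration of leave-one-out cross-validation under the truth.

    Simulates ``n_reps`` surveys from the spatial LMM and cross-validates
    each holding the covariance parameters at their true values, so any
    departure of the pooled mean SSPE from 1 (or the median from the
    chi-square(1) median 0.455) indicates a defect in the kriging system,
    not in estimation.
    """
    sspes = []
    for rep in range(n_reps):
        locs, X, y = _survey_draw(seed + rep, truth=truth, **draw_kw)
        fit = SpatialLMMFit(beta=np.zeros(X.shape[1]),
                            fixed_effect_names=[f"x{j}" for j in range(X.shape[1])],
                            matern=truth, loglik=0.0, method="REML", n=len(y))
        records, _ = loo_cross_validate(fit, locs, X, y)
        sspes.append(records["sspe"].to_numpy())
    pooled = np.concatenate(sspes)
    return {
        "mean_sspe": float(pooled.mean()),
        "median_sspe": float(np.median(pooled)),
        "n_folds": int(pooled.size),
        "n_reps": n_reps,
    }


def fdr_global_null(n_datasets: int = 500, n: int = 200, n_noise: int = 9,
                    alpha: float = 0.05, seed: int = 0,
                    truth: MaternParams = SURVEY_TRUTH) -> dict:
    """False-retention rate of sequential selection under the global null.

    Each dataset has a spatially correlated response (easting trend + Matérn
    field + nugget) and ``n_noise`` candidate predictors of pure noise,
    tested in a fixed ranking.  The proportion of datasets retaining at
    least one predictor estimates the procedure's family-level error, which
    alpha-investing holds at ``alpha``.
    """
    names = tuple(f"noise{j}" for j in range(n_noise))
    ranked = RankedPredictors(names, group="global-null")
    n_false = 0
    n_retained_total = 0
    for d in range(n_datasets):
        rng = np.random.default_rng(seed + 10_000 + d)
        locs = rng.uniform(0.0, 100.0, size=(n, 2))
        X0 = np.c_[np.ones(n), locs[:, 0] - locs[:, 0].mean()]
        L = cholesky_lower(build_covariance(locs, truth))
        y = X0 @ [10.0, 0.02] + L @ rng.standard_normal(n)
        cands = pd.DataFrame(rng.standard_normal((n, n_noise)), columns=names)
        res = sequential_select(locs, X0, y, cands, ranked, alpha=alpha,
                                kappa=truth.kappa)
        n_false += len(res.retained) > 0
        n_retained_total += len(res.retained)
    rate = n_false / n_datasets
    return {
        "false_retention_rate": float(rate),
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_datasets)),
        "mean_false_discoveries": n_retained_total / n_datasets,
        "n_datasets": n_datasets,
    }


def parameter_recovery(n_reps: int = 20, seed: int = 0,
                       truth: MaternParams = SURVEY_TRUTH,
                       kappa_grid=(0.5, 1.0, 2.0), **draw_kw) -> dict:
    """Variance-parameter recovery and smoothness selection under the truth.

    Each replicate profiles the Matérn smoothness over ``kappa_grid`` by ML;
    nugget and partial-sill bias are summarised at the true smoothness
    (which must be on the grid), and the modal selected smoothness is
    reported alongside.
    """
    if truth.kappa not in kappa_grid:
        raise ValueError("true kappa must be on the profiling grid")
    tau2s, sigma2s, selected = [], [], []
    for rep in range(n_reps):
        locs, X, y = _survey_draw(seed + 100 + rep, truth=truth, **draw_kw)
        best, fits = profile_kappa(locs, X, y, kappa_grid=kappa_grid, method="ML")
        selected.append(best)
        fit_true_kappa = fits[truth.kappa]
        tau2s.append(fit_true_kappa.matern.tau2)
        sigma2s.append(fit_true_kappa.matern.sigma2)
    counts = Counter(selected)
    return {
        "mean_tau2": float(np.mean(tau2s)),
        "mean_sigma2": float(np.mean(sigma2s)),
        "tau2_bias": float(np.mean(tau2s) / truth.tau2 - 1.0),
        "sigma2_bias": float(np.mean(sigma2s) / truth.sigma2 - 1.0),
        "modal_kappa": float(counts.most_common(1)[0][0]),
        "kappa_counts": {str(k): v for k, v in sorted(counts.items())},
        "n_reps": n_reps,
    }
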