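"""Sequential covariate selection with FDR control by alpha-investing.

Candidate predictors arrive in an a-priori expert ranking (never derived
from the response).  Starting from a null model (intercept + easting
trend) fitted by ML, each predictor in turn is added to the working model
and tested with a one-degree-of-freedom likelihood-ratio test:

1. screen — if p > alpha the predictor is dropped; otherwise it is
   provisionally retained and stays in the working model for later tests;
2. invest — after the pass, each test's p-value is compared with its
   alpha-investing threshold.  The alpha-wealth starts at alpha*(1-alpha),
   is spent on every test (accepted nulls charge alpha_j/(1-alpha_j)) and
   is replenished by alpha on every rejection; the spend at test j is the
   current wealth divided by (1 + j - r_j), with r_j the index of the most
   recent rejection.  Provisionally retained predictors whose p-value also
   falls below the threshold are definitively retained.

The final model (null effects + definitively retained) is refitted by REML,
the preferred basis for prediction.  This scheme controls the false
discovery rate over the ordered stream of hypotheses while concentrating
power on the front of the ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import SpatialLMMFit, fit_lmm, lrt

__all__ = [
    "InvestingRule",
    "RankedPredictors",
    "TestRecord",
    "SelectionResult",
    "alpha_investing_thresholds",
    "sequential_select",
]


@dataclass(frozen=True)
class InvestingRule:
    """Constants of the alpha-investing wealth dynamics, all configurable.

    initial_wealth_factor
        W0 = factor * alpha; default (1 - alpha) gives W0 = alpha(1-alpha).
    payout
        Wealth earned on each rejection; default alpha.
    """

    initial_wealth_factor: float | None = None  # None -> (1 - alpha)
    payout: float | None = None  # None -> alpha

    def initial_wealth(self, alpha: float) -> float:
        f = self.initial_wealth_factor if self.initial_wealth_factor is not None else (1 - alpha)
        return alpha * f

    def reward(self, alpha: float) -> float:
        return self.payout if self.payout is not None else alpha


@dataclass(frozen=True)
class RankedPredictors:
    """An a-priori ordered candidate list (e.g. the soil or environmental group)."""

    names: tuple[str, ...]
    group: str = ""

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranked predictor names must be unique")
        object.__setattr__(self, "names", tuple(self.names))

    def validate_against(self, columns) -> None:
        missing = [n for n in self.names if n not in columns]
        if missing:
            raise KeyError(f"ranked predictors absent from table: {missing}")


@dataclass
class TestRecord:
    """One sequential test: screen decision, wealth accounting, final decision."""

    predictor: str
    p_value: float | None
    screen_retained: bool
    alpha_threshold: float | None = None
    wealth_before: float | None = None
    wealth_after: float | None = None
    final_retained: bool = False
    skipped: bool = False


@dataclass
class SelectionResult:
    records: list[TestRecord]
    retained: list[str]
    final_fit: SpatialLMMFit
    null_fit: SpatialLMMFit

    def to_frame(self) -> pd.DataFrame:
        """Records table mirroring a p-value-versus-threshold selection plot."""
        return pd.DataFrame([{
            "predictor": r.predictor,
            "p_value": r.p_value,
            "screen_retained": r.screen_retained,
            "alpha_threshold": r.alpha_threshold,
            "wealth_before": r.wealth_before,
            "wealth_after": r.wealth_after,
            "final_retained": r.final_retained,
            "skipped": r.skipped,
        } for r in self.records])


def alpha_investing_thresholds(p_values, alpha: float = 0.05,
                               rule: InvestingRule = InvestingRule()):
    """Per-test alpha-investing thresholds and the wealth trajectory.

    At test j (1-indexed) the spend is alpha_j = W_{j-1} / (1 + j - r_j)
    where r_j indexes the last rejection so far (0 before any).  Rejection
    (p_j <= alpha_j) pays wealth back: W_j = W_{j-1} - alpha_j + payout;
    acceptance charges W_j = W_{j-1} - alpha_j/(1 - alpha_j).  Wealth can
    never go negative because the acceptance charge is derived from the
    current wealth.

    Returns ``(thresholds, wealth)`` with ``wealth[0] = W0`` and
    ``wealth[j]`` the wealth after test j.
    """
    p_values = np.asarray(p_values, dtype=float)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    W = rule.initial_wealth(alpha)
    payout = rule.reward(alpha)
    thresholds = np.empty(len(p_values))
    wealth = np.empty(len(p_values) + 1)
    wealth[0] = W
    last_rejection = 0
    for j, p in enumerate(p_values, start=1):
        a_j = W / (1 + j - last_rejection)
        thresholds[j - 1] = a_j
        if p <= a_j:
            W = W - a_j + payout
            last_rejection = j
        else:
            W = W - a_j / (1 - a_j) if a_j < 1 else 0.0
        W = max(W, 0.0)
        wealth[j] = W
    return thresholds, wealth


def sequential_select(locations, X_null, y, candidates: pd.DataFrame,
                      ranked: RankedPredictors, alpha: float = 0.05,
                      kappa: float = 1.0, rule: InvestingRule = InvestingRule(),
                      null_effect_names=None,
                      final_method: str = "REML") -> SelectionResult:
    """Forward sequential selection over a ranked list with FDR control.

    Parameters
    ----------
    locations : (n, 2) array of km coordinates.
    X_null : (n, p0) array
        Null-model design (intercept + easting trend), always retained.
    y : (n,) response.
    candidates : DataFrame
        One column per candidate predictor (already transformed as decided
        by the exploratory stage).
    ranked : RankedPredictors
        Test order; earlier ranks get more alpha-wealth, hence more power.
    alpha : float
        Screen level and FDR target.
    kappa : float
        Matérn smoothness, fixed across all fits (select it on the null
        model with :func:`~geozinc.lmm.profile_kappa` beforehand).

    Any intermediate fit that fails to converge is recorded as skipped: its
    predictor cannot be retained and no wealth is spent on it.
    """
    ranked.validate_against(candidates.columns)
    X_null = np.asarray(X_null, dtype=float)
    if X_null.ndim == 1:
        X_null = X_null[:, None]
    if null_effect_names is None:
        null_effect_names = [f"null{j}" for j in range(X_null.shape[1])]
    # the Matérn/Cholesky work depends only on (nu, phi), not on which
    # predictors are in the model, so all fits of this selection share it
    cov_cache: dict = {}
    null_fit = fit_lmm(locations, X_null, y, fixed_effect_names=null_effect_names,
                       kappa=kappa, method="ML", xatol=1e-3, fatol=1e-6,
                       cov_cache=cov_cache)

    def warm_starts(fit):
        # candidate fits start from the working model's optimum: adding one
        # coefficient moves the covariance parameters little, so a single
        # warm start suffices (the LRT clips at zero if it ever undershoots)
        m = fit.matern
        nu = m.tau2 / m.sigma2 if m.sigma2 > 0 else 1e3
        return [(float(np.clip(nu, 1e-5, 1e5)), m.phi)]

    records: list[TestRecord] = []
    working_X = X_null
    working_names = list(null_effect_names)
    working_fit = null_fit
    for name in ranked.names:
        col = candidates[name].to_numpy(dtype=float)[:, None]
        X_try = np.hstack([working_X, col])
        try:
            fit_try = fit_lmm(locations, X_try, y,
                              fixed_effect_names=working_names + [name],
                              kappa=kappa, method="ML",
                              starts=warm_starts(working_fit),
                              xatol=1e-3, fatol=1e-6, cov_cache=cov_cache)
            test = lrt(working_fit, fit_try)
        except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"predictor {name!r}: fit failed ({exc}); skipped, "
                          "no wealth spent")
            records.append(TestRecord(predictor=name, p_value=None,
                                      screen_retained=False, skipped=True))
            continue
        retained = test.p_value <= alpha
        records.append(TestRecord(predictor=name, p_value=test.p_value,
                                  screen_retained=bool(retained)))
        if retained:
            working_X, working_names, working_fit = X_try, working_names + [name], fit_try

    tested = [r for r in records if not r.skipped]
    thresholds, wealth = alpha_investing_thresholds(
        [r.p_value for r in tested], alpha=alpha, rule=rule)
    for j, r in enumerate(tested):
        r.alpha_threshold = float(thresholds[j])
        r.wealth_before = float(wealth[j])
        r.wealth_after = float(wealth[j + 1])
        r.final_retained = bool(r.screen_retained and r.p_value <= thresholds[j])

    retained_names = [r.predictor for r in records if r.final_retained]
    if retained_names:
        X_final = np.hstack([X_null] +
                            [candidates[n].to_numpy(dtype=float)[:, None]
                             for n in retained_names])
    else:
        X_final = X_null
    final_fit = fit_lmm(locations, X_final, y,
                        fixed_effect_names=list(null_effect_names) + retained_names,
                        kappa=kappa, method=final_method,
                        starts=warm_starts(working_fit) + [(0.4, working_fit.matern.phi * 2.0)],
                        cov_cache=cov_cache)
    return SelectionResult(records=records, retained=retained_names,
                           final_fit=final_fit, null_fit=null_fit)
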