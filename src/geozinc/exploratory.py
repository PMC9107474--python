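"""Summary statistics, robust skewness, and the log-transform decision rule.

Soil and environmental predictors are screened before modelling: columns
whose octile skewness exceeds 0.2 in absolute value are log-transformed,
except for variables already reported on a log scale (pH, the partition
coefficient Zn_Kd), which are exempt.  The response itself is never
transformed by default; a saturated OLS fit is used only to judge whether
normality of its residuals is plausible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "octile_skewness",
    "summary_stats",
    "decide_transform",
    "summarise_table",
    "fit_saturated_ols",
    "LOG_SCALE_EXEMPT",
]

# variables already on a logarithmic scale: never log-transformed again
LOG_SCALE_EXEMPT = frozenset({"ph", "zn_kd"})

OCTILE_SKEW_GUIDE = 0.2  # |octile skew| above this suggests log transform


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    median: float
    minimum: float
    maximum: float
    standard_deviation: float
    skewness: float
    octile_skewness: float
    n: int


def octile_skewness(values) -> float:
    """Robust skewness from the 1st, 4th and 7th octiles.

    [(O7 - O4) - (O4 - O1)] / (O7 - O1), bounded in [-1, 1]; insensitive to
    outliers, unlike the moment coefficient.  Octiles use the standard
    linear-interpolation quantile rule.  A degenerate middle (O7 = O1)
    returns 0 with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError("octile skewness requires at least 8 values")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing or non-finite values; filter before summarising")
    o1, o4, o7 = np.quantile(values, [1 / 8, 4 / 8, 7 / 8])
    spread = o7 - o1
    if spread == 0:
        warnings.warn("octile skewness undefined for constant middle; reporting 0")
        return 0.0
    return float(((o7 - o4) - (o4 - o1)) / spread)


def summary_stats(values) -> SummaryStats:
    """Summary statistics including moment and octile skewness."""
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("missing or non-finite values; filter before summarising")
    return SummaryStats(
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        minimum=float(np.min(values)),
        maximum=float(np.max(values)),
        standard_deviation=float(np.std(values, ddof=1)),
        skewness=float(stats.skew(values, bias=False)),
        octile_skewness=octile_skewness(values),
        n=int(values.size),
    )


def decide_transform(stats_or_values, name: str | None = None,
                     exempt=LOG_SCALE_EXEMPT) -> bool:
    """Whether a predictor should be log-transformed before modelling.

    True iff |octile skewness| strictly exceeds 0.2, unless ``name`` is on
    the log-scale exemption list.  Raises if a transform is indicated but the
    variable is not strictly positive.
    """
    if name is not None and name.lower() in {e.lower() for e in exempt}:
        return False
    if isinstance(stats_or_values, SummaryStats):
        s = stats_or_values
        flag = abs(s.octile_skewness) > OCTILE_SKEW_GUIDE
        if flag and s.minimum <= 0:
            raise ValueError(
                f"variable {name or '<unnamed>'} needs a log transform but has "
                f"non-positive values (min {s.minimum})"
            )
        return bool(flag)
    return decide_transform(summary_stats(stats_or_values), name=name, exempt=exempt)


def summarise_table(table: pd.DataFrame, columns=None, exempt=LOG_SCALE_EXEMPT) -> pd.DataFrame:
    """Per-column summary statistics plus the transform decision.

    One row per variable, mirroring a survey summary table: mean, median,
    min, max, SD, skew, octile skew, and ``log_transform`` flag.
    """
    columns = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    rows = []
    for c in columns:
        s = summary_stats(table[c].to_numpy())
        rows.append({
            "variable": c, "n": s.n, "mean": s.mean, "median": s.median,
            "min": s.minimum, "max": s.maximum, "sd": s.standard_deviation,
            "skew": s.skewness, "octile_skew": s.octile_skewness,
            "log_transform": decide_transform(s, name=c, exempt=exempt),
        })
    return pd.DataFrame(rows).set_index("variable")


def fit_saturated_ols(y, X, column_names=None):
    """OLS residuals of the saturated exploratory model.

    Used only to judge whether the response needs transformation: normality
    is taken as plausible when the residuals' |moment skew| <= 1 and
    |octile skew| <= 0.2.  Returns ``(residuals, SummaryStats, normality_plausible)``.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = column_names or [f"x{j}" for j in range(X.shape[1])]
        # identify columns whose removal restores full rank
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s = summary_stats(resid)
    plausible = abs(s.skewness) <= 1.0 and abs(s.octile_skewness) <= OCTILE_SKEW_GUIDE
    return resid, s, plausible
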