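"""Dietary threshold derivation, below-threshold probabilities, calibrated phrases.

The mapping question is communicated as risk: given a per-cell E-BLUP of
grain Zn concentration and its prediction error variance, what is the
probability that the true concentration falls below a nutritionally
meaningful threshold?  The threshold is derived from dietary reference
values: if the staple grain supplies a share s of daily energy, it should
supply the same share of the Zn estimated average requirement (EAR), which
pins the required grain concentration at

    threshold (mg/kg) = s * EAR (mg/day) / intake (kg/day).

With EAR 10.3 mg/day, maize intake 342.8 g/day and maize providing 61.9%
of daily energy (342.8 g x 3.79 kcal/g = 1299.2 kcal), the threshold is
18.6 mg/kg.  Probabilities are reported both numerically and as
calibrated phrases (IPCC-style likelihood language); the 33-66% bin reads
"about as likely as not".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DietaryParams",
    "derive_threshold",
    "intake_from_concentration",
    "prob_below",
    "calibrated_phrase",
    "PHRASE_BINS",
    "risk_table",
]

# ADER implied by maize at 1299.2 kcal being 61.9% of daily energy; a
# derived default, overridable wherever DietaryParams is constructed.
DEFAULT_ADER_KCAL = 2099.0


@dataclass(frozen=True)
class DietaryParams:
    """Dietary reference quantities for the grain-Zn threshold.

    ear
        Zn estimated average requirement, mg per capita per day.
    maize_intake_g
        Reference daily maize intake, g per capita per day.
    energy_density_kcal_g
        Maize energy density, kcal per g.
    energy_share
        Fraction of daily energy supplied by maize; if None it is derived
        as maize_intake * energy_density / ader_kcal.
    ader_kcal
        Average daily energy requirement, kcal; only needed when
        energy_share is None.
    """

    ear: float = 10.3
    maize_intake_g: float = 342.8
    energy_density_kcal_g: float = 3.79
    energy_share: float | None = None
    ader_kcal: float | None = DEFAULT_ADER_KCAL

    def __post_init__(self) -> None:
        for name in ("ear", "maize_intake_g", "energy_density_kcal_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.energy_share is not None and not (0 < self.energy_share <= 1):
            raise ValueError("energy_share must lie in (0, 1]")

    @property
    def daily_maize_energy_kcal(self) -> float:
        return self.maize_intake_g * self.energy_density_kcal_g

    def resolved_energy_share(self) -> float:
        if self.energy_share is not None:
            return self.energy_share
        if self.ader_kcal is None or self.ader_kcal <= 0:
            raise ValueError("need either energy_share or a positive ader_kcal")
        return self.daily_maize_energy_kcal / self.ader_kcal


def derive_threshold(params: DietaryParams) -> float:
    """Grain-Zn threshold (mg/kg) at which maize covers its energy share of the EAR."""
    share = params.resolved_energy_share()
    return share * params.ear / (params.maize_intake_g / 1000.0)


def intake_from_concentration(grain_zn_mg_kg: float, maize_intake_g: float,
                              ear: float | None = None):
    """Daily Zn intake from maize (mg/day), optionally with %EAR.

    intake = concentration (mg/kg) x maize intake (kg/day); with an EAR the
    percentage of the requirement met is also returned.
    """
    if grain_zn_mg_kg <= 0 or maize_intake_g <= 0:
        raise ValueError("concentration and intake must be positive")
    intake = grain_zn_mg_kg * maize_intake_g / 1000.0
    if ear is None:
        return intake
    return intake, 100.0 * intake / ear


def prob_below(eblup, pev, threshold: float):
    """P(grain Zn < threshold) assuming normal prediction errors.

    Phi((threshold - eblup) / sqrt(pev)); pev = 0 degenerates to a step
    function (0 or 1) with a warning.
    """
    eblup = np.asarray(eblup, dtype=float)
    pev = np.asarray(pev, dtype=float)
    if np.any(pev < 0):
        raise ValueError("prediction error variance must be non-negative")
    if np.any(pev == 0):
        import warnings

        warnings.warn("pev = 0: probability degenerates to a step function")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (threshold - eblup) / np.sqrt(pev)
        p = stats.norm.cdf(z)
    p = np.where(pev == 0, (eblup < threshold).astype(float), p)
    return float(p) if p.ndim == 0 else p


# lower-closed, upper-open bins except the top; only the 0.33-0.66 phrase is
# anchored in the communication literature used here, the rest follow the
# IPCC likelihood scale
PHRASE_BINS = (
    (0.00, 0.01, "exceptionally unlikely"),
    (0.01, 0.10, "very unlikely"),
    (0.10, 0.33, "unlikely"),
    (0.33, 0.66, "about as likely as not"),
    (0.66, 0.90, "likely"),
    (0.90, 0.99, "very likely"),
    (0.99, 1.00, "virtually certain"),
)


def calibrated_phrase(probability: float, bins=PHRASE_BINS) -> str:
    """Map a probability to its calibrated-language label.

    Bins are lower-closed and upper-open, except the top bin which includes
    1.0; together they partition [0, 1].
    """
    p = float(probability)
    if not (0.0 <= p <= 1.0):
        raise ValueError("probability must lie in [0, 1]")
    for lo, hi, label in bins:
        if lo <= p < hi:
            return label
    return bins[-1][2]  # p == 1.0


def risk_table(predictions: pd.DataFrame, threshold: float,
               eblup_col: str = "eblup", pev_col: str = "pev") -> pd.DataFrame:
    """Attach below-threshold probability and phrase columns to a prediction table."""
    out = predictions.copy()
    p = prob_below(out[eblup_col].to_numpy(), out[pev_col].to_numpy(), threshold)
    out["prob_below"] = p
    out["phrase"] = [calibrated_phrase(v) for v in np.atleast_1d(p)]
    return out
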