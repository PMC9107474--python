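"""End-to-end orchestration: explore -> select -> refit -> xval -> predict -> risk.

Holds the pipeline configuration, the shared design-matrix conventions
(intercept + centred easting trend + log-transformed covariates) and the
stage driver used by both the command-line interface and the analysis
scripts.  Soil and environmental predictor sequences are run as separate
selections producing separate models; the environmental model, whose
covariates are available on the prediction grid, is the one carried
forward to mapping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exploratory, lmm, prediction, risk, selection

logger = logging.getLogger("geozinc")

RESPONSE_COL = "grain_zn_mg_kg"
COORD_COLS = ("easting_km", "northing_km")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; see the demo config for a template."""

    survey_csv: str
    out_dir: str
    soil_ranking: str | None = None
    env_ranking: str | None = None
    grid_csv: str | None = None
    alpha: float = 0.05
    kappa_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.0, 2.5)
    dietary: risk.DietaryParams = dc_field(default_factory=risk.DietaryParams)
    seed: int = 0
    stages: tuple[str, ...] = ("explore", "select", "xval", "predict", "risk")

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 0.5):
            raise ValueError("alpha must lie in (0, 0.5]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        dietary = risk.DietaryParams(**doc.pop("dietary", {}))
        kappa_grid = tuple(doc.pop("kappa_grid", (0.25, 0.5, 1.0, 1.5, 2.0, 2.5)))
        stages = tuple(doc.pop("stages", ("explore", "select", "xval", "predict", "risk")))
        return cls(dietary=dietary, kappa_grid=kappa_grid, stages=stages, **doc)


def read_ranking(path) -> list[str]:
    """Ordered predictor names, one per line; '#' comments ignored."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(line)
    if not names:
        raise ValueError(f"ranking file {path} is empty")
    return names


def build_design(table: pd.DataFrame, covariate_names=(), transforms=None):
    """Design matrix [1, centred easting, covariates]; log where flagged.

    ``transforms`` maps covariate name -> bool (log-transform before entry).
    Eastings are centred so the intercept sits at the domain's mid-easting.
    Returns ``(X, names)``.
    """
    transforms = transforms or {}
    n = len(table)
    east = table["easting_km"].to_numpy(dtype=float)
    cols = [np.ones(n), east - east.mean()]
    names = ["intercept", "easting"]
    for c in covariate_names:
        v = table[c].to_numpy(dtype=float)
        if transforms.get(c, False):
            if np.any(v <= 0):
                raise ValueError(f"cannot log-transform {c!r}: non-positive values")
            v = np.log(v)
        cols.append(v)
        names.append(c)
    return np.column_stack(cols), names


def transformed_candidates(table: pd.DataFrame, names, transforms) -> pd.DataFrame:
    out = {}
    for c in names:
        v = table[c].to_numpy(dtype=float)
        out[c] = np.log(v) if transforms.get(c, False) else v
    return pd.DataFrame(out)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order; returns a summary dict.

    Artifacts land in ``config.out_dir``: summary_stats.csv, the per-group
    selection tables, fit reports (JSON), xval records and summary, the
    prediction table and the risk table.  Any stage failure propagates with
    the stage named, after logging.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(config.survey_csv)
    for c in (*COORD_COLS, RESPONSE_COL):
        if c not in table.columns:
            raise ValueError(f"survey table lacks mandatory column {c!r}")
    locs = table[list(COORD_COLS)].to_numpy(dtype=float)
    y = table[RESPONSE_COL].to_numpy(dtype=float)
    summary: dict = {"n": len(table), "seed": config.seed}

    candidate_cols = [c for c in table.columns
                      if c not in (*COORD_COLS, RESPONSE_COL)]
    transforms: dict[str, bool] = {}
    if "explore" in config.stages:
        logger.info("stage explore: %d candidate columns", len(candidate_cols))
        stats_df = exploratory.summarise_table(table, columns=candidate_cols)
        stats_df.to_csv(out / "summary_stats.csv")
        transforms = stats_df["log_transform"].to_dict()
        resp_stats = exploratory.summary_stats(y)
        summary["explore"] = {"response_octile_skew": resp_stats.octile_skewness,
                              "log_transformed": sorted(k for k, v in transforms.items() if v)}

    X_null, null_names = build_design(table)
    logger.info("profiling kappa on the null model over %s", config.kappa_grid)
    kappa, kfits = lmm.profile_kappa(locs, X_null, y, kappa_grid=config.kappa_grid,
                                     method="ML", fixed_effect_names=null_names)
    null_fit = kfits[kappa]
    summary["null_model"] = null_fit.to_dict()
    summary["kappa_profile"] = {str(k): f.loglik for k, f in kfits.items()}
    logger.info("selected kappa = %s (loglik %.3f)", kappa, null_fit.loglik)

    results: dict[str, selection.SelectionResult] = {}
    if "select" in config.stages:
        for group, path in (("soil", config.soil_ranking),
                            ("environmental", config.env_ranking)):
            if path is None:
                continue
            ranked = selection.RankedPredictors(tuple(read_ranking(path)), group=group)
            cands = transformed_candidates(table, ranked.names, transforms)
            logger.info("stage select (%s): %s", group, ranked.names)
            res = selection.sequential_select(
                locs, X_null, y, cands, ranked, alpha=config.alpha, kappa=kappa,
                null_effect_names=null_names)
            res.to_frame().to_csv(out / f"selection_{group}.csv", index=False)
            comp = lmm.compare_models(res.null_fit, res.final_fit)
            summary[f"model_{group}"] = {
                "retained": res.retained,
                "fit": res.final_fit.to_dict(),
                "r2_adj": comp.r2_adj,
                "r2_adj_c": comp.r2_adj_c,
                "wealth_trajectory": [r.wealth_after for r in res.records
                                      if not r.skipped],
            }
            logger.info("%s model retained %s (r2_adj_c=%s)", group, res.retained,
                        comp.r2_adj_c)
            results[group] = res

    # the environmental model maps; fall back to the null model if absent
    map_res = results.get("environmental")
    if map_res is not None:
        retained = map_res.retained
        X_map, map_names = build_design(table, retained, transforms)
        map_fit = map_res.final_fit
    else:
        retained, (X_map, map_names), map_fit = [], (X_null, null_names), None
        map_fit = lmm.fit_lmm(locs, X_null, y, fixed_effect_names=null_names,
                              kappa=kappa, method="REML")
    summary["mapping_model"] = map_fit.to_dict()

    if "xval" in config.stages:
        logger.info("stage xval: leave-one-out over %d sites", len(y))
        records, xs = prediction.loo_cross_validate(map_fit, locs, X_map, y)
        records.to_csv(out / "xval_records.csv", index=False)
        summary["xval"] = {
            "mean_sspe": xs.mean_sspe, "median_sspe": xs.median_sspe,
            "median_ci": [xs.median_ci_low, xs.median_ci_high],
            "mean_error": xs.mean_error, "sd_error": xs.sd_error, "n": xs.n,
        }
        logger.info("xval mean SSPE %.3f, median %.3f (valid-model CI %.2f-%.2f)",
                    xs.mean_sspe, xs.median_sspe, xs.median_ci_low, xs.median_ci_high)

    if "predict" in config.stages and config.grid_csv is not None:
        grid = pd.read_csv(config.grid_csv)
        missing = [c for c in retained if c not in grid.columns]
        if missing:
            raise ValueError(f"prediction grid lacks covariates {missing}")
        X0, _ = build_design(grid, retained, transforms)
        # centre grid eastings about the survey mean, same convention as X
        east = table["easting_km"].to_numpy(dtype=float)
        X0[:, 1] = grid["easting_km"].to_numpy(dtype=float) - east.mean()
        logger.info("stage predict: %d grid cells", len(grid))
        pres = prediction.eblup(map_fit, locs, X_map, y,
                                grid[list(COORD_COLS)].to_numpy(dtype=float), X0)
        pred_df = pres.to_frame(grid[list(COORD_COLS)])
        pred_df.to_csv(out / "predictions.csv", index=False)
        summary["predict"] = {"n_cells": len(pred_df),
                              "mean_eblup": float(pred_df["eblup"].mean()),
                              "mean_pev": float(pred_df["pev"].mean())}

        if "risk" in config.stages:
            threshold = risk.derive_threshold(config.dietary)
            risk_df = risk.risk_table(pred_df, threshold)
            risk_df.to_csv(out / "risk.csv", index=False)
            summary["risk"] = {
                "threshold_mg_kg": threshold,
                "mean_prob_below": float(risk_df["prob_below"].mean()),
                "phrase_counts": risk_df["phrase"].value_counts().to_dict(),
            }
            logger.info("stage risk: threshold %.1f mg/kg, mean P(below) %.3f",
                        threshold, summary["risk"]["mean_prob_below"])

    with open(out / "pipeline_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
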