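#!/usr/bin/env python
"""Cross-validation diagnostics of the mapping model, plus calibration study.

Leave-one-out cross-validates the REML mapping model on the synthetic
survey and compares the standardised squared prediction errors against
their valid-model reference: mean 1, median 0.455, with the order-statistic
CI for the median at the survey size.  Then runs the pure calibration
study (simulating from a known model and cross-validating with the true
parameters) to show the diagnostics themselves are well calibrated.

Run after 03:  python analysis/04_cross_validate.py
"""

import argparse
from pathlib import Path

from geozinc.experiments import xval_calibration
from geozinc.pipeline import PipelineConfig, run_pipeline
from geozinc.prediction import median_sspe_ci

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
parser.add_argument("--out", type=Path, default=Path("results/xval"))
parser.add_argument("--calibration-reps", type=int, default=5)
args = parser.parse_args()

cfg = PipelineConfig(
    survey_csv=str(args.data / "survey.csv"),
    out_dir=str(args.out),
    env_ranking=str(args.data / "env_ranking.txt"),
    kappa_grid=(1.0,),
    stages=("explore", "select", "xval"),
)
summary = run_pipeline(cfg)
x = summary["xval"]
lo, hi = x["median_ci"]
print(f"survey LOO: mean SSPE {x['mean_sspe']:.3f} (expect ~1), median "
      f"{x['median_sspe']:.3f} (valid-model CI [{lo:.2f}, {hi:.2f}])")

lo16, hi16 = median_sspe_ci(1600)
print(f"reference CI at the full survey size n=1600: [{lo16:.2f}, {hi16:.2f}]")

cal = xval_calibration(n_reps=args.calibration_reps, seed=99)
print(f"calibration study ({cal['n_reps']} simulated surveys, true parameters): "
      f"mean SSPE {cal['mean_sspe']:.3f}, median {cal['median_sspe']:.3f}")
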