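#!/usr/bin/env python
"""Stage 1 — standard-curve recovery for the two Fe2+ readout methods.

Generates noisy synthetic standard curves for (a) the luminescent
nanoprobe (log10-intensity vs Fe2+/Fe_total, percent) and (b) a
phenanthroline-style absorbance assay (absorbance at 510 nm vs Fe2+),
fits each by ordinary least squares, and reports how well the known
generating constants are recovered.  Writes results/calibration_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from redoxlan import fit_linear_calibration, predict_log_intensity, reference_calibration
from redoxlan.synthetic import ABSORBANCE_INTERCEPT, ABSORBANCE_SLOPE

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=100)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    calib = reference_calibration()
    ratios = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0])
    clean_log_i = np.array([predict_log_intensity(calib, r) for r in ratios])
    fe2 = np.linspace(0.0, 2.0, 7)
    clean_abs = ABSORBANCE_SLOPE * fe2 + ABSORBANCE_INTERCEPT

    rows = []
    seeds = np.random.SeedSequence(args.seed).generate_state(args.replicates) % (2**31)
    for s in seeds:
        rng = np.random.default_rng(int(s))
        lum = fit_linear_calibration(ratios, clean_log_i + rng.normal(0, 0.01, ratios.size))
        phen = fit_linear_calibration(fe2, clean_abs + rng.normal(0, 0.01, fe2.size))
        rows.append({
            "seed": int(s),
            "lum_slope": lum.calibration.slope,
            "lum_intercept": lum.calibration.intercept,
            "lum_R": lum.pearson_r,
            "phen_slope": phen.calibration.slope,
            "phen_intercept": phen.calibration.intercept,
            "phen_R": phen.pearson_r,
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "calibration_recovery.csv", index=False)

    print(f"luminescence curve ({args.replicates} replicates):")
    print(f"  mean slope     {df.lum_slope.mean():.6f}  (generating {calib.slope})")
    print(f"  mean intercept {df.lum_intercept.mean():.4f}  (generating {calib.intercept})")
    print(f"  mean R         {df.lum_R.mean():.4f}")
    print("phenanthroline-style curve:")
    print(f"  mean slope     {df.phen_slope.mean():.4f}  (generating {ABSORBANCE_SLOPE})")
    print(f"  mean intercept {df.phen_intercept.mean():.4f}  (generating {ABSORBANCE_INTERCEPT})")


if __name__ == "__main__":
    main()
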