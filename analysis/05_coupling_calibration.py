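#!/usr/bin/env python
"""P3-pupil coupling per cohort, with replicate calibration of the test.

Reads the pipeline's coupling table (Theil-Sen fits of P3 amplitude on
pupil peak across subjects, per cohort and condition), then checks the
across-subject coupling statistic itself on 200 replicate cohorts drawn
from the generator's subject-level model: the control configuration
(slope 0) should be significant at roughly the nominal rate, the
TBI-like configuration (slope 0.5) in the large majority of replicates.
Writes results/coupling_calibration.tsv.
"""

from pathlib import Path

import pandas as pd

from antpupil import simulate, validation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cp = pd.read_csv(ROOT / "results" / "pipeline" / "coupling.tsv", sep="\t")
    raw = cp[cp.regressand == "p3_amplitude"]
    print("pipeline coupling fits (P3 amplitude ~ pupil peak):")
    print(raw[["cohort", "condition", "slope", "pearson_r", "p", "n"]]
          .round(3).to_string(index=False))
    if raw["n"].max() < 15:
        print("note: at the demo cohort size a single fit is dominated by "
              "sampling noise; the replicate block below carries the "
              "calibration/power evidence at the study's sample sizes")

    cfg = simulate.default_config()
    fp, null_slope = validation.coupling_replicate_rates(
        cfg.control, 35, n_replicates=200, seed=11)
    power, alt_slope = validation.coupling_replicate_rates(
        cfg.tbi, 23, n_replicates=200, seed=12)
    rows = pd.DataFrame([
        {"cohort": "control", "configured_slope": cfg.control.coupling_slope,
         "significant_fraction": fp, "mean_fitted_slope": null_slope},
        {"cohort": "tbi", "configured_slope": cfg.tbi.coupling_slope,
         "significant_fraction": power, "mean_fitted_slope": alt_slope},
    ])
    print("\nreplicate calibration (200 cohorts each):")
    print(rows.round(3).to_string(index=False))
    out = ROOT / "results" / "coupling_calibration.tsv"
    rows.to_csv(out, sep="\t", index=False)
    print(f"written to {out}")


if __name__ == "__main__":
    main()
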