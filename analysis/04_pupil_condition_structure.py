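#!/usr/bin/env python
"""Condition structure of the task-evoked pupil response.

Reads results/pipeline/condition_summaries.tsv and tabulates
response-aligned pupil peak amplitude/latency per cue and target
condition and cohort; tests the cue-condition effect with a one-way
repeated-measures ANOVA within each cohort. Writes
results/pupil_condition_structure.tsv.
"""

from pathlib import Path

import pandas as pd

from antpupil import stats

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cs = pd.read_csv(ROOT / "results" / "pipeline" / "condition_summaries.tsv",
                     sep="\t")
    cues = ["none", "center", "spatial"]
    table = (cs[cs.condition.isin(cues)]
             .groupby(["cohort", "condition"])[["pupil_peak", "pupil_latency"]]
             .agg(["mean", "sem"]).round(2))
    print(table.to_string())

    for cohort, sub in cs[cs.condition.isin(cues)].groupby("cohort"):
        wide = sub.pivot(index="subject", columns="condition",
                         values="pupil_peak")[cues].dropna()
        r = stats.rm_anova_oneway(wide.to_numpy())
        print(f"{cohort}: cue effect F({r.df1}, {r.df2}) = {r.F:.1f}, "
              f"p = {r.p_value:.2g} (n = {len(wide)})")

    out = ROOT / "results" / "pupil_condition_structure.tsv"
    table.to_csv(out, sep="\t")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
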