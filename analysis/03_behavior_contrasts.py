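#!/usr/bin/env python
"""Group behavioral contrasts: cohort RT/network-score Welch tests.

Reads results/pipeline/subject_metrics.tsv, tests each behavioral metric
across cohorts (Welch, BH-corrected as one family), and reproduces the
two closed-form worked examples from the study's printed group summaries
(overall RT and retained-trial counts). Writes results/behavior_tests.tsv.
"""

from pathlib import Path

import pandas as pd

from antpupil import coupling, stats

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    metrics = pd.read_csv(ROOT / "results" / "pipeline" / "subject_metrics.tsv",
                          sep="\t")
    tests = coupling.group_comparisons(
        metrics, ["overall_rt", "accuracy", "alerting", "orienting",
                  "executive", "n_usable", "n_rejected"])
    out = ROOT / "results" / "behavior_tests.tsv"
    out.parent.mkdir(exist_ok=True)
    tests.to_csv(out, sep="\t", index=False)
    print(tests.round(4).to_string(index=False))

    r1 = stats.welch_t_from_stats(594.2, 85.1, 45, 682.2, 92.3, 25)
    r2 = stats.welch_t_from_stats(243.2, 67.4, 45, 206.4, 66.8, 25)
    print(f"\nworked examples from printed group summaries:")
    print(f"  overall RT: t({r1.df:.1f}) = {r1.statistic:.1f}, p = {r1.p_value:.2g}")
    print(f"  retained trials: t({r2.df:.1f}) = {r2.statistic:.1f}, "
          f"p = {r2.p_value:.2g}")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
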