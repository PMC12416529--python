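#!/usr/bin/env python
"""Generate the demo two-cohort dataset used by the downstream drivers.

Writes EyeLink-dialect ASC recordings, trial tables, and EEG epoch arrays
for a control and a TBI-like cohort (6 subjects each, 2 blocks of 96
trials — a reduced-size session that keeps the demo fast) under
scratch/demo_dataset. The full-size study conditions live in
antpupil.simulate.default_config(); only the counts are reduced here.
"""

from pathlib import Path

from antpupil import simulate

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "demo_dataset"


def main() -> None:
    cfg = simulate.default_config(master_seed=2026, n_control=6, n_tbi=6,
                                  n_blocks=2, trials_per_block=96)
    manifest = simulate.make_cohort(cfg, OUT, overwrite=True)
    n = len(manifest["subjects"])
    print(f"wrote {n} subjects ({cfg.control.n_subjects} control, "
          f"{cfg.tbi.n_subjects} TBI-like) to {OUT}")
    print(f"master seed {manifest['master_seed']}; per-subject seeds recorded "
          "in manifest.json")


if __name__ == "__main__":
    main()
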