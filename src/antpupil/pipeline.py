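"""End-to-end orchestration: dataset -> pupil -> ERP -> behavior -> coupling.

``run_pipeline`` consumes either a dataset directory written by
:func:`antpupil.simulate.make_cohort` (ASC + trial-table TSV + EEG
epoch arrays) or in-memory subject data, applies both signal pipelines
with a shared usable-trial mask, and assembles the subject summary
tables, group comparisons, and coupling fits, together with a
machine-readable run log of every exclusion and QC action.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as coupling_mod
from . import erp as erp_mod
from . import pupil as pupil_mod
from .behavior import network_effects, summarize_rt
from .io_eyelink import CUE_TYPES, TARGET_TYPES, extract_trial_traces, parse_asc, read_trials_tsv
from .simulate import SubjectData

CONDITIONS = list(CUE_TYPES) + list(TARGET_TYPES)


@dataclass
class PipelineConfig:
    dataset_dir: str | Path | None = None
    output_dir: str | Path | None = None
    with_eeg: bool = True
    n_bootstrap: int = 200
    seed: int = 0
    fdr_q: float = 0.05
    use_snr_for_coupling: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = {k: (str(v) if isinstance(v, Path) else v)
                for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class PipelineResult:
    subject_metrics: pd.DataFrame        # one row per included subject
    condition_summaries: pd.DataFrame    # subject x condition metrics
    trial_table: pd.DataFrame            # usable-trial rows for trialwise fits
    coupling: pd.DataFrame               # cohort x condition coupling fits
    group_tests: pd.DataFrame
    trialwise: list = field(default_factory=list)
    run_log: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subject_metrics.to_csv(outdir / "subject_metrics.tsv", sep="\t", index=False)
        self.condition_summaries.to_csv(outdir / "condition_summaries.tsv", sep="\t", index=False)
        self.trial_table.to_csv(outdir / "trial_metrics.tsv", sep="\t", index=False)
        self.coupling.to_csv(outdir / "coupling.tsv", sep="\t", index=False)
        self.group_tests.to_csv(outdir / "group_tests.tsv", sep="\t", index=False)
        (outdir / "run_log.json").write_text(json.dumps(self.run_log, indent=2) + "\n")


def load_subject(subject_dir: str | Path, with_eeg: bool = True) -> SubjectData:
    """Read one subject from the documented on-disk container."""
    subject_dir = Path(subject_dir)
    session = parse_asc(subject_dir.joinpath("pupil.asc").read_text())
    trials = read_trials_tsv(subject_dir / "trials.tsv")
    epochs = times = channels = None
    npz_path = subject_dir / "eeg_epochs.npz"
    if with_eeg and npz_path.exists():
        with np.load(npz_path, allow_pickle=False) as z:
            epochs = z["epochs"].astype(float)
            times = z["times"].astype(float)
            channels = [str(c) for c in z["channels"]]
    return SubjectData(None, trials, session, epochs, times, channels)


def iter_dataset(dataset_dir: str | Path, with_eeg: bool = True):
    """Yield (cohort, subject_id, SubjectData) from a dataset directory."""
    dataset_dir = Path(dataset_dir)
    manifest = json.loads((dataset_dir / "manifest.json").read_text())
    for entry in manifest["subjects"]:
        sdir = dataset_dir / entry["cohort"] / entry["subject_id"]
        yield entry["cohort"], entry["subject_id"], load_subject(sdir, with_eeg)


def process_subject(
    data: SubjectData,
    subject_id: str,
    cohort: str,
    with_eeg: bool = True,
    n_bootstrap: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[dict | None, list[dict], list[dict], dict]:
    """Both signal pipelines for one subject, on a shared usable-trial mask.

    Returns (subject metrics row or None if excluded, condition summary
    rows, usable-trial rows, log entry).
    """
    log: dict = {"subject": subject_id, "cohort": cohort}
    traces = extract_trial_traces(data.session, data.trials)
    pres = pupil_mod.process_subject(traces)
    log["n_usable_trials"] = pres.n_usable
    log["n_rejected_trials"] = pres.n_rejected
    trial_flags: dict[str, int] = {}
    for ep in pres.epochs_cue:
        for f in ep.qc_flags:
            trial_flags[f] = trial_flags.get(f, 0) + 1
    log["trial_rejection_reasons"] = trial_flags
    if not pres.include:
        log["excluded"] = pres.exclusion_reason
        return None, [], [], log

    beh = summarize_rt(data.trials)
    eff = network_effects(beh)

    p3_metrics: dict[str, erp_mod.P3Metrics] = {}
    if with_eeg and data.eeg_epochs is not None:
        p3_metrics, _erps, screen = erp_mod.process_subject(
            data.eeg_epochs, data.eeg_times, data.eeg_channels,
            data.trials, pres.usable_mask,
            n_bootstrap=n_bootstrap, seed=seed,
        )
        log["eeg_screen"] = {
            lbl: {"bad_channels": r["bad_channels"],
                  "n_dropped_epochs": len(r["dropped_epochs"])}
            for lbl, r in screen.items()
        }
        if any(r["subject_failure"] for r in screen.values()):
            log["excluded"] = "eeg_subject_failure"
            return None, [], [], log

    row = {
        "subject": subject_id,
        "cohort": cohort,
        "overall_rt": beh.overall_mean,
        "accuracy": beh.accuracy,
        "alerting": eff.alerting,
        "orienting": eff.orienting,
        "executive": eff.executive,
        "n_usable": pres.n_usable,
        "n_rejected": pres.n_rejected,
    }

    cond_rows = []
    for label in CONDITIONS:
        grouping = "cue" if label in CUE_TYPES else "target"
        pm = pres.metrics_response.get((grouping, label))
        pm_cue = pres.metrics_cue.get((grouping, label))
        p3 = p3_metrics.get(label)
        cond_rows.append(
            {
                "subject": subject_id,
                "cohort": cohort,
                "condition": label,
                "pupil_peak": pm.peak_amplitude if pm else np.nan,
                "pupil_latency": pm.peak_latency if pm else np.nan,
                "pupil_peak_cue_aligned": pm_cue.peak_amplitude if pm_cue else np.nan,
                "pupil_latency_cue_aligned": pm_cue.peak_latency if pm_cue else np.nan,
                "p3_amplitude": p3.amplitude if p3 else np.nan,
                "p3_amplitude_unc": p3.amplitude_uncertainty if p3 else np.nan,
                "p3_latency": p3.latency if p3 else np.nan,
                "p3_latency_unc": p3.latency_uncertainty if p3 else np.nan,
                "p3_snr": p3.snr_amplitude if p3 else np.nan,
            }
        )

    trial_rows = [
        {**r, "subject": subject_id, "cohort": cohort} for r in pres.trial_metrics
    ]
    return row, cond_rows, trial_rows, log


def run_pipeline(
    config: PipelineConfig,
    subjects: list[tuple[str, str, SubjectData]] | None = None,
) -> PipelineResult:
    """Execute the full analysis over a dataset directory or supplied subjects.

    Subject-level failures are logged and skipped; the pipeline raises
    only when a cohort ends up empty.
    """
    rng = np.random.default_rng(config.seed)
    if subjects is None:
        if config.dataset_dir is None:
            raise ValueError("need dataset_dir or explicit subjects")
        subjects = list(iter_dataset(config.dataset_dir, config.with_eeg))

    metric_rows, cond_rows, trial_rows, logs = [], [], [], []
    for cohort, subject_id, data in subjects:
        row, conds, trows, log = process_subject(
            data, subject_id, cohort,
            with_eeg=config.with_eeg,
            n_bootstrap=config.n_bootstrap,
            seed=rng,
        )
        logs.append(log)
        if row is not None:
            metric_rows.append(row)
            cond_rows.extend(conds)
            trial_rows.extend(trows)

    subject_metrics = pd.DataFrame(metric_rows)
    cond_summaries = pd.DataFrame(cond_rows)
    trial_table = pd.DataFrame(trial_rows)
    cohorts_present = set(subject_metrics["cohort"]) if len(subject_metrics) else set()
    if not cohorts_present:
        raise RuntimeError("no subject survived QC in any cohort")

    coupling_rows = []
    for cohort in sorted(cohorts_present):
        for condition in CONDITIONS:
            for use_snr in (False, True):
                res = coupling_mod.across_subject_coupling(
                    cond_summaries, cohort, condition,
                    use_snr=use_snr, n_boot=300,
                    seed=int(rng.integers(2**31)),
                ) if len(cond_summaries) else None
                if res is None:
                    continue
                coupling_rows.append(
                    {
                        "cohort": res.cohort,
                        "condition": res.condition,
                        "regressand": res.regressand,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "pearson_r": res.pearson_r,
                        "p": res.p,
                        "n": res.n,
                        "slope_ci_lo": res.slope_ci[0],
                        "slope_ci_hi": res.slope_ci[1],
                    }
                )
    coupling_df = pd.DataFrame(coupling_rows)

    if len(cohorts_present) == 2:
        group_tests = coupling_mod.group_comparisons(
            subject_metrics,
            ["overall_rt", "accuracy", "alerting", "orienting", "executive",
             "n_usable", "n_rejected"],
            q=config.fdr_q,
        )
    else:
        group_tests = pd.DataFrame()

    trialwise = []
    if len(trial_table):
        for cohort in sorted(cohorts_present):
            sub = trial_table[trial_table["cohort"] == cohort]
            for relation in ("pupil_vs_rt", "evoked_vs_baseline"):
                trialwise.append(
                    coupling_mod.within_subject_trialwise(
                        sub, relation, cohort=cohort,
                        seed=int(rng.integers(2**31)),
                    )
                )

    run_log = {
        "seed": config.seed,
        "n_bootstrap": config.n_bootstrap,
        "with_eeg": config.with_eeg,
        "subjects": logs,
        "n_included": int(len(subject_metrics)),
        "exclusions": [
            {"subject": l["subject"], "reason": l["excluded"]}
            for l in logs if "excluded" in l
        ],
    }
    result = PipelineResult(
        subject_metrics=subject_metrics,
        condition_summaries=cond_summaries,
        trial_table=trial_table,
        coupling=coupling_df,
        group_tests=group_tests,
        trialwise=trialwise,
        run_log=run_log,
    )
    if config.output_dir is not None:
        result.write(config.output_dir)
    return result
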