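"""Cohort-level validation runs: parameter recovery and coupling calibration.

Helpers that run full synthetic cohorts through the signal pipelines and
tabulate extracted against configured (generator) values, plus replicate
checks of the across-subject coupling statistic. Used by the acceptance
checks and the analysis drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import coupling as coupling_mod
from . import erp as erp_mod
from . import pupil as pupil_mod
from . import simulate
from .io_eyelink import CUE_TYPES, TARGET_TYPES, extract_trial_traces


def _cohort_spec(cfg: simulate.CohortConfig, cohort: str) -> simulate.CohortSpec:
    return {"control": cfg.control, "tbi": cfg.tbi}[cohort]


def run_pupil_cohort(
    cohort: str, n_subjects: int, master_seed: int
) -> pd.DataFrame:
    """Full pupil signal path for one cohort.

    Returns one row per included subject x condition with extracted
    (response-aligned peak) and configured amplitude/latency.
    """
    cfg = simulate.default_config(master_seed=master_seed)
    spec = _cohort_spec(cfg, cohort)
    spec.n_subjects = n_subjects
    rows = []
    for data in simulate.generate_cohort(cfg, cohort, with_eeg=False):
        res = pupil_mod.process_subject(
            extract_trial_traces(data.session, data.trials))
        if not res.include:
            continue
        p = data.params
        for cue in CUE_TYPES:
            m = res.metrics_response.get(("cue", cue))
            if m is None:
                continue
            rows.append({
                "subject": p.subject_id, "condition": cue,
                "extracted_amp": m.peak_amplitude,
                "configured_amp": float(np.mean(
                    [p.pupil_peak[(cue, t)] for t in TARGET_TYPES])),
                "extracted_lat": m.peak_latency,
                "configured_lat": p.pupil_peak_latency[cue],
            })
        for tgt in TARGET_TYPES:
            m = res.metrics_response.get(("target", tgt))
            if m is None:
                continue
            rows.append({
                "subject": p.subject_id, "condition": tgt,
                "extracted_amp": m.peak_amplitude,
                "configured_amp": float(np.mean(
                    [p.pupil_peak[(c, tgt)] for c in CUE_TYPES])),
                "extracted_lat": m.peak_latency,
                "configured_lat": float(np.mean(
                    [p.pupil_peak_latency[c] for c in CUE_TYPES])),
            })
    return pd.DataFrame(rows)


def run_eeg_cohort(
    cohort: str, n_subjects: int, master_seed: int, n_bootstrap: int = 40
) -> pd.DataFrame:
    """Full joint path (pupil QC mask feeding the ERP branch) for one cohort.

    Returns one row per included subject x condition with extracted and
    configured P3 amplitude/latency, the SNR amplitude, and the subject's
    response-aligned pupil peak for coupling fits.
    """
    cfg = simulate.default_config(master_seed=master_seed)
    spec = _cohort_spec(cfg, cohort)
    spec.n_subjects = n_subjects
    rows = []
    for data in simulate.generate_cohort(cfg, cohort, with_eeg=True):
        res = pupil_mod.process_subject(
            extract_trial_traces(data.session, data.trials))
        if not res.include:
            continue
        mets, _, _ = erp_mod.process_subject(
            data.eeg_epochs, data.eeg_times, data.eeg_channels, data.trials,
            res.usable_mask, n_bootstrap=n_bootstrap, seed=0)
        p = data.params
        for label, m in mets.items():
            if label in CUE_TYPES:
                cells = [(label, t) for t in TARGET_TYPES]
                grouping = "cue"
            else:
                cells = [(c, label) for c in CUE_TYPES]
                grouping = "target"
            pm = res.metrics_response.get((grouping, label))
            rows.append({
                "subject": p.subject_id, "condition": label,
                "extracted_amp": m.amplitude,
                "configured_amp": float(np.mean([p.p3_amplitude[c] for c in cells])),
                "extracted_lat": m.latency,
                "configured_lat": float(np.mean([p.p3_latency[c] for c in cells])),
                "p3_snr": m.snr_amplitude,
                "pupil_peak": pm.peak_amplitude if pm else np.nan,
            })
    return pd.DataFrame(rows)


def relative_bias(df: pd.DataFrame, column_pair=("extracted_amp", "configured_amp")) -> float:
    """Mean(extracted - configured) / mean(configured), signed."""
    ext, cfg = column_pair
    return float((df[ext] - df[cfg]).mean() / df[cfg].mean())


def coupling_replicate_rates(
    spec: simulate.CohortSpec,
    n_subjects: int,
    n_replicates: int = 200,
    condition: str = "spatial",
    seed: int = 0,
    n_boot: int = 200,
) -> tuple[float, float]:
    """Fraction of replicate cohorts with significant coupling, and the
    mean fitted slope. Replicates are drawn at the subject-summary level
    (the between-subject structure the coupling statistic sees)."""
    rng = np.random.default_rng(seed)
    count = 0
    slopes = []
    for _ in range(n_replicates):
        df = simulate.subject_level_summaries(spec, n_subjects, rng)
        res = coupling_mod.across_subject_coupling(
            df, spec.name, condition, n_boot=n_boot,
            seed=int(rng.integers(2**31)))
        count += res.p < 0.05
        slopes.append(res.slope)
    return count / n_replicates, float(np.mean(slopes))
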