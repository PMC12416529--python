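"""Headline analyses: trialwise couplings, group contrasts, P3-pupil coupling.

Three levels:

* within-subject, across trials — robust (Theil-Sen) fits of pupil peak
  amplitude on RT and of evoked amplitude on baseline pupil size, with the
  cohort summarized by the fraction of subjects showing significant
  positive (or negative) slopes;
* between cohorts — Welch tests on per-subject metrics and pointwise on
  condition-average traces, Benjamini-Hochberg corrected within each
  comparison family;
* across subjects, within cohort — Theil-Sen fit of P3 amplitude (raw or
  SNR-transformed) on pupil peak amplitude per condition, the marker of
  interest: positive exclusively in the TBI-like cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import RegressionResult, bh_fdr, theil_sen, welch_t


@dataclass
class CouplingResult:
    cohort: str
    condition: str
    slope: float
    intercept: float
    pearson_r: float
    p: float
    n: int
    slope_ci: tuple[float, float] = (np.nan, np.nan)
    regressand: str = "p3_amplitude"


@dataclass
class TrialwiseSummary:
    cohort: str
    relation: str                   # "pupil_vs_rt" | "evoked_vs_baseline"
    n_subjects: int
    frac_significant_positive: float
    frac_significant_negative: float
    per_subject: pd.DataFrame


def within_subject_trialwise(
    trial_table: pd.DataFrame,
    relation: str,
    cohort: str = "",
    min_trials: int = 10,
    alpha: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
) -> TrialwiseSummary:
    """Per-subject Theil-Sen fits over usable trials.

    ``trial_table`` has one row per usable trial with columns ``subject``,
    ``rt``, ``baseline``, ``evoked_amplitude``. ``relation`` selects
    (pupil peak ~ RT) or (evoked amplitude ~ baseline). Subjects with
    fewer than ``min_trials`` usable trials are skipped.
    """
    if relation == "pupil_vs_rt":
        xcol, ycol = "rt", "evoked_amplitude"
    elif relation == "evoked_vs_baseline":
        xcol, ycol = "baseline", "evoked_amplitude"
    else:
        raise ValueError(f"unknown relation {relation!r}")
    rows = []
    rng = np.random.default_rng(seed)
    for subject, sub in trial_table.groupby("subject"):
        sub = sub.dropna(subset=[xcol, ycol])
        if len(sub) < min_trials:
            continue
        res = theil_sen(sub[xcol].to_numpy(), sub[ycol].to_numpy(),
                        n_boot=n_boot, seed=rng)
        rows.append(
            {
                "subject": subject,
                "slope": res.slope,
                "pearson_r": res.pearson_r,
                "p": res.slope_p,
                "n_trials": len(sub),
            }
        )
    per_subject = pd.DataFrame(rows)
    if len(per_subject):
        sig = per_subject["p"] < alpha
        pos = float(np.mean(sig & (per_subject["slope"] > 0)))
        neg = float(np.mean(sig & (per_subject["slope"] < 0)))
    else:
        pos = neg = np.nan
    return TrialwiseSummary(cohort, relation, len(per_subject), pos, neg, per_subject)


def group_comparisons(
    metrics: pd.DataFrame,
    value_columns: list[str],
    cohort_column: str = "cohort",
    cohorts: tuple[str, str] = ("control", "tbi"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Welch tests (control vs TBI-like) per metric, BH-corrected as one family.

    ``metrics`` has one row per subject. Returns a tidy frame with raw and
    adjusted p-values; the t sign follows ``cohorts[0] - cohorts[1]``.
    """
    a = metrics[metrics[cohort_column] == cohorts[0]]
    b = metrics[metrics[cohort_column] == cohorts[1]]
    rows = []
    for col in value_columns:
        x = a[col].dropna().to_numpy()
        y = b[col].dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            rows.append({"metric": col, "t": np.nan, "df": np.nan, "p": np.nan,
                         "mean_" + cohorts[0]: np.nan, "mean_" + cohorts[1]: np.nan})
            continue
        res = welch_t(x, y)
        rows.append(
            {
                "metric": col,
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "mean_" + cohorts[0]: float(x.mean()),
                "mean_" + cohorts[1]: float(y.mean()),
            }
        )
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    p_adj = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if valid.any():
        p_adj[valid.to_numpy()], rej[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"], q)
    out["p_adj"] = p_adj
    out["reject"] = rej
    return out


def trace_comparison(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    times: np.ndarray,
    q: float = 0.05,
) -> pd.DataFrame:
    """Pointwise Welch test of two cohorts' subject-mean traces, one BH family.

    ``traces_*`` are (n_subjects, n_samples); samples where either cohort
    has < 2 finite values are skipped.
    """
    rows = []
    for j, t in enumerate(times):
        x = traces_a[:, j]
        y = traces_b[:, j]
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            continue
        res = welch_t(x, y)
        rows.append({"time": float(t), "t": res.statistic, "p": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"], out["reject"] = bh_fdr(out["p"].to_numpy(), q)
    return out


def across_subject_coupling(
    summaries: pd.DataFrame,
    cohort: str,
    condition: str,
    use_snr: bool = False,
    pupil_on_p3: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> CouplingResult | None:
    """Theil-Sen fit of P3 amplitude on pupil peak across a cohort's subjects.

    ``summaries`` has one row per subject x condition with columns
    ``cohort``, ``condition``, ``pupil_peak``, ``p3_amplitude``,
    ``p3_snr``. Needs >= 3 subjects with both metrics; returns None
    otherwise. ``use_snr`` regresses the SNR-transformed amplitude;
    ``pupil_on_p3`` transposes the regression (Pearson's r is unaffected).
    """
    ycol = "p3_snr" if use_snr else "p3_amplitude"
    sub = summaries[
        (summaries["cohort"] == cohort) & (summaries["condition"] == condition)
    ].dropna(subset=["pupil_peak", ycol])
    if len(sub) < 3:
        return None
    x = sub["pupil_peak"].to_numpy()
    y = sub[ycol].to_numpy()
    if pupil_on_p3:
        x, y = y, x
    res: RegressionResult = theil_sen(x, y, n_boot=n_boot, seed=seed)
    return CouplingResult(
        cohort=cohort,
        condition=condition,
        slope=res.slope,
        intercept=res.intercept,
        pearson_r=res.pearson_r,
        p=res.slope_p,
        n=res.n,
        slope_ci=res.slope_ci,
        regressand=("pupil_peak" if pupil_on_p3 else ycol),
    )
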