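"""Pupillometry pipeline: blink handling, QC, alignment, averaging, peaks.

Processing per trial (500 Hz traces cut from the continuous recording):

1. blink/gap detection — union of tracker-reported blink events, missing
   samples, and derivative-detected abrupt changes; every gap is extended
   by 160 ms on both sides (edge effects of blinks corrupt neighbouring
   samples) and overlapping gaps are merged;
2. linear interpolation across interior gaps, constant fill at the trace
   edges; trials with >= 45% interpolated samples are rejected;
3. alignment to cue onset (t = 0 at cue, target at +500 ms) and,
   separately, to the response; baseline = mean of the 400 ms window
   preceding cue onset, subtracted from the whole trial;
4. arithmetic condition averages with SEM, and peak amplitude/latency
   taken as the maximum of the trace in the post-target (cue-aligned) or
   post-response (response-aligned) search window.

Participants with fewer than 15% usable trials in any cue or target
condition are excluded, as are participants whose mean pre-cue trace has
an inclined baseline trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_eyelink import (
    CUE_TYPES,
    SAMPLE_STEP_MS,
    TARGET_TYPES,
    TrialTrace,
)

#: blink-gap padding on each side, ms
BLINK_PAD_MS = 160.0
#: trial rejected when this fraction of samples (or more) is interpolated
MAX_INTERP_FRACTION = 0.45
#: participant excluded when any condition has fewer usable trials than this
MIN_USABLE_FRACTION = 0.15
#: baseline window, ms relative to cue onset (half-open)
BASELINE_WINDOW = (-400.0, 0.0)

CUE_ALIGNED_SPAN = (-400.0, 3500.0)     # ms relative to cue onset
RESPONSE_ALIGNED_SPAN = (-2000.0, 1500.0)  # ms relative to response


@dataclass
class PupilEpoch:
    """One trial's aligned, baseline-corrected pupil trace with QC metadata."""

    alignment: str                   # "cue" | "response"
    times: np.ndarray                # ms relative to alignment zero
    trace: np.ndarray                # AU, baseline-corrected; NaN = uncovered
    baseline_value: float            # AU, mean of the 400 ms pre-cue window
    interpolated_fraction: float
    qc_flags: set[str] = field(default_factory=set)
    trial_index: int = -1
    cue_type: str = ""
    target_type: str = ""

    @property
    def usable(self) -> bool:
        return not self.qc_flags


@dataclass
class PupilMetrics:
    peak_amplitude: float            # AU, baseline-corrected
    peak_latency: float              # ms post-target (cue) / post-response
    baseline: float = np.nan         # AU


# ---------------------------------------------------------------------------
# blink detection / interpolation


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _runs_to_intervals(times: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous True runs of a per-sample mask as half-open time intervals."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        out.append((float(times[run[0]]), float(times[run[-1]] + SAMPLE_STEP_MS)))
    return out


def detect_blinks(
    times: np.ndarray,
    pupil: np.ndarray,
    reported_events: list[tuple[float, float]] = (),
    pad_ms: float = BLINK_PAD_MS,
    deriv_mult: float = 5.0,
) -> list[tuple[float, float]]:
    """Padded, merged gap intervals needing interpolation.

    Union of (a) tracker-reported blink events, (b) runs of missing
    samples, and (c) samples where the absolute first difference exceeds
    ``deriv_mult`` times the median absolute first difference of the valid
    samples (abrupt-change detector). Each interval is extended by
    ``pad_ms`` on both sides; overlaps are merged.
    """
    times = np.asarray(times, dtype=float)
    pupil = np.asarray(pupil, dtype=float)
    intervals = [(float(s), float(e)) for s, e in reported_events]
    missing = np.isnan(pupil)
    intervals += _runs_to_intervals(times, missing)

    d = np.diff(pupil)
    valid_d = np.abs(d[np.isfinite(d)])
    if valid_d.size:
        scale = np.median(valid_d)
        if scale > 0:
            abrupt = np.abs(d) > deriv_mult * scale
            abrupt = np.concatenate([[False], abrupt]) | np.concatenate([abrupt, [False]])
            intervals += _runs_to_intervals(times, abrupt & np.isfinite(pupil))

    padded = [(s - pad_ms, e + pad_ms) for s, e in intervals]
    lo, hi = times[0], times[-1] + SAMPLE_STEP_MS
    padded = [(max(s, lo), min(e, hi)) for s, e in padded]
    return merge_intervals(padded)


def interpolate_blinks(
    times: np.ndarray,
    pupil: np.ndarray,
    intervals: list[tuple[float, float]],
) -> tuple[np.ndarray, float, bool]:
    """Fill gap intervals; return (filled trace, interpolated fraction, failed).

    Interior gaps are linearly bridged between the bounding valid samples;
    gaps touching the trace edges are filled with the nearest valid value.
    Only samples inside the intervals (or missing) are modified. ``failed``
    is set when no valid samples remain, or when a filled value falls far
    (>50% of the valid range) outside the range of the valid samples.
    """
    times = np.asarray(times, dtype=float)
    filled = np.asarray(pupil, dtype=float).copy()
    mask = np.isnan(filled)
    for s, e in intervals:
        mask |= (times >= s) & (times < e)
    good = ~mask & np.isfinite(filled)
    frac = float(mask.sum() / mask.size) if mask.size else 0.0
    if not good.any():
        return filled, frac, True
    # np.interp: linear interior, constant extrapolation at edges
    filled[mask] = np.interp(times[mask], times[good], filled[good])
    lo, hi = filled[good].min(), filled[good].max()
    span = hi - lo
    failed = bool(
        span > 0
        and (np.any(filled[mask] > hi + 0.5 * span) or np.any(filled[mask] < lo - 0.5 * span))
    )
    return filled, frac, failed


# ---------------------------------------------------------------------------
# QC


def qc_reject(
    interpolated_fraction: float,
    failed_interpolation: bool,
    missing_data: bool,
    correct: bool | None,
    max_interp_fraction: float = MAX_INTERP_FRACTION,
) -> set[str]:
    """Trial rejection flags; the trial is usable iff the set is empty.

    The interpolation threshold is inclusive: a fraction of exactly 45%
    is rejected. Incorrect and missing responses are rejected together.
    """
    flags = set()
    if not correct:
        flags.add("incorrect")
    if missing_data:
        flags.add("missing_data")
    if failed_interpolation:
        flags.add("failed_interpolation")
    if interpolated_fraction >= max_interp_fraction:
        flags.add("over_interpolated")
    return flags


def participant_qc(
    usable_counts: dict[str, int],
    total_counts: dict[str, int],
    min_usable_fraction: float = MIN_USABLE_FRACTION,
) -> bool:
    """Include the participant iff every cue and target condition retains at
    least ``min_usable_fraction`` of its trials (strict: exactly 15% passes)."""
    for key, total in total_counts.items():
        if total == 0:
            return False
        if usable_counts.get(key, 0) / total < min_usable_fraction:
            return False
    return True


# ---------------------------------------------------------------------------
# alignment / baseline


def _grid(span: tuple[float, float]) -> np.ndarray:
    return np.arange(span[0], span[1], SAMPLE_STEP_MS)


def align_and_baseline(
    trace: TrialTrace,
    filled: np.ndarray,
    mode: str,
    interpolated_fraction: float = 0.0,
    qc_flags: set[str] | None = None,
    baseline_interp_mask: np.ndarray | None = None,
) -> PupilEpoch:
    """Align a filled trial trace to cue onset or to the response.

    Cue mode puts t = 0 at cue onset (target lands at exactly +500 ms) on
    the grid [-400, +3500) ms; response mode puts t = 0 at the response on
    [-2000, +1500) ms, with samples outside the trial's coverage set NaN.
    Both subtract the mean of the [-400, 0) ms pre-cue window. A trial
    whose baseline window is unavailable (or entirely interpolated) is
    flagged ``missing_data``.
    """
    tr = trace.trial
    flags = set(qc_flags) if qc_flags else set()
    times = trace.times

    bw = (tr.cue_onset + BASELINE_WINDOW[0], tr.cue_onset + BASELINE_WINDOW[1])
    in_base = (times >= bw[0]) & (times < bw[1])
    n_expected = int(round((BASELINE_WINDOW[1] - BASELINE_WINDOW[0]) / SAMPLE_STEP_MS))
    base_vals = filled[in_base]
    if base_vals.size < n_expected or np.any(~np.isfinite(base_vals)):
        flags.add("missing_data")
        baseline = float(np.nanmean(base_vals)) if base_vals.size else np.nan
    else:
        baseline = float(base_vals.mean())
    if baseline_interp_mask is not None and in_base.any():
        if np.all(baseline_interp_mask[in_base]):
            flags.add("missing_data")

    if mode == "cue":
        zero = tr.cue_onset
        grid = _grid(CUE_ALIGNED_SPAN)
    elif mode == "response":
        if tr.response_time is None:
            flags.add("incorrect")
            zero = tr.target_onset  # placeholder; epoch unusable anyway
        else:
            zero = tr.response_time
        grid = _grid(RESPONSE_ALIGNED_SPAN)
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    out = np.full(grid.size, np.nan)
    if times.size:
        abs_times = grid + zero
        idx = np.round((abs_times - times[0]) / SAMPLE_STEP_MS).astype(int)
        ok = (idx >= 0) & (idx < times.size)
        out[ok] = filled[idx[ok]] - baseline

    return PupilEpoch(
        alignment=mode,
        times=grid,
        trace=out,
        baseline_value=baseline,
        interpolated_fraction=interpolated_fraction,
        qc_flags=flags,
        trial_index=tr.index,
        cue_type=tr.cue_type,
        target_type=tr.target_type,
    )


# ---------------------------------------------------------------------------
# averaging / peak metrics


def condition_average(
    epochs: list[PupilEpoch], grouping: str = "cue"
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]]:
    """Pointwise arithmetic mean and SEM of usable epochs per condition.

    Returns ``{label: (times, mean, sem, n_epochs)}``. Samples a trial does
    not cover (NaN) are excluded pointwise; SEM for a single epoch is 0.
    """
    labels = CUE_TYPES if grouping == "cue" else TARGET_TYPES
    attr = "cue_type" if grouping == "cue" else "target_type"
    out = {}
    for label in labels:
        group = [e for e in epochs if e.usable and getattr(e, attr) == label]
        if not group:
            continue
        stack = np.vstack([e.trace for e in group])
        n_pt = np.sum(np.isfinite(stack), axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
            sd = np.nanstd(stack, axis=0, ddof=1) if len(group) > 1 else np.zeros_like(mean)
        sem = np.where(n_pt > 0, sd / np.sqrt(np.maximum(n_pt, 1)), np.nan)
        out[label] = (group[0].times, mean, sem, len(group))
    return out


def pupil_peak(
    times: np.ndarray,
    trace: np.ndarray,
    window: tuple[float, float],
    latency_offset: float = 0.0,
    baseline: float = np.nan,
) -> PupilMetrics:
    """Peak amplitude and latency over a half-open (lo, hi] search window.

    Ties break to the earliest sample. ``latency_offset`` shifts reported
    latency to the pipeline's convention (post-target for cue-aligned
    traces, post-response for response-aligned ones).
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    sel = (times > window[0]) & (times <= window[1]) & np.isfinite(trace)
    if not sel.any():
        raise ValueError("empty peak search window")
    t_w, x_w = times[sel], trace[sel]
    i = int(np.argmax(x_w))  # argmax returns the first maximum: earliest tie
    return PupilMetrics(
        peak_amplitude=float(x_w[i]),
        peak_latency=float(t_w[i] - latency_offset),
        baseline=baseline,
    )


def peak_from_average(
    times: np.ndarray, mean: np.ndarray, alignment: str
) -> PupilMetrics:
    """Peak metrics of a condition-average trace with the default windows:
    cue-aligned searches (target onset, end]; response-aligned (0, end]."""
    if alignment == "cue":
        return pupil_peak(times, mean, (500.0, float(times[-1])), latency_offset=500.0)
    return pupil_peak(times, mean, (0.0, float(times[-1])))


# ---------------------------------------------------------------------------
# per-subject driver


@dataclass
class SubjectPupilResult:
    include: bool
    exclusion_reason: str | None
    epochs_cue: list[PupilEpoch]
    epochs_response: list[PupilEpoch]
    usable_mask: np.ndarray                   # bool per trial, shared with ERP
    averages_cue: dict                        # grouping -> label -> avg tuple
    averages_response: dict
    metrics_cue: dict[tuple[str, str], PupilMetrics]
    metrics_response: dict[tuple[str, str], PupilMetrics]
    trial_metrics: list[dict]                 # per-trial rows for trialwise fits
    n_usable: int = 0
    n_rejected: int = 0


def process_subject(
    traces: list[TrialTrace],
    baseline_slope_limit: float = 0.02,
) -> SubjectPupilResult:
    """Run the full pupil pipeline for one subject's trial traces.

    ``baseline_slope_limit`` (AU/ms) is the automatic stand-in for the
    visual inclined-baseline screen: the subject is excluded when the
    linear slope of the mean cue-aligned trace over the baseline window
    exceeds it in absolute value.
    """
    epochs_cue: list[PupilEpoch] = []
    epochs_resp: list[PupilEpoch] = []
    trial_rows: list[dict] = []
    usable = np.zeros(len(traces), dtype=bool)

    for k, trace in enumerate(traces):
        tr = trace.trial
        if trace.times.size == 0:
            flags = {"missing_data"}
            if not tr.correct:
                flags.add("incorrect")
            ep = PupilEpoch("cue", _grid(CUE_ALIGNED_SPAN),
                            np.full(_grid(CUE_ALIGNED_SPAN).size, np.nan),
                            np.nan, 1.0, flags, tr.index, tr.cue_type, tr.target_type)
            epochs_cue.append(ep)
            epochs_resp.append(PupilEpoch("response", _grid(RESPONSE_ALIGNED_SPAN),
                                          np.full(_grid(RESPONSE_ALIGNED_SPAN).size, np.nan),
                                          np.nan, 1.0, set(flags), tr.index,
                                          tr.cue_type, tr.target_type))
            continue
        intervals = detect_blinks(trace.times, trace.pupil, trace.blinks)
        filled, frac, fail = interpolate_blinks(trace.times, trace.pupil, intervals)
        interp_mask = np.zeros(trace.times.size, dtype=bool)
        for s, e in intervals:
            interp_mask |= (trace.times >= s) & (trace.times < e)
        flags = qc_reject(frac, fail, trace.missing_data, tr.correct)
        ep_cue = align_and_baseline(trace, filled, "cue", frac, flags, interp_mask)
        ep_resp = align_and_baseline(trace, filled, "response", frac, flags, interp_mask)
        epochs_cue.append(ep_cue)
        epochs_resp.append(ep_resp)
        usable[k] = ep_cue.usable and ep_resp.usable

        if usable[k]:
            try:
                m = peak_from_average(ep_resp.times, ep_resp.trace, "response")
                trial_rows.append(
                    {
                        "trial": tr.index,
                        "cue_type": tr.cue_type,
                        "target_type": tr.target_type,
                        "rt": tr.rt,
                        "baseline": ep_cue.baseline_value,
                        "evoked_amplitude": m.peak_amplitude,
                        "evoked_latency": m.peak_latency,
                    }
                )
            except ValueError:
                pass

    # participant-level QC: usable fraction per cue and per target condition
    usable_counts: dict[str, int] = {}
    total_counts: dict[str, int] = {}
    for k, trace in enumerate(traces):
        for key in (trace.trial.cue_type, trace.trial.target_type):
            total_counts[key] = total_counts.get(key, 0) + 1
            if usable[k]:
                usable_counts[key] = usable_counts.get(key, 0) + 1
    include = participant_qc(usable_counts, total_counts)
    reason = None if include else "under_15pct_usable"

    averages_cue, averages_resp = {}, {}
    metrics_cue: dict[tuple[str, str], PupilMetrics] = {}
    metrics_resp: dict[tuple[str, str], PupilMetrics] = {}
    if include:
        for grouping in ("cue", "target"):
            averages_cue[grouping] = condition_average(epochs_cue, grouping)
            averages_resp[grouping] = condition_average(epochs_resp, grouping)
        for grouping in ("cue", "target"):
            for label, (t, m, _s, _n) in averages_cue[grouping].items():
                metrics_cue[(grouping, label)] = peak_from_average(t, m, "cue")
            for label, (t, m, _s, _n) in averages_resp[grouping].items():
                metrics_resp[(grouping, label)] = peak_from_average(t, m, "response")

        # inclined-baseline screen on the mean cue-aligned trace
        cue_all = [e for e in epochs_cue if e.usable]
        if cue_all:
            stack = np.vstack([e.trace for e in cue_all])
            mean = np.nanmean(stack, axis=0)
            t = cue_all[0].times
            sel = (t >= BASELINE_WINDOW[0]) & (t < BASELINE_WINDOW[1])
            if np.all(np.isfinite(mean[sel])):
                slope = np.polyfit(t[sel], mean[sel], 1)[0]
                if abs(slope) > baseline_slope_limit:
                    include = False
                    reason = "inclined_baseline"

    return SubjectPupilResult(
        include=include,
        exclusion_reason=reason,
        epochs_cue=epochs_cue,
        epochs_response=epochs_resp,
        usable_mask=usable,
        averages_cue=averages_cue,
        averages_response=averages_resp,
        metrics_cue=metrics_cue,
        metrics_response=metrics_resp,
        trial_metrics=trial_rows,
        n_usable=int(usable.sum()),
        n_rejected=int(len(traces) - usable.sum()),
    )
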