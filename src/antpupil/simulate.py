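"""Synthetic two-cohort ANT datasets: behavior, pupil traces, EEG epochs.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any recording:

* balanced ANT schedules (3 cue x 2 target cells, fixed 4000 ms trials,
  fixation 400-1600 ms, cue->target gap 500 ms, max RT 1700 ms);
* per-condition truncated-normal RTs, slower in the TBI-like cohort with
  preserved accuracy;
* 500 Hz pupil traces: slowly wandering per-trial baseline, a smooth
  gamma-shaped evoked kernel peaking at a configured latency after the
  response, amplitude scaled down on high-baseline trials (negative
  tonic-phasic relationship), a biphasic (cue-locked + response-locked)
  kernel on spatial-cue trials of the control cohort, and blinks injected
  as missing-sample gaps with matching blink events;
* EEG epochs (-0.9..+1.0 s around target, 1000 Hz, small named montage
  incl. Pz and mastoids): pink-noise background plus a Pz-maximal
  Gaussian-in-time P3 component whose subject-level amplitude is coupled
  to the subject's pupil peak through the cohort's coupling slope.

Amplitude convention: configured P3 amplitudes are on the *measurement*
scale — the injected component is calibrated so that the expected ERP
(trial-jitter-smeared template), passed through the standard band-pass /
baseline / window-average extraction, returns exactly the configured
value. Pupil peak amplitudes need no calibration (the pipeline reads the
kernel maximum directly).

Everything is deterministic under a fixed master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import signal

from . import erp as erp_mod
from .io_eyelink import (
    CUE_TYPES,
    SAMPLE_STEP_MS,
    TARGET_TYPES,
    TRIAL_DURATION_MS,
    EyeSession,
    TrialRecord,
    write_asc,
    write_trials_tsv,
)

EEG_CHANNELS = ["Fz", "Cz", "Pz", "Oz", "P3", "P4", "C3", "C4", "M1", "M2"]
#: spatial falloff of the P3 component (Pz-maximal, tiny at the mastoids)
P3_TOPOGRAPHY = {
    "Pz": 1.0, "P3": 0.72, "P4": 0.72, "Cz": 0.62, "Oz": 0.50,
    "C3": 0.32, "C4": 0.32, "Fz": 0.22, "M1": 0.02, "M2": 0.02,
}
EEG_TIMES_MS = np.arange(-900.0, 1000.0)   # 1900 samples at 1000 Hz

CELLS = [(c, t) for c in CUE_TYPES for t in TARGET_TYPES]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class SubjectParams:
    """Everything needed to synthesize one subject's session."""

    subject_id: str
    cohort: str                                   # "control" | "tbi"
    rt_mean: dict[tuple[str, str], float]         # ms per condition cell
    rt_sd: float                                  # ms, within-subject
    accuracy: float                               # (0, 1]
    pupil_baseline: float                         # AU, tonic level
    baseline_trial_sd: float                      # AU, trial-to-trial wander
    baseline_coupling: float                      # k in (1 - k * z(baseline))
    pupil_peak: dict[tuple[str, str], float]      # AU per cell
    pupil_peak_latency: dict[str, float]          # ms post-response per cue
    pupil_latency_jitter: float                   # ms, trial-level
    pupil_amp_noise: float                        # multiplicative, trial-level
    pupil_trace_noise: float                      # AU, additive smooth noise
    kernel_shape: float                           # gamma shape of the kernel
    biphasic_spatial: bool
    blink_rate: float                             # events / trial
    p3_amplitude: dict[tuple[str, str], float]    # AU per cell (measurement scale)
    p3_latency: dict[tuple[str, str], float]      # ms post-target per cell
    p3_trial_amp_noise: float
    p3_latency_jitter: float                      # ms, trial-level
    p3_sigma: float                               # ms, Gaussian bump width
    eeg_noise_rms: float                          # AU, pink background
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.accuracy <= 1):
            raise ValueError("accuracy must lie in (0, 1]")
        for lat in list(self.pupil_peak_latency.values()) + list(self.p3_latency.values()):
            if lat <= 0:
                raise ValueError("latencies must be positive")


@dataclass
class CohortSpec:
    """Group-level means/SDs from which subjects are drawn."""

    name: str
    n_subjects: int
    rt_base_mean: float
    rt_base_sd: float
    cue_rt_effects: dict[str, float]
    executive_effect_mean: float
    executive_effect_sd: float
    rt_trial_sd: float
    accuracy_mean: float
    accuracy_sd: float
    pupil_peak_mean: dict[str, float]             # per cue, response-aligned
    pupil_peak_sd: dict[str, float]
    pupil_target_effect: float                    # incongruent - congruent, AU
    pupil_latency_mean: dict[str, float]          # ms post-response per cue
    pupil_latency_sd: float
    biphasic_spatial: bool
    blink_rate: float
    p3_base_mean: dict[str, float]                # per target, cohort mean AU
    p3_latency_mean: float                        # ms post-target
    p3_latency_sd: float
    coupling_slope: float                         # AU of P3 per AU of pupil peak
    coupling_noise_sd: float                      # between-subject residual
    pupil_baseline_mean: float = 3000.0
    pupil_baseline_sd: float = 400.0
    baseline_trial_sd: float = 150.0
    baseline_coupling: float = 0.2
    pupil_latency_jitter: float = 30.0
    pupil_amp_noise: float = 0.35
    pupil_trace_noise: float = 1.0
    kernel_shape: float = 3.0
    p3_trial_amp_noise: float = 0.3
    p3_latency_jitter: float = 20.0
    p3_sigma: float = 55.0
    eeg_noise_rms: float = 6.0


@dataclass
class CohortConfig:
    control: CohortSpec
    tbi: CohortSpec
    n_blocks: int = 3
    trials_per_block: int = 96
    master_seed: int = 0

    @property
    def cohorts(self) -> list[CohortSpec]:
        return [self.control, self.tbi]


def default_config(
    master_seed: int = 0,
    n_control: int = 35,
    n_tbi: int = 23,
    n_blocks: int = 3,
    trials_per_block: int = 96,
) -> CohortConfig:
    """Default study conditions.

    Control pupil peaks follow the group values 10.3/12.9/13.7 AU
    (no/center/spatial cue) at latencies 722/684/672 ms post-response; the
    TBI-like cohort uses 8.3/11.1/10.4 AU at 718/702/686 ms, loses the
    biphasic spatial-cue response, responds ~90 ms slower with preserved
    accuracy, and has an attenuated, delayed P3 whose subject amplitude is
    positively coupled (slope 0.5 AU/AU) to the subject's pupil peak;
    the control coupling slope is 0.
    """
    cue_fx = {"none": 55.0 / 3, "center": 55.0 / 3 - 20.0, "spatial": 55.0 / 3 - 35.0}
    control = CohortSpec(
        name="control",
        n_subjects=n_control,
        rt_base_mean=594.2,
        rt_base_sd=85.1,
        cue_rt_effects=dict(cue_fx),
        executive_effect_mean=100.0,
        executive_effect_sd=25.0,
        rt_trial_sd=120.0,
        accuracy_mean=0.95,
        accuracy_sd=0.02,
        pupil_peak_mean={"none": 10.3, "center": 12.9, "spatial": 13.7},
        pupil_peak_sd={"none": 1.6, "center": 1.5, "spatial": 1.5},
        pupil_target_effect=1.5,
        pupil_latency_mean={"none": 722.0, "center": 684.0, "spatial": 672.0},
        pupil_latency_sd=25.0,
        biphasic_spatial=True,
        blink_rate=0.35,
        p3_base_mean={"congruent": 5.5, "incongruent": 6.5},
        p3_latency_mean=380.0,
        p3_latency_sd=25.0,
        coupling_slope=0.0,
        coupling_noise_sd=1.2,
    )
    tbi = CohortSpec(
        name="tbi",
        n_subjects=n_tbi,
        rt_base_mean=682.2,
        rt_base_sd=92.3,
        cue_rt_effects=dict(cue_fx),
        executive_effect_mean=150.0,
        executive_effect_sd=30.0,
        rt_trial_sd=130.0,
        accuracy_mean=0.95,
        accuracy_sd=0.02,
        pupil_peak_mean={"none": 8.3, "center": 11.1, "spatial": 10.4},
        pupil_peak_sd={"none": 2.2, "center": 2.5, "spatial": 2.5},
        pupil_target_effect=1.5,
        pupil_latency_mean={"none": 718.0, "center": 702.0, "spatial": 686.0},
        pupil_latency_sd=25.0,
        biphasic_spatial=False,
        blink_rate=0.5,
        p3_base_mean={"congruent": 4.0, "incongruent": 5.0},
        p3_latency_mean=430.0,
        p3_latency_sd=25.0,
        coupling_slope=0.5,
        coupling_noise_sd=1.2,
    )
    return CohortConfig(control=control, tbi=tbi, n_blocks=n_blocks,
                        trials_per_block=trials_per_block,
                        master_seed=master_seed)


# ---------------------------------------------------------------------------
# subject draws


def draw_subject_params(
    spec: CohortSpec, rng: np.random.Generator, subject_id: str, seed: int = 0
) -> SubjectParams:
    """Draw one subject from the cohort model.

    The subject's pupil responsiveness is a single shared factor across
    cue conditions (plus small per-cue noise), and the subject's P3
    amplitude is ``cohort base + slope * (subject pupil peak - cohort
    pupil peak) + noise``: centering on the cohort mean keeps the cohort's
    configured mean amplitude while leaving the slope fully recoverable.
    """
    rt_base = rng.normal(spec.rt_base_mean, spec.rt_base_sd)
    execf = max(0.0, rng.normal(spec.executive_effect_mean, spec.executive_effect_sd))
    rt_mean = {
        (c, t): rt_base + spec.cue_rt_effects[c]
        + (execf / 2 if t == "incongruent" else -execf / 2)
        for c, t in CELLS
    }
    accuracy = float(np.clip(rng.normal(spec.accuracy_mean, spec.accuracy_sd), 0.75, 1.0))

    u = rng.standard_normal()
    peak_cue = {
        c: max(1.0, spec.pupil_peak_mean[c] + spec.pupil_peak_sd[c] * u
               + rng.normal(0.0, 0.3))
        for c in CUE_TYPES
    }
    pupil_peak = {
        (c, t): peak_cue[c]
        + (spec.pupil_target_effect / 2 if t == "incongruent" else -spec.pupil_target_effect / 2)
        for c, t in CELLS
    }
    lat_shift = rng.normal(0.0, spec.pupil_latency_sd)
    pupil_latency = {c: spec.pupil_latency_mean[c] + lat_shift for c in CUE_TYPES}

    subj_pupil_mean = float(np.mean(list(peak_cue.values())))
    cohort_pupil_mean = float(np.mean(list(spec.pupil_peak_mean.values())))
    coupling_term = spec.coupling_slope * (subj_pupil_mean - cohort_pupil_mean)
    amp_resid = rng.normal(0.0, spec.coupling_noise_sd)
    p3_amp = {
        (c, t): max(0.5, spec.p3_base_mean[t] + coupling_term + amp_resid)
        for c, t in CELLS
    }
    p3_lat_subj = float(
        np.clip(rng.normal(spec.p3_latency_mean, spec.p3_latency_sd), 330.0, 640.0)
    )
    p3_lat = {cell: p3_lat_subj for cell in CELLS}

    return SubjectParams(
        subject_id=subject_id,
        cohort=spec.name,
        rt_mean=rt_mean,
        rt_sd=spec.rt_trial_sd,
        accuracy=accuracy,
        pupil_baseline=float(rng.normal(spec.pupil_baseline_mean, spec.pupil_baseline_sd)),
        baseline_trial_sd=spec.baseline_trial_sd,
        baseline_coupling=spec.baseline_coupling,
        pupil_peak=pupil_peak,
        pupil_peak_latency=pupil_latency,
        pupil_latency_jitter=spec.pupil_latency_jitter,
        pupil_amp_noise=spec.pupil_amp_noise,
        pupil_trace_noise=spec.pupil_trace_noise,
        kernel_shape=spec.kernel_shape,
        biphasic_spatial=spec.biphasic_spatial,
        blink_rate=spec.blink_rate,
        p3_amplitude=p3_amp,
        p3_latency=p3_lat,
        p3_trial_amp_noise=spec.p3_trial_amp_noise,
        p3_latency_jitter=spec.p3_latency_jitter,
        p3_sigma=spec.p3_sigma,
        eeg_noise_rms=spec.eeg_noise_rms,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# schedule and behavior


def _round_grid(x: float) -> float:
    return float(np.round(x / SAMPLE_STEP_MS) * SAMPLE_STEP_MS)


def make_trial_schedule(
    n_blocks: int,
    trials_per_block: int,
    seed: int | np.random.Generator | None = 0,
) -> list[TrialRecord]:
    """Balanced, shuffled ANT schedule with fixed 4000 ms trials.

    ``trials_per_block`` must be divisible by the 6 condition cells; each
    block contains an equal count per cell, shuffled. Fixation durations
    are uniform on [400, 1600] ms (rounded to the 2 ms sampling grid).
    """
    if trials_per_block % 6 != 0:
        raise ValueError("trials_per_block must be divisible by 6")
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    idx = 0
    per_cell = trials_per_block // 6
    for _ in range(n_blocks):
        cells = [cell for cell in CELLS for _ in range(per_cell)]
        rng.shuffle(cells)
        for cue, tgt in cells:
            start = idx * TRIAL_DURATION_MS
            fix = _round_grid(rng.uniform(400.0, 1600.0))
            cue_onset = start + fix
            trials.append(
                TrialRecord(
                    index=idx,
                    cue_type=cue,
                    target_type=tgt,
                    fixation_duration=fix,
                    cue_onset=cue_onset,
                    target_onset=cue_onset + 500.0,
                )
            )
            idx += 1
    return trials


def simulate_behavior(
    trials: list[TrialRecord],
    params: SubjectParams,
    seed: int | np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Fill rt/correct: truncated-normal RTs per condition, errors at
    rate 1 - accuracy (a third of errors are missing responses)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    out = []
    for tr in trials:
        mu = params.rt_mean[tr.condition]
        rt = rng.normal(mu, params.rt_sd)
        while not (0 < rt <= 1700.0):
            rt = rng.normal(mu, params.rt_sd)
        rt = max(_round_grid(rt), SAMPLE_STEP_MS)
        correct = bool(rng.random() < params.accuracy)
        missing = (not correct) and (rng.random() < 1 / 3)
        out.append(
            TrialRecord(
                index=tr.index,
                cue_type=tr.cue_type,
                target_type=tr.target_type,
                fixation_duration=tr.fixation_duration,
                cue_onset=tr.cue_onset,
                target_onset=tr.target_onset,
                rt=None if missing else rt,
                response_time=None if missing else tr.target_onset + rt,
                correct=correct,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pupil traces


def _gamma_kernel(u: np.ndarray, tau: float, shape: float) -> np.ndarray:
    """Smooth unimodal kernel, 0 at u<=0, unit peak at u=tau."""
    out = np.zeros_like(u)
    pos = u > 0
    r = u[pos] / tau
    out[pos] = r**shape * np.exp(shape * (1.0 - r))
    return out


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  smooth_ms: float = 25.0) -> np.ndarray:
    w = rng.standard_normal(n)
    sigma = smooth_ms / SAMPLE_STEP_MS
    kern_t = np.arange(-4 * sigma, 4 * sigma + 1)
    kern = np.exp(-0.5 * (kern_t / sigma) ** 2)
    kern /= kern.sum()
    s = np.convolve(w, kern, mode="same")
    return sd * s / s.std()


def simulate_pupil(
    trials: list[TrialRecord],
    params: SubjectParams,
    seed: int | np.random.Generator | None = None,
) -> EyeSession:
    """Continuous 500 Hz pupil recording for a behavior-filled schedule.

    Per trial: wandering baseline (AR(1) across trials) + evoked kernel
    peaking at the configured latency after the response, scaled by
    ``1 - k * z(baseline)`` (negative tonic-phasic relationship) and by
    multiplicative trial noise; a cue-locked secondary kernel on
    spatial-cue trials when ``biphasic_spatial``; smooth additive noise;
    blinks as missing-sample gaps (100-400 ms) with blink events. The
    evoked response is tapered to zero over the trial's final 300 ms so
    it never contaminates the next trial's pre-cue baseline.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_per_trial = int(TRIAL_DURATION_MS / SAMPLE_STEP_MS)
    n = len(trials) * n_per_trial
    times = np.arange(n) * SAMPLE_STEP_MS
    pupil = np.empty(n)

    # AR(1) baseline wander across trials (stationary sd = baseline_trial_sd)
    rho = 0.9
    b = rng.normal(0.0, params.baseline_trial_sd)
    baselines = []
    for _ in trials:
        baselines.append(params.pupil_baseline + b)
        b = rho * b + rng.normal(0.0, params.baseline_trial_sd * np.sqrt(1 - rho**2))

    blink_events: list[tuple[float, float]] = []
    saccade_events: list[tuple[float, float]] = []
    messages: list[tuple[float, str]] = []

    for k, tr in enumerate(trials):
        sl = slice(k * n_per_trial, (k + 1) * n_per_trial)
        t = times[sl]
        trial_trace = np.full(n_per_trial, baselines[k])

        z = (baselines[k] - params.pupil_baseline) / params.baseline_trial_sd
        amp = params.pupil_peak[tr.condition]
        amp = amp * (1.0 - params.baseline_coupling * z)
        amp = amp * (1.0 + params.pupil_amp_noise * rng.standard_normal())

        rt = tr.rt if tr.rt is not None else 600.0
        lat = params.pupil_peak_latency[tr.cue_type] + rng.normal(
            0.0, params.pupil_latency_jitter
        )
        tau = max(200.0, rt + lat)
        u = t - tr.target_onset
        evoked = amp * _gamma_kernel(u, tau, params.kernel_shape)

        if params.biphasic_spatial and tr.cue_type == "spatial":
            u_cue = t - tr.cue_onset
            evoked = evoked + 0.35 * abs(amp) * _gamma_kernel(u_cue, 450.0, 4.0)

        # taper to zero over the trial's last 300 ms
        taper = np.ones(n_per_trial)
        tail = t > tr.end - 300.0
        taper[tail] = 0.5 * (1 + np.cos(np.pi * (t[tail] - (tr.end - 300.0)) / 300.0))
        trial_trace += evoked * taper
        pupil[sl] = trial_trace

        messages.append((tr.start, f"TRIALID {tr.index}"))
        n_sacc = rng.poisson(1.0)
        for _ in range(n_sacc):
            s0 = rng.uniform(tr.start, tr.end - 80.0)
            saccade_events.append((_round_grid(s0), _round_grid(s0 + rng.uniform(30, 60))))

    if params.pupil_trace_noise > 0:
        pupil += _smooth_noise(rng, n, params.pupil_trace_noise)
    pupil = np.round(pupil, 3)  # keeps the ASC export compact

    for k, tr in enumerate(trials):
        for _ in range(rng.poisson(params.blink_rate)):
            dur = _round_grid(rng.uniform(100.0, 400.0))
            s0 = _round_grid(rng.uniform(tr.start + 50.0, tr.end - dur - 50.0))
            i0 = int(s0 / SAMPLE_STEP_MS)
            i1 = int((s0 + dur) / SAMPLE_STEP_MS)
            pupil[i0:i1] = np.nan
            blink_events.append((s0, s0 + dur))

    gaze = np.column_stack(
        [
            np.round(960.0 + _smooth_noise(rng, n, 12.0, smooth_ms=100.0), 1),
            np.round(540.0 + _smooth_noise(rng, n, 12.0, smooth_ms=100.0), 1),
        ]
    )
    return EyeSession(
        sample_times=times,
        pupil=pupil,
        gaze=gaze,
        blinks=sorted(blink_events),
        saccades=sorted(saccade_events),
        messages=messages,
    )


# ---------------------------------------------------------------------------
# EEG epochs


@lru_cache(maxsize=256)
def _p3_measurement_gain(latency: float, sigma_eff: float, peak_scale: float) -> float:
    """Amplitude the standard extraction reports for a unit-raw-amplitude
    component; the generator divides by it so configured amplitudes are on
    the measurement scale."""
    bump = peak_scale * np.exp(-0.5 * ((EEG_TIMES_MS - latency) / sigma_eff) ** 2)
    x = erp_mod.band_pass(bump[None, :])
    bsel = (EEG_TIMES_MS >= erp_mod.EEG_BASELINE_WINDOW[0]) & (
        EEG_TIMES_MS < erp_mod.EEG_BASELINE_WINDOW[1]
    )
    x = x - x[:, bsel].mean()
    xd = signal.resample_poly(x, 3, 25, axis=-1)[0]
    td = EEG_TIMES_MS[0] + np.arange(xd.size) * (25 / 3)
    sel = (td >= erp_mod.P3_SEARCH_WINDOW[0]) & (td <= erp_mod.P3_SEARCH_WINDOW[1])
    t_w, x_w = td[sel], xd[sel]
    i = int(np.argmax(x_w))
    wsel = (td >= t_w[i] + erp_mod.P3_AVG_WINDOW[0]) & (td <= t_w[i] + erp_mod.P3_AVG_WINDOW[1])
    return float(xd[wsel].mean())


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float = 1000.0) -> np.ndarray:
    n = shape[-1]
    white = rng.standard_normal(shape)
    F = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    y = np.fft.irfft(F * scale, n, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    return y / np.where(sd > 0, sd, 1.0)


def simulate_eeg(
    trials: list[TrialRecord],
    params: SubjectParams,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-trial EEG epochs (n_trials, n_channels, 1900) at 1000 Hz.

    Pink-noise background plus the calibrated P3 component (Gaussian in
    time, Pz-maximal spatial falloff, per-trial amplitude and latency
    jitter). Returns (epochs, times_ms, channel_names).
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    n_ch = len(EEG_CHANNELS)
    w = np.array([P3_TOPOGRAPHY[c] for c in EEG_CHANNELS])
    w_eff = P3_TOPOGRAPHY["Pz"] - 0.5 * (P3_TOPOGRAPHY["M1"] + P3_TOPOGRAPHY["M2"])
    epochs = np.empty((len(trials), n_ch, EEG_TIMES_MS.size))
    for k, tr in enumerate(trials):
        noise = params.eeg_noise_rms * _pink_noise(rng, (n_ch, EEG_TIMES_MS.size))
        a_cfg = params.p3_amplitude[tr.condition]
        lat_cfg = params.p3_latency[tr.condition]
        sigma_eff = float(np.hypot(params.p3_sigma, params.p3_latency_jitter))
        gain = _p3_measurement_gain(
            round(lat_cfg, 1), round(sigma_eff, 3),
            round(w_eff * params.p3_sigma / sigma_eff, 6),
        )
        a_trial = (a_cfg / gain) * (1.0 + params.p3_trial_amp_noise * rng.standard_normal())
        lat_trial = lat_cfg + rng.normal(0.0, params.p3_latency_jitter)
        bump = np.exp(-0.5 * ((EEG_TIMES_MS - lat_trial) / params.p3_sigma) ** 2)
        epochs[k] = noise + a_trial * w[:, None] * bump[None, :]
    return epochs, EEG_TIMES_MS.copy(), list(EEG_CHANNELS)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SubjectData:
    params: SubjectParams
    trials: list[TrialRecord]
    session: EyeSession
    eeg_epochs: np.ndarray | None
    eeg_times: np.ndarray | None
    eeg_channels: list[str] | None


def simulate_subject(
    params: SubjectParams,
    n_blocks: int = 3,
    trials_per_block: int = 96,
    with_eeg: bool = True,
) -> SubjectData:
    """Generate one subject end-to-end from their parameters and seed."""
    rng = np.random.default_rng(params.seed)
    schedule = make_trial_schedule(n_blocks, trials_per_block, rng)
    trials = simulate_behavior(schedule, params, rng)
    session = simulate_pupil(trials, params, rng)
    if with_eeg:
        epochs = _cut_eeg(trials, params, rng)
        return SubjectData(params, trials, session, *epochs)
    return SubjectData(params, trials, session, None, None, None)


def _cut_eeg(trials, params, rng):
    return simulate_eeg(trials, params, rng)


def subject_seed(master_seed: int, cohort_index: int, subject_index: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, cohort_index, subject_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    config: CohortConfig, cohort: str, with_eeg: bool = True
):
    """Yield SubjectData for one cohort, deterministically from the master seed."""
    spec = {"control": config.control, "tbi": config.tbi}[cohort]
    c_idx = 0 if cohort == "control" else 1
    for s_idx in range(spec.n_subjects):
        seed = subject_seed(config.master_seed, c_idx, s_idx)
        prng = np.random.default_rng(seed)
        params = draw_subject_params(spec, prng, f"{cohort}-{s_idx:03d}", seed=seed + 1)
        yield simulate_subject(params, config.n_blocks, config.trials_per_block, with_eeg)


def subject_level_summaries(
    spec: CohortSpec,
    n_subjects: int,
    rng: np.random.Generator,
    measurement_noise: float = 0.3,
):
    """Subject-by-condition summary rows drawn straight from the cohort model.

    Used for replicate-level calibration and power checks of the
    across-subject coupling statistics, where running the full signal
    pipeline hundreds of times would add nothing but runtime: the
    between-subject structure (coupling slope, residual SDs) is identical
    to what the signal path carries. ``measurement_noise`` (AU) mimics the
    extraction noise of the signal pipeline.
    """
    import pandas as pd

    rows = []
    for i in range(n_subjects):
        p = draw_subject_params(spec, rng, f"{spec.name}-{i:03d}")
        for label in list(CUE_TYPES) + list(TARGET_TYPES):
            if label in CUE_TYPES:
                cells = [(label, t) for t in TARGET_TYPES]
            else:
                cells = [(c, label) for c in CUE_TYPES]
            peak = float(np.mean([p.pupil_peak[c] for c in cells]))
            amp = float(np.mean([p.p3_amplitude[c] for c in cells]))
            amp += rng.normal(0.0, measurement_noise)
            rows.append(
                {
                    "subject": p.subject_id,
                    "cohort": spec.name,
                    "condition": label,
                    "pupil_peak": peak + rng.normal(0.0, measurement_noise),
                    "p3_amplitude": amp,
                    "p3_snr": amp / max(measurement_noise, 0.1),
                }
            )
    return pd.DataFrame(rows)


def make_cohort(
    config: CohortConfig,
    outdir: str | Path,
    overwrite: bool = False,
    with_eeg: bool = True,
) -> dict:
    """Write both cohorts to disk and return the manifest.

    Layout: ``<out>/<cohort>/<subject>/pupil.asc`` (ASC dialect),
    ``trials.tsv`` (trial table), ``eeg_epochs.npz`` (epochs/times/
    channels arrays), plus ``manifest.json`` at the root listing every
    file with its per-subject seed. Refuses a non-empty output directory
    unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "container_version": 1,
        "master_seed": config.master_seed,
        "subjects": [],
    }
    for cohort in ("control", "tbi"):
        for data in generate_cohort(config, cohort, with_eeg=with_eeg):
            sdir = outdir / cohort / data.params.subject_id
            sdir.mkdir(parents=True, exist_ok=True)
            (sdir / "pupil.asc").write_text(write_asc(data.session))
            write_trials_tsv(data.trials, sdir / "trials.tsv")
            files = ["pupil.asc", "trials.tsv"]
            if with_eeg and data.eeg_epochs is not None:
                np.savez(
                    sdir / "eeg_epochs.npz",
                    epochs=data.eeg_epochs.astype(np.float32),
                    times=data.eeg_times,
                    channels=np.array(data.eeg_channels),
                )
                files.append("eeg_epochs.npz")
            manifest["subjects"].append(
                {
                    "subject_id": data.params.subject_id,
                    "cohort": cohort,
                    "seed": data.params.seed,
                    "files": [f"{cohort}/{data.params.subject_id}/{f}" for f in files],
                }
            )
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
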