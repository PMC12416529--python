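# Methods

This note documents the models, parameters, and numerical choices behind
`antpupil`, and what the synthetic benchmark does and does not establish
about real recordings.

## Task and timeline model

Each ANT trial occupies exactly 4000 ms: an initial fixation of random
duration (uniform on 400–1600 ms, rounded to the 2 ms sampling grid), a
100 ms cue phase, a 400 ms fixation, the target (response window up to
1700 ms), and inter-trial fixation filling the remainder. Cue onset is
therefore always 500 ms before target onset; for no-cue trials a virtual
cue onset at target − 500 ms keeps the cue-aligned timeline defined.
Sessions are three blocks of 96 trials, balanced over the 3 × 2
condition cells and shuffled within block.

Trial windows are half-open `[start, start + 4000)` in milliseconds;
eye-tracking runs at 500 Hz (2 ms grid), EEG at 1000 Hz, and all event
times are snapped to the 2 ms grid so alignment is exact by indexing.

## Pupil pipeline

* **Gap detection.** Union of tracker-reported blink events, runs of
  missing samples, and samples whose absolute first difference exceeds
  5 × the median absolute first difference of the trial's valid samples
  (a robust, scale-free default; the multiplier is configurable).
  Every interval is extended by 160 ms on each side — blink edges
  corrupt neighbouring samples — and overlaps are merged.
* **Interpolation.** Linear across interior gaps, constant fill at the
  trace edges (`np.interp` semantics). Samples outside gap intervals are
  bit-identical to the input. Interpolation is marked failed when no
  valid samples remain or a filled value leaves the valid range by more
  than 50 % of its span (an automatic stand-in for visual screening of
  failed interpolations; linear fills cannot trigger it, so it guards
  configuration errors).
* **QC thresholds.** A trial is rejected when ≥ 45 % of its samples are
  interpolated (the boundary is inclusive), when its response is
  incorrect or missing, or when its window is not covered by the
  recording. A participant is excluded when any cue or target condition
  keeps < 15 % usable trials (strict inequality: exactly 15 % passes),
  or when the mean pre-cue trace has an inclined baseline (absolute
  linear slope over the baseline window above 0.02 AU/ms, the automatic
  replacement for visual inspection).
* **Alignment and baseline.** Cue-aligned epochs span [−400, +3500) ms
  around cue onset; response-aligned epochs span [−2000, +1500) ms
  around the response, with samples outside the trial's coverage treated
  as missing and excluded pointwise from averages. Both subtract the
  mean of the [−400, 0) ms pre-cue window. Baseline correction is
  idempotent by construction.
* **Peaks.** Condition averages are pointwise arithmetic means with SEM;
  peak amplitude/latency is the maximum (earliest sample on ties) in the
  post-target window for cue-aligned traces and the post-response window
  for response-aligned traces.

## ERP pipeline

* **Filtering.** Mastoid-average re-reference, then a 4th-order
  Butterworth band-pass 1–10 Hz applied forward-backward (zero phase).
  Filtering uses long odd-reflection padding (up to 1 s): the 1 Hz edge
  has a time constant comparable to the 1.9 s epoch, and short default
  padding leaves edge transients well above the designed stopband.
* **Epochs.** [−900, +1000) ms around target onset; baseline is the
  pre-cue segment [−900, −500) ms; polyphase resampling 1000 → 120 Hz
  (228 samples). The epoch set mirrors the pupil pipeline's usable-trial
  mask exactly, so both modalities describe the same trials.
* **Artifact screening** (simplified, pluggable): a channel is
  interpolated (inverse-squared-distance weights over the schematic
  montage) when its MAD exceeds 5 × the montage's lower-quartile MAD —
  the lower quartile, not the median, so that the reference stays valid
  even when most channels are corrupted; an epoch is dropped when its
  peak-to-peak amplitude exceeds 5 × the median epoch peak-to-peak;
  more than 50 % bad channels flags the subject as failed.
* **KDE-weighted averaging.** At each time sample the epoch values get
  weights proportional to the Gaussian-kernel density estimate
  (Silverman bandwidth) evaluated at each value — a mode-seeking robust
  mean that down-weights outlying epochs and converges to the arithmetic
  mean for homogeneous data. Weights are computed per time sample;
  zero-spread columns fall back to the arithmetic mean. The bootstrap
  (default 1000 resamples, seeded) resamples epochs, never time samples,
  with one index vector shared across channels and samples; per-sample
  uncertainty is the SD of the weighted mean over resamples. The
  bootstrap loop runs in float32 — the weights are a smooth functional
  and reduced precision does not move the estimate.
* **P3 metrics.** Peak of the Pz trace in 300–700 ms post-target
  (earliest on ties); amplitude is the trace average over
  [peak − 42, peak + 83] ms, its uncertainty the SD of that window
  average recomputed on every bootstrap replicate (neighbouring samples
  are strongly correlated, so propagating per-sample SDs under an
  independence assumption would be wrong); latency uncertainty is half
  the interval between the crossings, on each side of the peak, of the
  level (peak value − its bootstrap SD), linearly interpolated between
  samples. SNR amplitude = amplitude / bootstrap amplitude SD;
  it is invariant to rescaling all epochs, and a zero uncertainty flags
  the metric rather than dividing.

## Statistics

Welch's t (summary-statistic and raw forms agree to machine precision),
paired t, one-sample t, Benjamini–Hochberg step-up FDR applied within an
explicit comparison family, and one-way repeated-measures ANOVA with the
standard within-subject decomposition, df = (k − 1, (k − 1)(n − 1)), no
sphericity correction.

Theil–Sen regression: slope = median of all pairwise slopes, intercept =
median of y − slope·x. Because a single point estimate has no variance,
the slope test uses a seeded bootstrap over observations:
t = slope / SD_boot with n − 2 degrees of freedom, two-tailed. On 200
replicate null cohorts this test is calibrated-to-conservative (observed
false-positive rate ≈ 2–5 % at nominal 5 %); the mild conservatism comes
from the bootstrap SD of a median-based estimator slightly
overestimating the sampling SD at these n.

The across-subject coupling regresses P3 amplitude on pupil peak
amplitude per cohort × condition (the transpose is available behind a
flag; Pearson's r is orientation-free and always reported). Both the raw
and SNR-transformed amplitudes are fitted and emitted; slope-recovery
checks use the raw amplitude, since dividing by a subject-specific
bootstrap SD rescales the slope by an arbitrary per-subject factor.

## Synthetic cohorts

The generator draws subjects from a two-cohort model and synthesizes raw
signals, so the whole pipeline — ASC parsing included — runs on data
with known ground truth.

* **Behavior.** Truncated-normal RTs per condition cell. Control: base
  594.2 ms (between-subject SD 85.1), executive effect 100 ms; TBI-like:
  682.2 ms (SD 92.3), executive effect 150 ms; alerting/orienting 20 and
  15 ms in both cohorts; within-subject trial SD 120–130 ms; accuracy
  0.95 in both cohorts (slower but preserved-accuracy phenotype).
  Errors occur at rate 1 − accuracy; a third of errors are missing
  responses.
* **Pupil.** Tonic baseline ~3000 AU with an AR(1) trial-to-trial wander
  (SD 150 AU). The evoked response is a gamma-shaped kernel
  (unit peak at u = τ, shape 3) starting at target onset and peaking at
  the configured latency after the response; response-aligned peak
  amplitudes are the group values 10.3/12.9/13.7 AU (no/center/spatial)
  for controls and 8.3/11.1/10.4 AU for the TBI-like cohort, at 722/684/
  672 and 718/702/686 ms post-response, with incongruent targets +1.5 AU
  over congruent. The printed dispersions (±1.5–2.5 AU) are used as
  between-subject SDs. Trial amplitude is scaled by
  (1 − 0.2·z(baseline)) — the negative tonic–phasic relationship — and
  by multiplicative noise (CV 0.35), giving trialwise baseline–amplitude
  correlations around −0.45. Spatial-cue trials in controls add a
  smaller cue-locked kernel (0.35 × amplitude, peaking 450 ms
  post-cue): the biphasic rise–plateau–rise pattern, absent in the
  TBI-like cohort. The evoked component is tapered to zero over the
  trial's final 300 ms so it cannot contaminate the next trial's
  baseline window. Blinks (0.35–0.5 per trial, 100–400 ms) become
  missing-sample gaps plus blink events; traces are quantized to
  0.001 AU for compact ASC export.
* **EEG.** Pink-noise background (RMS 6 AU per channel) on a 10-channel
  schematic montage, plus a Gaussian-in-time P3 (σ = 55 ms) that is
  Pz-maximal with smooth spatial falloff and near-zero at the mastoids.
  Control amplitudes 5.5/6.5 AU (congruent/incongruent) at 380 ms
  post-target; TBI-like 4.0/5.0 AU at 430 ms (attenuated and delayed).
  Subject amplitude = cohort base + coupling slope × (subject pupil
  peak − cohort mean) + residual (SD 1.2): centering keeps the cohort
  mean amplitude equal to the configured base while leaving the slope
  fully recoverable. The control slope is 0; the TBI-like slope is 0.5
  AU per AU, which puts the power of the coupling test at n = 23 near
  0.9 — a slope of 0.4 leaves it below 0.8 and indistinguishable from a
  marginal effect at this sample size.
* **Amplitude convention (calibration).** Configured P3 amplitudes are
  defined on the measurement scale: the generator passes the expected
  ERP template (the trial-jitter-smeared Gaussian, including the mastoid
  reference weight) through the standard band-pass / baseline /
  downsample / window-average extraction once, and scales the injected
  component by the inverse of the measured gain. Without this, the 1 Hz
  high-pass and the 125 ms window average impose a deterministic
  10–20 % shrinkage and "configured amplitude" would be a number no
  measurement could return. Pupil amplitudes need no calibration: the
  pipeline reads the kernel maximum directly.
* **Determinism.** Every subject's seed derives from the master seed via
  `SeedSequence([master, cohort, subject])`; manifests and raw files are
  byte-identical across runs with the same master seed.
* **On-disk container (version 1).** One directory per cohort, one per
  subject: `pupil.asc` (the ASC dialect: SAMPLE lines with `.` as the
  missing-pupil token, SBLINK/EBLINK, SSACC/ESACC, MSG), `trials.tsv`
  (the trial-table columns), and `eeg_epochs.npz` (arrays `epochs`
  [n_trials × n_channels × 1900 at 1000 Hz], `times`, `channels`). A
  root `manifest.json` records the container version, master seed, and
  every file with its subject seed. Pipeline configuration round-trips
  through YAML (`PipelineConfig.from_yaml`/`to_yaml`).

## What the synthetic benchmark shows — and what it does not

Passing the recovery and calibration suites shows that the pipeline is
an unbiased, correctly calibrated measurement chain *for data matching
the generator's assumptions*: smooth unimodal evoked kernels, Gaussian
P3 bumps on pink noise, stationary baselines, blinks as clean gaps. Real
recordings violate all of these in degree — pupil foreshortening and
gaze-dependent artifacts, non-Gaussian EEG artifacts surviving the
simplified screener, drifting arousal states, session effects. The
benchmark validates the code and the statistics, not the physiological
model; group-level findings from real cohorts (e.g., the specific
coupling correlations) are not reproducible from synthetic data and are
not claimed.

## Problem sizes and runtime choices

Cohort-level checks run at 23–30 subjects × 288 trials (the recovery
suite's standard conditions) with 40–100 bootstrap resamples inside the
per-subject ERP estimation; the function default stays at 1000, which a
single-subject analysis comfortably affords. Replicate calibration of
the coupling statistic (200 cohorts per configuration) runs at the
subject-summary level — the between-subject structure is what that
statistic sees, and full-signal replicates would add runtime but no
information about its calibration. The demo dataset uses 6 + 6 subjects
and 2 blocks; all counts are plain parameters of
`simulate.default_config`.

## Known limitations

* The derivative blink detector's multiplier (5 × median |Δ|) is a
  robust default, not a tuned constant; heavily quantized pupil traces
  change the median derivative and may need a different multiplier.
* The artifact screener is deliberately simple (variance- and
  peak-to-peak-based); it is a pluggable stand-in, not a replication of
  published consensus/rejection algorithms.
* The latency-uncertainty rule (level crossing at peak − SD) degrades on
  flat or multi-peaked traces; degenerate cases are flagged rather than
  extrapolated.
* Condition-average peaks carry a small positive noise bias (max of a
  noisy mean) and a small early-latency bias from the earliest-tie rule
  on quantized plateaus; both are well under the 5 % recovery tolerance
  at the benchmark's trial counts but grow at low trial counts.
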