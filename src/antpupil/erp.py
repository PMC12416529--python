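"""ERP pipeline: filtering, epoching, artifact screening, robust averaging.

EEG epochs (named channels, 1000 Hz, -0.9 to +1.0 s around target onset)
are re-referenced to the mastoid average, band-pass filtered 1-10 Hz
(zero-phase 4th-order Butterworth), baseline-corrected over the pre-cue
segment [-900, -500) ms, and downsampled to 120 Hz with polyphase
anti-aliasing. Epochs follow exactly the usable-trial mask produced by
the pupil pipeline, so both modalities describe the same trials.

The per-condition ERP is a KDE-weighted average: at each time sample the
epoch values are weighted by the Gaussian kernel density (Silverman
bandwidth) evaluated at each value, which down-weights outlying epochs.
Per-sample uncertainty is the SD of that weighted mean over bootstrap
resamples of epochs (resampling epochs, never time samples).

P3 metrics at Pz: peak in the 300-700 ms post-target window; amplitude is
the trace average over a 125 ms window (-42, +83) ms around the peak,
with its uncertainty propagated by recomputing that window average on
every bootstrap replicate; latency uncertainty is half the width of the
level set at (peak value - its uncertainty).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

P3_SEARCH_WINDOW = (300.0, 700.0)        # ms post-target
P3_AVG_WINDOW = (-42.0, 83.0)            # ms around the peak (125 ms total)
EEG_BASELINE_WINDOW = (-900.0, -500.0)   # ms, the pre-cue segment
EEG_FS = 1000.0
EEG_FS_DOWN = 120.0
EEG_BAND = (1.0, 10.0)

#: schematic 2D positions (x: left-right, y: posterior-anterior) for the
#: small montage; used for distance-weighted bad-channel interpolation.
MONTAGE = {
    "Fz": (0.0, 0.8), "Cz": (0.0, 0.0), "Pz": (0.0, -0.6), "Oz": (0.0, -1.0),
    "P3": (-0.5, -0.6), "P4": (0.5, -0.6), "C3": (-0.7, 0.0), "C4": (0.7, 0.0),
    "M1": (-1.0, -0.7), "M2": (1.0, -0.7),
}
MASTOIDS = ("M1", "M2")


@dataclass
class EEGEpochSet:
    """Epochs for one condition: (n_epochs, n_channels, n_samples) at 120 Hz."""

    condition: str
    epochs: np.ndarray
    times: np.ndarray                # ms relative to target onset
    channels: list[str]
    trial_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_epochs(self) -> int:
        return int(self.epochs.shape[0])

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


@dataclass
class ERPEstimate:
    """KDE-weighted mean trace with per-sample bootstrap uncertainty."""

    mean: np.ndarray                 # (n_channels, n_samples)
    uncertainty: np.ndarray          # bootstrap SD, NaN where not computed
    times: np.ndarray
    channels: list[str]
    n_epochs: int
    n_bootstrap: int
    replicates: dict[str, np.ndarray] = field(default_factory=dict)
    degenerate: bool = False         # single epoch: uncertainty undefined


@dataclass
class P3Metrics:
    amplitude: float
    amplitude_uncertainty: float
    latency: float                   # ms post-target
    latency_uncertainty: float
    snr_amplitude: float = np.nan
    degenerate: bool = False


# ---------------------------------------------------------------------------
# preprocessing


def band_pass(
    data: np.ndarray, fs: float = EEG_FS, band: tuple[float, float] = EEG_BAND,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Uses long odd-reflection padding: the 1 Hz high-pass edge has a time
    constant comparable to the epoch length, and the default padding
    leaves edge transients that leak through the stopband.
    """
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    padlen = min(data.shape[-1] - 1, int(fs))
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def preprocess(
    epochs: np.ndarray,
    channels: list[str],
    fs: float = EEG_FS,
    band: tuple[float, float] = EEG_BAND,
    mastoids: tuple[str, str] = MASTOIDS,
) -> np.ndarray:
    """Mastoid-average re-reference followed by the 1-10 Hz band-pass.

    Accepts (..., n_channels, n_samples); raises if a mastoid is missing.
    """
    for m in mastoids:
        if m not in channels:
            raise ValueError(f"mastoid channel {m} not in montage")
    mi = [channels.index(m) for m in mastoids]
    data = np.asarray(epochs)
    if data.dtype not in (np.float32, np.float64):
        data = data.astype(float)
    ref = data[..., mi, :].mean(axis=-2, keepdims=True, dtype=data.dtype)
    return band_pass(data - ref, fs=fs, band=band)


def make_epochs(
    epochs_1khz: np.ndarray,
    times_1khz: np.ndarray,
    channels: list[str],
    trials: list,
    usable_mask: np.ndarray,
    preprocessed: bool = False,
) -> dict[str, EEGEpochSet]:
    """Baseline, downsample to 120 Hz, and group usable epochs by condition.

    ``epochs_1khz`` is (n_trials, n_channels, n_samples) cut at
    [-900, +1000) ms around target onset. The epoch sets mirror the pupil
    pipeline's usable-trial mask exactly. Groups are the three cue types
    and the two target types (an epoch appears in one of each).
    """
    usable_mask = np.asarray(usable_mask, dtype=bool)
    keep = np.flatnonzero(usable_mask)
    data = np.asarray(epochs_1khz)[keep].astype(np.float32)
    if not preprocessed:
        data = preprocess(data, channels)
    times = np.asarray(times_1khz, dtype=float)
    bsel = (times >= EEG_BASELINE_WINDOW[0]) & (times < EEG_BASELINE_WINDOW[1])
    data = data - data[..., bsel].mean(axis=-1, keepdims=True, dtype=data.dtype)

    up, down = 3, 25  # 1000 Hz -> 120 Hz
    data_ds = signal.resample_poly(data, up, down, axis=-1).astype(float)
    n_out = data_ds.shape[-1]
    times_ds = times[0] + np.arange(n_out) * (down / up)

    out: dict[str, EEGEpochSet] = {}
    for attr, labels in (("cue_type", ("none", "center", "spatial")),
                         ("target_type", ("congruent", "incongruent"))):
        for label in labels:
            sel = np.array(
                [j for j, k in enumerate(keep)
                 if getattr(trials[k], attr) == label],
                dtype=int,
            )
            if sel.size == 0:
                continue
            out[label] = EEGEpochSet(
                condition=label,
                epochs=data_ds[sel],
                times=times_ds,
                channels=list(channels),
                trial_indices=keep[sel],
            )
    return out


# ---------------------------------------------------------------------------
# artifact screening


def screen_artifacts(
    epoch_set: EEGEpochSet,
    channel_mult: float = 5.0,
    epoch_mult: float = 5.0,
    exclude: tuple[str, ...] = MASTOIDS,
) -> tuple[EEGEpochSet, dict]:
    """Simplified artifact screener with a full action report.

    Channels whose robust variance (MAD of the channel signal over all
    epochs) exceeds ``channel_mult`` times the montage's lower-quartile
    MAD (a clean-floor reference that stays valid even when most channels
    are corrupted) are interpolated from the remaining channels with
    inverse-squared-distance weights. Epochs whose maximum peak-to-peak amplitude across scalp
    channels exceeds ``epoch_mult`` times the median epoch peak-to-peak
    are dropped. More than 50% bad channels sets a subject-failure flag.
    """
    X = epoch_set.epochs.copy()
    chans = epoch_set.channels
    scalp = [c for c in chans if c not in exclude]
    report: dict = {"bad_channels": [], "dropped_epochs": [], "subject_failure": False}

    mad = np.median(
        np.abs(X - np.median(X, axis=(0, 2), keepdims=True)), axis=(0, 2)
    )
    ref_mad = np.percentile(mad[[chans.index(c) for c in scalp]], 25)
    bad = [c for c in scalp if ref_mad > 0 and mad[chans.index(c)] > channel_mult * ref_mad]
    if len(bad) > 0.5 * len(scalp):
        report["subject_failure"] = True
        report["bad_channels"] = bad
        return epoch_set, report
    for c in bad:
        ci = chans.index(c)
        donors = [d for d in scalp if d not in bad]
        pos = np.array(MONTAGE[c])
        w = np.array([
            1.0 / max(np.sum((np.array(MONTAGE[d]) - pos) ** 2), 1e-6) for d in donors
        ])
        w /= w.sum()
        di = [chans.index(d) for d in donors]
        X[:, ci, :] = np.tensordot(w, X[:, di, :], axes=(0, 1))
        report["bad_channels"].append(c)

    si = [chans.index(c) for c in scalp]
    ptp = np.ptp(X[:, si, :], axis=2).max(axis=1)
    med_ptp = np.median(ptp)
    keep = ptp <= epoch_mult * med_ptp if med_ptp > 0 else np.ones(len(ptp), bool)
    report["dropped_epochs"] = [int(i) for i in epoch_set.trial_indices[~keep]]
    cleaned = EEGEpochSet(
        condition=epoch_set.condition,
        epochs=X[keep],
        times=epoch_set.times,
        channels=list(chans),
        trial_indices=epoch_set.trial_indices[keep],
    )
    return cleaned, report


# ---------------------------------------------------------------------------
# KDE-weighted averaging with bootstrap uncertainty


def _silverman(x2d: np.ndarray) -> np.ndarray:
    """Silverman bandwidth per column of an (n, m) value matrix."""
    n = x2d.shape[0]
    sd = x2d.std(axis=0, ddof=1)
    q75, q25 = np.percentile(x2d, [75, 25], axis=0)
    a = np.minimum(sd, (q75 - q25) / 1.34)
    a = np.where(a > 0, a, sd)
    return 0.9 * a * n ** (-1 / 5)


def kde_weighted_mean(x2d: np.ndarray, dtype=np.float64) -> np.ndarray:
    """KDE-density-weighted mean per column of an (n_epochs, m) matrix.

    Weight of epoch i at a column is the Gaussian-kernel density of the
    column's values evaluated at x_i (weights renormalized to sum 1);
    columns with zero spread fall back to the arithmetic mean.
    ``dtype=np.float32`` speeds up the bootstrap loop; the weights are a
    smooth functional, so reduced precision does not move the estimate.
    """
    n, m = x2d.shape
    if n == 1:
        return x2d[0].astype(float)
    h = _silverman(x2d)
    degenerate = ~(h > 0)
    h_safe = np.where(degenerate, 1.0, h)
    x = np.ascontiguousarray(x2d, dtype=dtype)
    d = (x[:, None, :] - x[None, :, :]) / h_safe.astype(dtype)  # (n, n, m)
    np.multiply(d, d, out=d)
    d *= -0.5
    np.exp(d, out=d)
    w = d.sum(axis=1)                              # (n, m) unnormalized density
    w = np.where(degenerate[None, :], dtype(1.0), w)
    return np.asarray((w * x).sum(axis=0) / w.sum(axis=0), dtype=float)


def kde_weighted_erp(
    epoch_set: EEGEpochSet,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = 0,
    uncertainty_channels: tuple[str, ...] | None = ("Pz",),
) -> ERPEstimate:
    """KDE-weighted ERP with bootstrap per-sample uncertainty.

    Bootstrap resamples are drawn over epochs (one index vector per
    resample, shared by all channels and time samples). Uncertainty is
    computed for ``uncertainty_channels`` (None = all); replicate traces
    are retained for those channels so window-averaged amplitudes can be
    propagated without an independence assumption.
    """
    X = np.asarray(epoch_set.epochs, dtype=float)
    n, n_ch, n_s = X.shape
    if n < 1:
        raise ValueError("no epochs")
    mean = np.stack(
        [kde_weighted_mean(X[:, c, :], dtype=np.float32) for c in range(n_ch)]
    )
    unc = np.full((n_ch, n_s), np.nan)
    reps: dict[str, np.ndarray] = {}
    if n == 1:
        return ERPEstimate(mean, unc, epoch_set.times, list(epoch_set.channels),
                           n, 0, reps, degenerate=True)

    chan_sel = (
        list(range(n_ch))
        if uncertainty_channels is None
        else [epoch_set.channels.index(c) for c in uncertainty_channels
              if c in epoch_set.channels]
    )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    for c in chan_sel:
        rc = np.empty((n_bootstrap, n_s))
        Xc = X[:, c, :]
        for b in range(n_bootstrap):
            rc[b] = kde_weighted_mean(Xc[idx[b]], dtype=np.float32)
        unc[c] = rc.std(axis=0, ddof=1)
        reps[epoch_set.channels[c]] = rc
    return ERPEstimate(mean, unc, epoch_set.times, list(epoch_set.channels),
                       n, n_bootstrap, reps)


# ---------------------------------------------------------------------------
# P3 extraction


def _crossing(times: np.ndarray, trace: np.ndarray, i_peak: int, level: float,
              direction: int) -> float:
    """Time where the trace first crosses below ``level`` moving out from
    the peak; linear interpolation between samples; window edge if never."""
    i = i_peak
    while 0 <= i + direction < trace.size:
        j = i + direction
        if trace[j] < level:
            # interpolate between samples i (>= level) and j (< level)
            f = (trace[i] - level) / (trace[i] - trace[j])
            return float(times[i] + f * (times[j] - times[i]))
        i = j
    return float(times[i])


def extract_p3(
    erp: ERPEstimate,
    channel: str = "Pz",
    search_window: tuple[float, float] = P3_SEARCH_WINDOW,
    avg_window: tuple[float, float] = P3_AVG_WINDOW,
) -> P3Metrics:
    """P3 amplitude/latency with bootstrap-propagated uncertainties.

    Peak = maximum of the weighted-mean trace at ``channel`` within the
    search window (ties to earliest). Amplitude = trace average over
    [peak-42, peak+83] ms (clipped to the epoch); its uncertainty is the
    SD of that window average across bootstrap replicates. Latency = peak
    time; its uncertainty is half the interval between the left and right
    crossings of level (peak value - peak uncertainty).
    """
    ci = erp.channels.index(channel)
    trace = erp.mean[ci]
    times = erp.times
    sel = (times >= search_window[0]) & (times <= search_window[1])
    if not sel.any():
        raise ValueError("ERP does not cover the P3 search window")
    t_w, x_w = times[sel], trace[sel]
    i_loc = int(np.argmax(x_w))
    latency = float(t_w[i_loc])
    peak_val = float(x_w[i_loc])
    i_peak = int(np.flatnonzero(sel)[i_loc])

    wsel = (times >= latency + avg_window[0]) & (times <= latency + avg_window[1])
    amplitude = float(trace[wsel].mean())

    degenerate = bool(np.ptp(trace) == 0)
    rc = erp.replicates.get(channel)
    if rc is not None and rc.size:
        amp_unc = float(rc[:, wsel].mean(axis=1).std(ddof=1))
        peak_unc = float(rc[:, i_peak].std(ddof=1))
    else:
        amp_unc, peak_unc = np.nan, np.nan

    if degenerate or not np.isfinite(peak_unc):
        lat_unc = np.nan
    else:
        level = peak_val - peak_unc
        t_left = _crossing(times, trace, i_peak, level, -1)
        t_right = _crossing(times, trace, i_peak, level, +1)
        lat_unc = 0.5 * (t_right - t_left)

    m = P3Metrics(amplitude, amp_unc, latency, lat_unc, degenerate=degenerate)
    m.snr_amplitude = snr_transform(m)
    return m


def snr_transform(metrics: P3Metrics) -> float:
    """Signal-to-noise amplitude: amplitude / bootstrap uncertainty.

    Dimensionless; invariant to rescaling every epoch. A zero or missing
    uncertainty flags the metric as degenerate instead of dividing.
    """
    if metrics.amplitude == 0:
        return 0.0
    if not np.isfinite(metrics.amplitude_uncertainty) or metrics.amplitude_uncertainty == 0:
        metrics.degenerate = True
        return np.nan
    return float(metrics.amplitude / metrics.amplitude_uncertainty)


# ---------------------------------------------------------------------------
# per-subject driver


def process_subject(
    epochs_1khz: np.ndarray,
    times_1khz: np.ndarray,
    channels: list[str],
    trials: list,
    usable_mask: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> tuple[dict[str, P3Metrics], dict[str, ERPEstimate], dict]:
    """Filter, epoch, screen, and estimate condition ERPs + P3 metrics."""
    sets = make_epochs(epochs_1khz, times_1khz, channels, trials, usable_mask)
    rng = np.random.default_rng(seed)
    metrics: dict[str, P3Metrics] = {}
    erps: dict[str, ERPEstimate] = {}
    screen_report: dict = {}
    for label, es in sets.items():
        cleaned, rep = screen_artifacts(es)
        screen_report[label] = rep
        if rep["subject_failure"] or cleaned.n_epochs < 2:
            continue
        erp = kde_weighted_erp(cleaned, n_bootstrap=n_bootstrap, seed=rng)
        erps[label] = erp
        metrics[label] = extract_p3(erp)
    return metrics, erps, screen_report
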