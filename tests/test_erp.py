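"""ERP pipeline: filtering, epoching, screening, KDE averaging, P3 metrics."""

import numpy as np
import pytest
from scipy import signal

from antpupil import erp
from antpupil.io_eyelink import TrialRecord

FS = 1000.0
T = np.arange(-900.0, 1000.0)
CH = list(erp.MONTAGE)


def make_trials(n):
    out = []
    for i in range(n):
        start = i * 4000.0
        cue = start + 600.0
        out.append(TrialRecord(i, ["none", "center", "spatial"][i % 3],
                               ["congruent", "incongruent"][i % 2],
                               600.0, cue, cue + 500.0, rt=600.0,
                               response_time=cue + 1100.0, correct=True))
    return out


class TestPreprocess:
    def test_constant_offsets_removed_by_highpass(self):
        x = np.ones((len(CH), T.size)) * np.arange(len(CH))[:, None]
        y = erp.preprocess(x, CH)
        assert np.abs(y).max() < 1e-6

    def test_passband_sinusoid_preserved(self):
        x = np.zeros((len(CH), T.size))
        x[CH.index("Pz")] = np.sin(2 * np.pi * 5.0 * T / FS)
        y = erp.band_pass(x)
        mid = slice(500, 1400)
        ratio = y[CH.index("Pz"), mid].std() / x[CH.index("Pz"), mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation_of_30hz_tone(self):
        # oracle: the designed zero-phase transfer function at 30 Hz is far
        # below -20 dB; the applied filter on a finite epoch must still
        # attenuate a 30 Hz tone by >= 20 dB (edge transients limit it to
        # less than the steady-state figure)
        sos = signal.butter(4, (1.0, 10.0), btype="bandpass", fs=FS, output="sos")
        _, h = signal.sosfreqz(sos, worN=[30.0], fs=FS)
        designed_db = 40 * np.log10(np.abs(h[0]))  # forward-backward squares |H|
        assert designed_db < -40.0
        x = np.zeros((1, T.size))
        x[0] = np.sin(2 * np.pi * 30.0 * T / FS)
        y = erp.band_pass(x)
        mid = slice(500, 1400)
        got_db = 20 * np.log10(y[0, mid].std() / x[0, mid].std())
        assert got_db < -20.0
        assert got_db > designed_db - 1.0  # cannot beat the designed response

    def test_missing_mastoid_is_configuration_error(self):
        with pytest.raises(ValueError):
            erp.preprocess(np.zeros((2, 100)), ["Pz", "Cz"])


class TestMakeEpochs:
    def test_downsampled_epoch_has_228_samples(self):
        n = 6
        x = np.random.default_rng(0).normal(0, 1, (n, len(CH), T.size))
        sets = erp.make_epochs(x, T, CH, make_trials(n), np.ones(n, bool))
        for es in sets.values():
            assert es.epochs.shape[-1] == 228

    def test_pupil_rejected_trials_absent(self):
        n = 12
        x = np.random.default_rng(0).normal(0, 1, (n, len(CH), T.size))
        mask = np.ones(n, bool)
        mask[[2, 5, 7]] = False
        sets = erp.make_epochs(x, T, CH, make_trials(n), mask)
        all_idx = np.concatenate(
            [es.trial_indices for es in sets.values() if es.condition in
             ("none", "center", "spatial")])
        assert set(all_idx) == set(np.flatnonzero(mask))

    def test_constant_epoch_zero_after_baseline(self):
        x = np.full((3, len(CH), T.size), 7.5)
        sets = erp.make_epochs(x, T, CH, make_trials(3), np.ones(3, bool),
                               preprocessed=True)
        for es in sets.values():
            assert np.abs(es.epochs).max() < 1e-6


class TestScreenArtifacts:
    def _clean_set(self, n=20, seed=0):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1.0, (n, len(CH), 228))
        return erp.EEGEpochSet("none", x, np.arange(228.0), list(CH),
                               np.arange(n))

    def test_clean_set_untouched(self):
        es = self._clean_set()
        cleaned, report = erp.screen_artifacts(es)
        assert report["bad_channels"] == []
        assert report["dropped_epochs"] == []
        assert cleaned.n_epochs == es.n_epochs

    def test_high_variance_channel_interpolated_and_named(self):
        es = self._clean_set()
        ci = es.channels.index("C3")
        es.epochs[:, ci, :] *= 100.0
        before = es.epochs[:, ci, :].copy()
        cleaned, report = erp.screen_artifacts(es)
        assert report["bad_channels"] == ["C3"]
        assert not np.allclose(cleaned.epochs[:, ci, :], before)

    def test_spike_epoch_dropped(self):
        es = self._clean_set()
        es.epochs[4, es.channels.index("Pz"), 100] += 10 * np.ptp(es.epochs)
        cleaned, report = erp.screen_artifacts(es)
        assert report["dropped_epochs"] == [4]
        assert cleaned.n_epochs == es.n_epochs - 1

    def test_majority_bad_channels_flag_subject(self):
        es = self._clean_set()
        for name in ("Fz", "Cz", "Pz", "Oz", "P3"):
            es.epochs[:, es.channels.index(name), :] *= 100.0
        _, report = erp.screen_artifacts(es)
        assert report["subject_failure"]


def epoch_set_from_values(x, condition="none"):
    """(n_epochs, n_samples) values on a flat trace -> single-channel-like set."""
    n, m = x.shape
    epochs = np.zeros((n, len(CH), m))
    epochs[:, CH.index("Pz"), :] = x
    return erp.EEGEpochSet(condition, epochs, np.arange(m) * (25 / 3), list(CH),
                           np.arange(n))


class TestKDEWeightedAverage:
    def test_identical_epochs_reproduce_epoch_with_zero_uncertainty(self):
        x = np.tile(np.sin(np.arange(50) / 5.0), (8, 1))
        est = erp.kde_weighted_erp(epoch_set_from_values(x), n_bootstrap=30,
                                   seed=0)
        pz = est.channels.index("Pz")
        np.testing.assert_allclose(est.mean[pz], x[0], atol=1e-7)
        assert np.nanmax(est.uncertainty[pz]) < 1e-7

    def test_symmetric_values_give_arithmetic_mean(self):
        x = np.array([[-1.0], [0.0], [1.0]])
        m = erp.kde_weighted_mean(x)
        assert m[0] == pytest.approx(0.0, abs=1e-12)

    def test_outlier_down_weighted_relative_to_arithmetic_mean(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 20), [100.0]])
        wm = erp.kde_weighted_mean(vals[:, None])[0]
        am = vals.mean()
        assert abs(wm) < abs(am)

    def test_converges_to_arithmetic_mean_on_homogeneous_data(self, rng):
        x = rng.normal(10.0, 1.0, (200, 20))
        wm = erp.kde_weighted_mean(x)
        am = x.mean(axis=0)
        assert np.max(np.abs(wm - am)) < 0.02 * 10.0

    def test_bootstrap_uncertainty_scales_inverse_sqrt_n(self, rng):
        x_small = rng.normal(0, 1.0, (20, 40))
        x_big = rng.normal(0, 1.0, (80, 40))
        u_small = erp.kde_weighted_erp(epoch_set_from_values(x_small),
                                       n_bootstrap=150, seed=1)
        u_big = erp.kde_weighted_erp(epoch_set_from_values(x_big),
                                     n_bootstrap=150, seed=2)
        pz = CH.index("Pz")
        ratio = (np.mean(u_small.uncertainty[pz])
                 / np.mean(u_big.uncertainty[pz]))
        assert ratio == pytest.approx(2.0, abs=0.5)

    def test_single_epoch_flagged_degenerate(self):
        x = np.ones((1, 30))
        est = erp.kde_weighted_erp(epoch_set_from_values(x), n_bootstrap=10,
                                   seed=0)
        assert est.degenerate
        np.testing.assert_allclose(est.mean[CH.index("Pz")], 1.0)


def erp_estimate_from_trace(trace, times, unc_at=None):
    """Wrap a Pz trace (+optional constant replicate spread) as ERPEstimate."""
    n_ch = len(CH)
    mean = np.zeros((n_ch, times.size))
    pz = CH.index("Pz")
    mean[pz] = trace
    reps = {}
    unc = np.full((n_ch, times.size), np.nan)
    if unc_at is not None:
        c = unc_at / np.sqrt(2.0)
        reps["Pz"] = np.vstack([trace + c, trace - c])
        unc[pz] = unc_at
    return erp.ERPEstimate(mean, unc, times, list(CH), 10, 2, reps)


class TestExtractP3:
    times = -900.0 + np.arange(228) * (25 / 3)

    def test_noise_free_gaussian_bump(self):
        trace = 6.0 * np.exp(-0.5 * ((self.times - 500.0) / 60.0) ** 2)
        m = erp.extract_p3(erp_estimate_from_trace(trace, self.times, 0.5))
        assert m.latency == pytest.approx(500.0, abs=25 / 3)
        assert 0.8 * 6.0 < m.amplitude < 6.0  # window average below bump max

    def test_triangular_peak_closed_form_latency_uncertainty(self):
        peak_t, height, slope = 500.0, 6.0, 0.02  # AU per ms
        trace = np.maximum(0.0, height - slope * np.abs(self.times - peak_t))
        u = 0.4
        m = erp.extract_p3(erp_estimate_from_trace(trace, self.times, u))
        # level set at height-u has half-width u/slope on each side
        peak_sample_t = self.times[np.argmax(trace)]
        assert m.latency == pytest.approx(peak_sample_t)
        expected = u / slope + (peak_t - peak_sample_t) * 0  # symmetric triangle
        assert m.latency_uncertainty == pytest.approx(expected, rel=0.15)

    def test_flat_zero_trace_degenerate(self):
        trace = np.zeros(self.times.size)
        m = erp.extract_p3(erp_estimate_from_trace(trace, self.times, 0.0))
        assert m.amplitude == 0.0
        assert m.degenerate

    def test_window_not_covered_raises(self):
        times = np.arange(0.0, 200.0, 8.0)
        with pytest.raises(ValueError):
            erp.extract_p3(erp_estimate_from_trace(np.ones(times.size), times))


class TestSNR:
    def test_definition_arithmetic(self):
        m = erp.P3Metrics(6.0, 2.0, 500.0, 10.0)
        assert erp.snr_transform(m) == pytest.approx(3.0)

    def test_zero_amplitude_gives_zero(self):
        m = erp.P3Metrics(0.0, 2.0, 500.0, 10.0)
        assert erp.snr_transform(m) == 0.0

    def test_zero_uncertainty_flagged_not_infinite(self):
        m = erp.P3Metrics(6.0, 0.0, 500.0, 10.0)
        assert np.isnan(erp.snr_transform(m))
        assert m.degenerate

    def test_scale_invariance_through_full_estimate(self, rng):
        base = rng.normal(0, 1.0, (30, 228))
        bump = 5.0 * np.exp(-0.5 * ((self_times() - 450.0) / 60.0) ** 2)
        x = base + bump
        m1 = erp.extract_p3(erp.kde_weighted_erp(epoch_set_from_values(x),
                                                 n_bootstrap=80, seed=3))
        m2 = erp.extract_p3(erp.kde_weighted_erp(epoch_set_from_values(2 * x),
                                                 n_bootstrap=80, seed=3))
        assert m2.amplitude == pytest.approx(2 * m1.amplitude, rel=1e-6)
        assert m2.snr_amplitude == pytest.approx(m1.snr_amplitude, rel=1e-6)


def self_times():
    return -900.0 + np.arange(228) * (25 / 3)
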