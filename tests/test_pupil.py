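"""Pupil pipeline: blink handling, QC boundaries, alignment, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antpupil import pupil
from antpupil.io_eyelink import TrialRecord, TrialTrace


def grid(n=2000, t0=0.0):
    return t0 + np.arange(n) * 2.0


class TestDetectBlinks:
    def test_smooth_trace_gives_no_intervals(self):
        t = grid(500)
        x = 3000 + np.sin(t / 300.0)
        assert pupil.detect_blinks(t, x) == []

    def test_gap_padded_by_160ms_each_side(self):
        t = grid(1000)
        x = np.full(1000, 3000.0) + np.sin(t / 300.0)
        x[400:450] = np.nan  # 100 ms gap at t = [800, 900)
        ivs = pupil.detect_blinks(t, x)
        assert len(ivs) == 1
        s, e = ivs[0]
        assert (s, e) == (800.0 - 160.0, 900.0 + 160.0)
        assert e - s == pytest.approx(420.0)

    def test_overlapping_padded_gaps_merge(self):
        t = grid(1000)
        x = np.full(1000, 3000.0) + np.sin(t / 300.0)
        x[300:310] = np.nan   # [600, 620)
        x[400:410] = np.nan   # [800, 820): padded intervals overlap
        ivs = pupil.detect_blinks(t, x)
        assert ivs == [(600.0 - 160.0, 820.0 + 160.0)]

    def test_merge_matches_interval_union_oracle(self, rng):
        for _ in range(50):
            raw = [(float(a), float(a + d)) for a, d in
                   zip(rng.uniform(0, 500, 6), rng.uniform(5, 80, 6))]
            merged = pupil.merge_intervals(raw)
            # oracle: membership function on a fine grid
            gridpts = np.arange(-10, 650, 0.5)
            member = np.zeros(gridpts.size, bool)
            for s, e in raw:
                member |= (gridpts >= s) & (gridpts < e)
            member2 = np.zeros(gridpts.size, bool)
            for s, e in merged:
                member2 |= (gridpts >= s) & (gridpts < e)
            assert np.array_equal(member, member2)
            assert all(a[1] < b[0] for a, b in zip(merged, merged[1:]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 500), st.floats(1, 100)),
                    min_size=1, max_size=8))
    def test_merged_intervals_are_disjoint_and_cover_inputs(self, raw):
        ivs = [(s, s + d) for s, d in raw]
        merged = pupil.merge_intervals(ivs)
        assert all(a[1] < b[0] for a, b in zip(merged, merged[1:]))
        for s, e in ivs:
            assert any(ms <= s and e <= me for ms, me in merged)

    def test_derivative_detector_catches_abrupt_jump(self):
        t = grid(1000)
        x = np.full(1000, 3000.0) + 0.3 * np.sin(t / 100.0)
        x[500:520] += 200.0  # recorded (not missing) blink artifact
        ivs = pupil.detect_blinks(t, x)
        assert any(s <= t[500] <= e for s, e in ivs)


class TestInterpolateBlinks:
    def test_no_intervals_leaves_trace_untouched(self):
        t = grid(100)
        x = np.sin(t)
        filled, frac, failed = pupil.interpolate_blinks(t, x, [])
        np.testing.assert_array_equal(filled, x)
        assert frac == 0.0 and not failed

    def test_interior_gap_linear_closed_form(self):
        t = np.arange(7) * 2.0
        x = np.array([10.0, np.nan, np.nan, np.nan, np.nan, 20.0, 20.0])
        filled, frac, _ = pupil.interpolate_blinks(t, x, [(2.0, 10.0)])
        np.testing.assert_allclose(filled[1:5], [12.0, 14.0, 16.0, 18.0])
        assert frac == pytest.approx(4 / 7)

    def test_edge_gap_constant_fill(self):
        t = np.arange(6) * 2.0
        x = np.array([np.nan, np.nan, 7.0, 7.5, 8.0, 8.5])
        filled, _, _ = pupil.interpolate_blinks(t, x, [(0.0, 4.0)])
        np.testing.assert_allclose(filled[:2], [7.0, 7.0])

    def test_only_samples_inside_intervals_modified(self, rng):
        t = grid(400)
        x = 3000 + rng.normal(0, 1, 400)
        ivs = [(100.0, 180.0), (500.0, 570.0)]
        filled, _, _ = pupil.interpolate_blinks(t, x, ivs)
        inside = np.zeros(400, bool)
        for s, e in ivs:
            inside |= (t >= s) & (t < e)
        np.testing.assert_array_equal(filled[~inside], x[~inside])

    def test_no_valid_samples_sets_failed(self):
        t = grid(10)
        x = np.full(10, np.nan)
        _, frac, failed = pupil.interpolate_blinks(t, x, [])
        assert failed and frac == 1.0


class TestQCBoundaries:
    def test_fraction_just_below_threshold_usable(self):
        assert pupil.qc_reject(0.44, False, False, True) == set()

    def test_fraction_at_threshold_rejected(self):
        assert pupil.qc_reject(0.45, False, False, True) == {"over_interpolated"}

    def test_incorrect_rejected_regardless_of_fraction(self):
        assert "incorrect" in pupil.qc_reject(0.0, False, False, False)
        assert "incorrect" in pupil.qc_reject(0.0, False, False, None)

    def test_participant_all_usable_included(self):
        counts = {k: 10 for k in ("none", "center", "spatial",
                                  "congruent", "incongruent")}
        assert pupil.participant_qc(counts, {k: 10 for k in counts})

    def test_participant_one_starved_condition_excluded(self):
        total = {k: 96 for k in ("none", "center", "spatial",
                                 "congruent", "incongruent")}
        usable = dict(total)
        usable["spatial"] = 9  # under 15%
        assert not pupil.participant_qc(usable, total)

    def test_participant_exactly_15pct_included(self):
        total = {k: 100 for k in ("none", "center", "spatial",
                                  "congruent", "incongruent")}
        usable = {k: 15 for k in total}
        assert pupil.participant_qc(usable, total)


def make_trace(value=None, fn=None, fix=600.0, rt=600.0, correct=True):
    start = 0.0
    cue = start + fix
    t = grid(2000, start)
    if fn is None:
        x = np.full(2000, value if value is not None else 3000.0)
    else:
        x = fn(t)
    tr = TrialRecord(0, "center", "congruent", fix, cue, cue + 500.0,
                     rt=rt, response_time=cue + 500.0 + rt, correct=correct)
    return TrialTrace(tr, t, x, [], False)


class TestAlignAndBaseline:
    def test_constant_trace_baselines_to_zero(self):
        trace = make_trace(value=3000.0)
        ep = pupil.align_and_baseline(trace, trace.pupil, "cue")
        assert ep.baseline_value == pytest.approx(3000.0)
        sel = np.isfinite(ep.trace)
        np.testing.assert_allclose(ep.trace[sel], 0.0, atol=1e-9)

    def test_baseline_correction_idempotent(self):
        trace = make_trace(fn=lambda t: 3000.0 + 0.01 * t)
        ep1 = pupil.align_and_baseline(trace, trace.pupil, "cue")
        trace2 = make_trace(fn=lambda t: 3000.0 + 0.01 * t)
        trace2.pupil = trace2.pupil - ep1.baseline_value
        ep2 = pupil.align_and_baseline(trace2, trace2.pupil, "cue")
        sel = np.isfinite(ep1.trace) & np.isfinite(ep2.trace)
        np.testing.assert_allclose(ep1.trace[sel], ep2.trace[sel], atol=1e-9)

    def test_target_lands_at_plus_500(self):
        # bump exactly at target onset shows up at +500 ms cue-aligned
        fix = 600.0
        target_abs = fix + 500.0

        def fn(t):
            return 3000.0 + np.where(np.abs(t - target_abs) < 1.0, 50.0, 0.0)

        trace = make_trace(fn=fn, fix=fix)
        ep = pupil.align_and_baseline(trace, trace.pupil, "cue")
        i = int(np.nanargmax(ep.trace))
        assert ep.times[i] == pytest.approx(500.0)

    def test_response_zero_matches_cue_timeline(self):
        # response-aligned t=0 must equal cue-aligned t = 500 + RT
        fix, rt = 800.0, 634.0
        resp_abs = fix + 500.0 + rt

        def fn(t):
            return 3000.0 + np.where(np.abs(t - resp_abs) < 1.0, 50.0, 0.0)

        trace = make_trace(fn=fn, fix=fix, rt=rt)
        ep_cue = pupil.align_and_baseline(trace, trace.pupil, "cue")
        ep_resp = pupil.align_and_baseline(trace, trace.pupil, "response")
        i_cue = int(np.nanargmax(ep_cue.trace))
        i_resp = int(np.nanargmax(ep_resp.trace))
        assert ep_cue.times[i_cue] == pytest.approx(500.0 + rt)
        assert ep_resp.times[i_resp] == pytest.approx(0.0)


class TestConditionAverage:
    def _epoch(self, value, cue="center", tgt="congruent"):
        t = np.arange(-400.0, 3500.0, 2.0)
        return pupil.PupilEpoch("cue", t, np.full(t.size, float(value)), 0.0,
                                0.0, set(), 0, cue, tgt)

    def test_single_epoch_mean_is_identity_sem_zero(self):
        avg = pupil.condition_average([self._epoch(5.0)], "cue")
        t, m, sem, n = avg["center"]
        assert n == 1
        np.testing.assert_allclose(m, 5.0)
        np.testing.assert_allclose(sem, 0.0)

    def test_two_epochs_average_to_midpoint(self):
        avg = pupil.condition_average([self._epoch(2.0), self._epoch(6.0)], "cue")
        np.testing.assert_allclose(avg["center"][1], 4.0)

    def test_matches_brute_force_mean(self, rng):
        eps = [self._epoch(v) for v in rng.normal(0, 1, 50)]
        stack = np.vstack([e.trace for e in eps])
        avg = pupil.condition_average(eps, "cue")
        np.testing.assert_allclose(avg["center"][1], stack.mean(axis=0))

    def test_unusable_epochs_excluded(self):
        bad = self._epoch(100.0)
        bad.qc_flags.add("incorrect")
        avg = pupil.condition_average([self._epoch(1.0), bad], "cue")
        np.testing.assert_allclose(avg["center"][1], 1.0)


class TestPupilPeak:
    def test_noise_free_bump(self):
        t = np.arange(-400.0, 3500.0, 2.0)
        x = 12.0 * np.exp(-0.5 * ((t - 1200.0) / 150.0) ** 2)
        m = pupil.pupil_peak(t, x, (500.0, 3498.0), latency_offset=500.0)
        assert m.peak_amplitude == pytest.approx(12.0, abs=1e-3)
        assert m.peak_latency == pytest.approx(700.0, abs=2.0)

    def test_monotone_trace_peaks_at_window_end(self):
        t = np.arange(0.0, 1500.0, 2.0)
        m = pupil.pupil_peak(t, t / 100.0, (0.0, 1498.0))
        assert m.peak_latency == pytest.approx(1498.0)

    def test_ties_break_to_earliest(self):
        t = np.arange(0.0, 100.0, 2.0)
        x = np.zeros(t.size)
        x[[10, 20]] = 5.0
        m = pupil.pupil_peak(t, x, (0.0, 98.0))
        assert m.peak_latency == pytest.approx(t[10])

    def test_empty_window_raises(self):
        t = np.arange(0.0, 100.0, 2.0)
        with pytest.raises(ValueError):
            pupil.pupil_peak(t, np.zeros(t.size), (200.0, 300.0))
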