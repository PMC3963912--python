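"""Diameter tracing, spike detection, and frequency computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ductokym.contract import (ContractionEvent, DiameterTrace,
                               _resolve_conflicts, contraction_frequency,
                               detect_contractions, frequency_profile,
                               trace_diameter)
from ductokym.kymo import Kymograph, extract_kymograph
from ductokym.simdata import simulate_movie
from _util import small_params, vline


def _trace_of(stack, col=64.0, lo=8.0, hi=56.0):
    return trace_diameter(extract_kymograph(stack, vline(col, lo, hi)))


def _synthetic_trace(depths_at, n=60, baseline=30.0, dt=1.0):
    """A hand-built diameter trace with triangular dips of given depths."""
    d = np.full(n, baseline)
    for t, depth in depths_at:
        d[t] -= depth
        d[t - 1] -= depth / 2
        d[t + 1] -= depth / 2
    times = np.arange(n) * dt
    return DiameterTrace(times_s=times, diameter_px=d,
                         baseline_px=np.full(n, baseline),
                         noise_sd_px=0.0, frame_interval_s=dt,
                         line_id="synth")


class TestTraceDiameter:
    def test_constant_diameter_is_recovered_within_half_pixel(self):
        p = small_params(contraction_amplitude_frac=0.0, noise_sd=0.0,
                         duration_s=20.0)
        stack, _ = simulate_movie(p)
        trace = _trace_of(stack)
        assert trace.gap_fraction == 0.0
        assert np.all(np.abs(trace.diameter_px - 28.0) < 0.5)

    def test_trough_depth_matches_amplitude_at_fine_time_resolution(self):
        # 7 fps samples the raised-cosine peak; depth = A * D0
        p = small_params(noise_sd=0.0, frame_interval_s=1 / 7,
                         duration_s=40.0)
        stack, _ = simulate_movie(p)
        trace = _trace_of(stack)
        depth = np.max(trace.baseline_px - trace.diameter_px)
        assert depth == pytest.approx(0.2 * 28.0, abs=0.5)

    def test_trace_is_invariant_to_affine_intensity_rescaling(self, fig1_stack):
        kym = extract_kymograph(fig1_stack, vline(96.0, 10.0, 86.0))
        scaled = Kymograph(matrix=0.5 * kym.matrix + 0.1,
                           sample_spacing_px=kym.sample_spacing_px,
                           frame_interval_s=kym.frame_interval_s,
                           line=kym.line)
        t1, t2 = trace_diameter(kym), trace_diameter(scaled)
        np.testing.assert_allclose(t2.diameter_px, t1.diameter_px,
                                   atol=1e-9)

    def test_untrackable_walls_raise(self):
        flat = Kymograph(matrix=np.full((40, 20), 0.8),
                         sample_spacing_px=1.0, frame_interval_s=1.0,
                         line=vline(0.0, 0.0, 39.0))
        with pytest.raises(ValueError, match="not trackable"):
            trace_diameter(flat)


class TestDetection:
    def test_flat_trace_has_no_events(self):
        trace = _synthetic_trace([])
        assert detect_contractions(trace) == []

    def test_fig1_events_match_ground_truth_within_one_frame(
            self, fig1_stack, fig1_truth):
        trace = _trace_of(fig1_stack, col=96.0, lo=10.0, hi=86.0)
        events = detect_contractions(trace)
        assert len(events) == 30
        # pulse trough lags onset by half the 3 s pulse width
        expected = fig1_truth.event_times_by_station[96] + 1.5
        detected = np.array([e.time_s for e in events])
        assert np.max(np.abs(detected - expected)) <= 1.0

    def test_conflicting_events_keep_the_deeper(self):
        # two pulses 2 s apart, resolvable at dt=0.25 s, min interval 3 s
        trace = _synthetic_trace([(80, 5.0), (88, 3.0)], n=240, dt=0.25)
        events = detect_contractions(trace, min_prominence=1.0,
                                     min_interval_s=3.0)
        assert len(events) == 1
        assert events[0].time_s == pytest.approx(20.0, abs=0.5)

    def test_equal_depth_conflicts_keep_the_earlier(self):
        trace = _synthetic_trace([(80, 4.0), (88, 4.0)], n=240, dt=0.25)
        events = detect_contractions(trace, min_prominence=1.0,
                                     min_interval_s=3.0,
                                     refine_times=False)
        assert len(events) == 1
        assert events[0].time_s == pytest.approx(20.0, abs=0.5)

    def test_well_separated_events_are_all_kept(self):
        trace = _synthetic_trace([(10, 4.0), (20, 3.0), (30, 5.0)])
        events = detect_contractions(trace, min_prominence=1.0,
                                     min_interval_s=3.0)
        assert len(events) == 3

    def test_short_trace_is_rejected(self):
        trace = _synthetic_trace([], n=5)
        with pytest.raises(ValueError, match="shorter"):
            detect_contractions(trace, min_interval_s=3.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 80),
                              st.integers(1, 50)),
                    min_size=1, max_size=12, unique_by=lambda t: t[0]),
           st.integers(1, 10))
    def test_conflict_resolution_is_deep_first_and_maximal(self, cands, gap):
        """Accepted events are pairwise separated; every rejected candidate
        conflicts with an accepted one that is deeper, or equally deep and
        earlier."""
        cands = sorted(cands)
        idx = np.array([c[0] for c in cands])
        depth = np.array([float(c[1]) for c in cands])
        chosen = _resolve_conflicts(idx, depth, gap)
        chosen_depth = {i: depth[list(idx).index(i)] for i in chosen}
        for a in chosen:
            for b in chosen:
                assert a == b or abs(a - b) >= gap
        for i, d in zip(idx, depth):
            if i in chosen:
                continue
            blockers = [c for c in chosen if abs(c - i) < gap]
            assert blockers
            assert any(chosen_depth[c] > d
                       or (chosen_depth[c] == d and c < i)
                       for c in blockers)


class TestFrequency:
    def test_events_every_8s_over_240s_give_7_5_bpm(self):
        events = np.arange(0.0, 240.0, 8.0)
        assert contraction_frequency(events, 0.0, 240.0) == 7.5

    def test_empty_window_gives_zero(self):
        assert contraction_frequency([], 0.0, 120.0) == 0.0

    def test_12_events_in_120s_give_6_bpm(self):
        events = np.linspace(5, 115, 12)
        assert contraction_frequency(events, 0.0, 120.0) == 6.0

    def test_invalid_window_is_rejected(self):
        with pytest.raises(ValueError):
            contraction_frequency([], 10.0, 10.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), max_size=30),
           st.floats(0, 40), st.floats(40, 70), st.floats(70, 100))
    def test_half_open_windows_partition_event_counts(self, times, a, b, c):
        events = [ContractionEvent(time_s=t, prominence_px=1.0, width_s=1.0)
                  for t in times]

        def count(lo, hi):
            if hi <= lo:
                return 0
            return round(contraction_frequency(events, lo, hi)
                         * (hi - lo) / 60.0)

        assert count(a, c) == count(a, b) + count(b, c)


class TestFrequencyProfile:
    def test_single_line_has_zero_difference(self, fig1_stack):
        prof = frequency_profile(fig1_stack, [vline(96.0, 10.0, 86.0)])
        assert len(prof.table) == 1
        assert prof.max_pairwise_diff_bpm == 0.0

    def test_peristaltic_stations_agree_despite_lag(self, peristaltic):
        stack, _ = peristaltic
        lines = [vline(c, 10.0, 86.0) for c in (40.0, 96.0, 150.0)]
        prof = frequency_profile(stack, lines)
        assert prof.max_pairwise_diff_bpm == 0.0
        assert (prof.table["bpm"] == prof.table["bpm"].iloc[0]).all()

    def test_requires_a_transverse_line(self, fig1_stack):
        from ductokym.stackio import AnalysisLine
        longitudinal = AnalysisLine(id="cl", kind="longitudinal",
                                    endpoints=((5.0, 48.0), (180.0, 48.0)))
        with pytest.raises(ValueError, match="transverse"):
            frequency_profile(fig1_stack, [longitudinal])
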