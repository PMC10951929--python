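"""Trajectory curves: smoothing, extrema, key-stage assignment, durations."""

import numpy as np
import pytest

from cyclemap.trajectory import (KeyEvents, assign_key_stages,
                                 duration_from_troughs,
                                 estimate_cycle_duration, find_extrema,
                                 infer_lateS_time, running_average,
                                 smooth_bspline)


class TestSmoothing:
    def test_bspline_preserves_constants(self):
        curve = smooth_bspline(np.full(20, 3.5))
        np.testing.assert_allclose(curve.smoothed, 3.5)

    def test_zero_smoothing_interpolates(self):
        rng = np.random.default_rng(0)
        y = rng.random(15)
        curve = smooth_bspline(y, smoothing_factor=0.0)
        np.testing.assert_allclose(curve.smoothed, y, atol=1e-8)

    def test_denoises_a_sine(self):
        rng = np.random.default_rng(1)
        t = np.arange(120)
        clean = np.sin(2 * np.pi * t / 60)
        noisy = clean + 0.3 * rng.standard_normal(len(t))
        curve = smooth_bspline(noisy)
        assert (np.sqrt(np.mean((curve.smoothed - clean) ** 2))
                < np.sqrt(np.mean((noisy - clean) ** 2)))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_bspline(np.arange(5.0))

    def test_running_average_identity_and_constant(self):
        y = np.array([1.0, 4.0, 2.0, 8.0])
        np.testing.assert_array_equal(running_average(y, 1).smoothed, y)
        np.testing.assert_allclose(running_average(np.full(9, 2.0), 4).smoothed,
                                   2.0)

    def test_running_average_window_mean(self):
        curve = running_average(np.array([0.0, 0, 10, 0, 0]), 5)
        assert curve.smoothed[2] == 2.0

    def test_running_average_window_validation(self):
        with pytest.raises(ValueError):
            running_average(np.arange(3.0), 5)


class TestFindExtrema:
    def test_monotone_curve_has_no_interior_extrema(self):
        peaks, troughs = find_extrema(np.linspace(0, 5, 30))
        assert len(peaks) == 0 and len(troughs) == 0

    @pytest.mark.parametrize("cycles,expected", [(1, 1), (2, 2), (3, 3)])
    def test_sine_extrema_counts_match_calculus(self, cycles, expected):
        t = np.linspace(0, cycles * 2 * np.pi, cycles * 100 + 1)
        peaks, troughs = find_extrema(np.sin(t), min_prominence=0.5)
        assert len(peaks) == expected
        assert len(troughs) in (expected - 1, expected)  # last trough at edge

    def test_negation_swaps_peaks_and_troughs(self):
        rng = np.random.default_rng(2)
        y = running_average(rng.standard_normal(80), 5).smoothed
        p1, t1 = find_extrema(y, min_prominence=0.1)
        p2, t2 = find_extrema(-y, min_prominence=0.1)
        np.testing.assert_array_equal(p1, t2)
        np.testing.assert_array_equal(t1, p2)


def _worked_curve():
    """Piecewise landscape: deep M troughs at 10/210, G1 peak at 60 (height 1),
    early-S trough at 100 (0.3), late-S peak at 150 (height 2)."""
    knots_x = [0, 10, 60, 100, 150, 210, 230]
    knots_y = [0.5, -2.0, 1.0, 0.3, 2.0, -2.2, 0.0]
    x = np.arange(231)
    return np.interp(x, knots_x, knots_y)


class TestKeyStages:
    def test_worked_curve_assignment(self):
        events = assign_key_stages(_worked_curve())
        assert sorted(events.frames_of("M")) == [10, 210]
        assert events.frames_of("G1") == [60]
        assert events.frames_of("earlyS") == [100]
        assert events.frames_of("lateS") == [150]
        assert infer_lateS_time(events) == 150

    def test_monotone_segment_yields_empty_assignment(self):
        with pytest.warns(UserWarning):
            events = assign_key_stages(np.linspace(0, 3, 50))
        assert events.assignments == {}
        with pytest.raises(ValueError):
            infer_lateS_time(events)

    def test_single_interior_peak_is_late_s(self):
        x = np.arange(101)
        y = np.interp(x, [0, 10, 50, 90, 100], [0.0, -2.0, 1.5, -2.0, 0.0])
        events = assign_key_stages(y)
        assert events.frames_of("lateS") == [50]
        assert events.frames_of("G1") == []

    def test_inflections_lie_between_cycle_boundaries(self):
        events = assign_key_stages(smooth_bspline(_worked_curve()))
        assert np.all(events.inflections > 10)
        assert np.all(events.inflections < 210)


class TestCycleDuration:
    def test_duration_arithmetic(self):
        assert np.isclose(duration_from_troughs(12, 213, 5.9), 19.765)
        assert duration_from_troughs(0, 60, 60.0) == 60.0

    def test_noiseless_sawtooth_recovers_exact_period(self):
        period = 40
        t = np.arange(2 * period + 12)
        saw = (t - 6) % period
        est = estimate_cycle_duration(saw.astype(float), frame_interval=5.9)
        assert est == period * 5.9 / 60

    def test_invariant_to_offset_and_scale(self):
        rng = np.random.default_rng(3)
        t = np.arange(140)
        y = np.sin(2 * np.pi * t / 60) + 0.05 * rng.standard_normal(len(t))
        a = estimate_cycle_duration(y, 5.9)
        b = estimate_cycle_duration(100 + 7 * y, 5.9)
        assert a == b

    def test_fewer_than_two_troughs_gives_none(self):
        assert estimate_cycle_duration(np.linspace(0, 1, 50), 5.9) is None

    def test_deepest_selection_prefers_lowest_troughs(self):
        # deep troughs at 20/80, a shallower but *more prominent-looking*
        # wiggle would not displace them under the deepest rule
        x = np.arange(101)
        y = np.interp(x, [0, 20, 50, 80, 100], [1.0, -3.0, 1.0, -3.0, 1.0])
        y += 0.2 * np.sin(x)
        est = estimate_cycle_duration(y, frame_interval=60.0, window=3,
                                      select="deepest")
        assert est is not None and abs(est - 60.0) <= 2.0

    def test_unknown_selection_rejected(self):
        with pytest.raises(ValueError):
            estimate_cycle_duration(np.zeros(30), 5.9, select="median")
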