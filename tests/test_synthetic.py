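"""The synthetic movie generator: stage geometry, rendering, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclemap.data import STAGES
from cyclemap.synthetic import (SyntheticConfig, phase_to_stage,
                                phases_to_stages, render_cell,
                                simulate_dataset, simulate_trajectory)


class TestPhaseToStage:
    def test_birth_is_g1_and_end_is_m(self):
        assert phase_to_stage(0.0) == "G1"
        assert phase_to_stage(0.999) == "M"

    def test_uniform_fractions_midpoint_is_late_s(self):
        uniform = {s: 1.0 / 6.0 for s in STAGES}
        # cumulative intervals: lateS spans [0.5, 0.666...)
        assert phase_to_stage(0.5, uniform) == "lateS"

    @pytest.mark.parametrize("bad", [-0.01, 1.0, 1.5])
    def test_rejects_phase_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            phase_to_stage(bad)

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(max_examples=200, deadline=None)
    def test_partitions_unit_interval(self, phase):
        cfg = SyntheticConfig()
        stage = phase_to_stage(phase)
        bounds = cfg.boundaries
        i = STAGES.index(stage)
        assert bounds[i] <= phase < bounds[i + 1] + 1e-12

    def test_fractions_must_sum_to_one(self):
        bad = {s: 0.2 for s in STAGES}
        with pytest.raises(ValueError):
            SyntheticConfig(stage_fractions=bad)


class TestRenderCell:
    def test_deterministic_given_rng_state(self):
        cfg = SyntheticConfig(patch_size=32)
        a = render_cell(0.3, cfg, np.random.default_rng(7))
        b = render_cell(0.3, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("phase", [0.0, 0.2, 0.4, 0.55, 0.8, 0.97])
    def test_pixels_stay_in_unit_range(self, phase):
        cfg = SyntheticConfig(patch_size=24, noise_sigma=0.1)
        img = render_cell(phase, cfg, np.random.default_rng(0))
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert img.shape == (24, 24)

    def test_mitotic_cell_brighter_than_g1_on_average(self):
        cfg = SyntheticConfig(patch_size=32, noise_sigma=0.0)
        rng = np.random.default_rng(0)
        m = render_cell(0.97, cfg, rng).mean()     # condensed, bright
        g1 = render_cell(0.05, cfg, rng).mean()    # small, dim
        assert m > g1


class TestSimulateTrajectory:
    def test_division_occurs_when_frames_exceed_period(self):
        cfg = SyntheticConfig(patch_size=16, n_frames=60, period_frames=40,
                              seed=0)
        _, truth = simulate_trajectory(cfg, np.random.default_rng(0))
        assert len(truth.division_frames) >= 1

    def test_bit_identical_rerun(self):
        cfg = SyntheticConfig(patch_size=16, n_frames=20, period_frames=16)
        t1, g1 = simulate_trajectory(cfg, np.random.default_rng(9))
        t2, g2 = simulate_trajectory(cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(t1.images, t2.images)
        np.testing.assert_array_equal(g1.phase, g2.phase)

    def test_zero_jitter_division_spacing_equals_period(self):
        cfg = SyntheticConfig(patch_size=16, n_frames=96, period_frames=48,
                              period_jitter=0.0, initial_phase_jitter=0.0)
        _, truth = simulate_trajectory(cfg, np.random.default_rng(1))
        assert len(truth.division_frames) == 2
        spacing = np.diff(truth.division_frames)[0]
        assert spacing * cfg.frame_interval == truth.true_period_minutes

    def test_stage_labels_consistent_with_phase(self):
        cfg = SyntheticConfig(patch_size=16, n_frames=30, period_frames=20)
        _, truth = simulate_trajectory(cfg, np.random.default_rng(2))
        np.testing.assert_array_equal(
            truth.stage, phases_to_stages(truth.phase, cfg.stage_fractions))


class TestSimulateDataset:
    def test_cells_are_distinct_and_reproducible(self):
        cfg = SyntheticConfig(patch_size=16, n_frames=10, period_frames=8,
                              seed=4)
        d1 = simulate_dataset(cfg, 3)
        d2 = simulate_dataset(cfg, 3)
        assert len(d1) == 3
        for (a, _), (b, _) in zip(d1, d2):
            np.testing.assert_array_equal(a.images, b.images)
        assert not np.array_equal(d1[0][0].images, d1[1][0].images)

    def test_stage_marginals_approximate_configured_fractions(self):
        cfg = SyntheticConfig(patch_size=16, n_frames=200, period_frames=50,
                              seed=8)
        ds = simulate_dataset(cfg, 20)
        stages = np.concatenate([g.stage for _, g in ds])
        n = len(stages)
        for s in STAGES:
            p = cfg.stage_fractions[s]
            se = np.sqrt(p * (1 - p) / n)
            # generous band: binomial error plus phase-grid discretisation
            assert abs(np.mean(stages == s) - p) < 6 * se + 2.0 / cfg.period_frames
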