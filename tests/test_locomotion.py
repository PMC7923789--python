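"""Block A locomotion descriptors."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormspectra import (
    WormMetrics,
    displacement_metrics,
    effective_area,
    merge_captures,
    treatment_block_a,
    worm_metrics,
)
from conftest import make_track, random_track


class TestDisplacementMetrics:
    def test_three_four_five_step(self):
        track = make_track([0, 3, 3], [0, 4, 4])
        M, t, V = displacement_metrics(track, motion_threshold=0.5)
        assert M == pytest.approx(5.0)
        assert t == pytest.approx(1 / 30)
        assert V == pytest.approx(150.0)

    def test_stationary_track_is_all_zero(self):
        M, t, V = displacement_metrics(make_track([5, 5, 5], [2, 2, 2]))
        assert (M, t, V) == (0.0, 0.0, 0.0)

    def test_fewer_than_two_valid_observations(self):
        track = make_track([0, 3], [0, 4], valid=[True, False])
        assert displacement_metrics(track) == (0.0, 0.0, 0.0)

    def test_steps_across_invalid_gaps_are_skipped(self):
        track = make_track([0, 100, 3], [0, 100, 4], valid=[True, False, True])
        M, t, V = displacement_metrics(track, motion_threshold=0.5)
        assert M == 0.0  # the only adjacent valid pair spans the gap

    def test_matches_brute_force_sum(self, rng):
        track = random_track(rng, n=200)
        threshold = 1.5
        x = track.df["x"].to_numpy()
        y = track.df["y"].to_numpy()
        steps = np.hypot(np.diff(x), np.diff(y))
        expected = steps[steps >= threshold].sum()
        M, t, _ = displacement_metrics(track, motion_threshold=threshold)
        assert M == pytest.approx(expected, rel=1e-12)
        assert t == pytest.approx((steps >= threshold).sum() / 30.0)

    def test_scaling_and_translation(self, rng):
        track = random_track(rng, n=100)
        s = 3.0
        scaled = make_track(s * track.df["x"], s * track.df["y"])
        shifted = make_track(track.df["x"] + 50, track.df["y"] - 20)
        M, _, _ = displacement_metrics(track, motion_threshold=0.0)
        Ms, _, _ = displacement_metrics(scaled, motion_threshold=0.0)
        Mt, _, _ = displacement_metrics(shifted, motion_threshold=0.0)
        assert Ms == pytest.approx(s * M)
        assert Mt == pytest.approx(M)
        assert effective_area(scaled) == pytest.approx(s**2 * effective_area(track))
        assert effective_area(shifted) == pytest.approx(effective_area(track))


class TestEffectiveArea:
    def test_bounding_rectangle(self):
        assert effective_area(make_track([0, 10, 10], [0, 0, 5])) == pytest.approx(50.0)

    def test_single_point_is_zero(self):
        assert effective_area(make_track([4], [4])) == 0.0

    def test_no_valid_observation_raises(self):
        with pytest.raises(ValueError):
            effective_area(make_track([0, 1], [0, 1], valid=[False, False]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4)), min_size=1, max_size=40))
    def test_matches_min_max_oracle(self, points):
        x, y = zip(*points)
        area = effective_area(make_track(x, y))
        assert area == pytest.approx((max(x) - min(x)) * (max(y) - min(y)))


class TestMergeCaptures:
    def _wm(self, M, t, A_m, fps=30.0, active=None):
        return WormMetrics(
            M=M, t=t, V=M / t if t else 0.0, A_m=A_m,
            active=M > 0 if active is None else active, fps=fps,
        )

    def test_sums_and_recomputed_velocity(self):
        merged = merge_captures(self._wm(100, 2, 20), self._wm(50, 1, 30))
        assert merged.M == 150
        assert merged.t == 3
        assert merged.V == pytest.approx(50.0)
        assert merged.A_m == 50
        assert merged.active

    def test_mismatched_fps_rejected(self):
        with pytest.raises(ValueError):
            merge_captures(self._wm(1, 1, 1, fps=30), self._wm(1, 1, 1, fps=25))

    def test_union_area_mode_uses_joint_bounding_box(self):
        a = worm_metrics(make_track([0, 10], [0, 10]))
        b = worm_metrics(make_track([20, 30], [20, 30]))
        merged = merge_captures(a, b, area_mode="union")
        assert merged.A_m == pytest.approx(900.0)  # 30x30 joint box


class TestTreatmentBlockA:
    def test_activity_percentage(self):
        worms = [self_make(M) for M in (10, 10, 10, 0, 0)]
        block = treatment_block_a(worms, activity_threshold_px=5)
        assert block.ACT == pytest.approx(60.0)

    def test_ratio_descriptors(self):
        worms = [self_make(M, A_m=100) for M in (500, 500, 500)]
        block = treatment_block_a(worms, activity_threshold_px=5)
        assert block.M_over_Am == pytest.approx(5.0)
        assert block.M_over_ACT == pytest.approx(1500 / 3)

    def test_movement_per_active_worm(self):
        worms = [self_make(M) for M in (250, 150, 100, 0, 0)]
        block = treatment_block_a(worms, activity_threshold_px=5)
        assert block.M_over_ACT == pytest.approx(500 / 3)

    def test_no_active_worms_gives_zero_ratio(self):
        block = treatment_block_a([self_make(0.0)], activity_threshold_px=5)
        assert block.ACT == 0.0
        assert block.M_over_ACT == 0.0

    def test_act_non_increasing_in_threshold(self, rng):
        worms = [self_make(float(M)) for M in rng.uniform(0, 100, 30)]
        acts = [
            treatment_block_a(worms, activity_threshold_px=thr).ACT
            for thr in (0, 5, 20, 50, 90)
        ]
        assert np.all(np.diff(acts) <= 0)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            treatment_block_a([])


def self_make(M, A_m=10.0):
    return WormMetrics(M=M, t=M / 50 if M else 0.0, V=50.0 if M else 0.0, A_m=A_m, active=M > 0)
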