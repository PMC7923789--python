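"""Generator: dose modulation, behavior simulation, rendering, lethality."""
import numpy as np
import pytest

from wormspectra import (
    BehaviorParams,
    DoseEffectConfig,
    LethalityModel,
    RenderConfig,
    TreatmentSpec,
    dose_effect_params,
    render_video,
    simulate_behavior_track,
    simulate_lethality_assay,
)
from wormspectra.synthetic import STATE_INACTIVE, STATE_RUN, STATE_TURN, GroundTruthTrack

UNIT_EFFECTS = DoseEffectConfig(
    slopes={"turn_rate": 0.5},
    asa_attenuation={0.0: 1.0, 5.0: 0.5, 10.0: 0.25},
    food_dose_scale={"AA": 1.0, "PA": 1.0, "PP": 1.0},
)


class TestDoseEffectParams:
    def test_control_is_identity(self):
        base = BehaviorParams()
        out = dose_effect_params(base, TreatmentSpec(0.0, 0.0, "AA"), UNIT_EFFECTS)
        assert out == base

    def test_linear_nitrite_effect_on_turn_rate(self):
        # effect = 1 - 0.5 * (dose / 10000) => 0.20 * 0.7 at 6000 mg/L
        base = BehaviorParams(turn_rate=0.20)
        out = dose_effect_params(base, TreatmentSpec(0.0, 6000.0, "AA"), UNIT_EFFECTS)
        assert out.turn_rate == pytest.approx(0.14)

    def test_ascorbic_acid_attenuates_multiplicatively(self):
        # attenuation 0.5 halves the nitrite effect: 0.20 * (1 - 0.5*0.5*0.6)
        base = BehaviorParams(turn_rate=0.20)
        out = dose_effect_params(base, TreatmentSpec(5.0, 6000.0, "AA"), UNIT_EFFECTS)
        assert out.turn_rate == pytest.approx(0.17)

    @pytest.mark.parametrize("param", ["turn_rate", "run_bend_amp", "turn_bend_amp", "activity_prob"])
    def test_monotone_in_nitrite_and_asa(self, param):
        base = BehaviorParams()
        cfg = DoseEffectConfig()
        by_dose = [
            getattr(dose_effect_params(base, TreatmentSpec(0.0, d, "AA"), cfg), param)
            for d in (0.0, 1000.0, 3000.0, 6000.0, 10000.0)
        ]
        assert np.all(np.diff(by_dose) <= 1e-12)
        by_asa = [
            getattr(dose_effect_params(base, TreatmentSpec(a, 6000.0, "AA"), cfg), param)
            for a in (0.0, 5.0, 10.0)
        ]
        assert np.all(np.diff(by_asa) >= -1e-12)  # asa pulls back toward baseline

    def test_rejects_modulation_leaving_valid_range(self):
        cfg = DoseEffectConfig(slopes={"turn_bend_amp": 0.9})
        with pytest.raises(ValueError):
            dose_effect_params(BehaviorParams(), TreatmentSpec(0.0, 10000.0, "AA"), cfg)


class TestBehaviorTrack:
    def test_inactive_worm_never_moves(self):
        track = simulate_behavior_track(BehaviorParams(activity_prob=0.0), 10, 30, seed=3)
        assert set(track.state) == {STATE_INACTIVE}
        assert np.ptp(track.x) == 0 and np.ptp(track.y) == 0
        assert np.ptp(track.length_fraction) == 0

    def test_pure_run_path_length_is_speed_times_time(self):
        params = BehaviorParams(turn_rate=0.0, run_speed=30.0, activity_prob=1.0)
        track = simulate_behavior_track(params, 60, 30, seed=5, speed_cv=0.0)
        path = np.hypot(np.diff(track.x), np.diff(track.y)).sum()
        assert path == pytest.approx(30.0 * 60.0, rel=0.02)

    def test_turn_occupancy_matches_independent_markov_oracle(self):
        # Oracle: per-frame Bernoulli two-state chain, vectorized over replicates.
        fps, duration, n_rep = 10.0, 15.0, 4000
        params = BehaviorParams(turn_rate=0.1, activity_prob=1.0)
        exit_rate = 1.2
        fractions = [
            (simulate_behavior_track(
                params, duration, fps, seed=10_000 + i, turn_exit_rate=exit_rate
            ).state == STATE_TURN).mean()
            for i in range(n_rep)
        ]
        rng = np.random.default_rng(99)
        n_frames = int(duration * fps)
        p_rt, p_tr = params.turn_rate / fps, exit_rate / fps
        turn = np.zeros(n_rep, dtype=bool)
        occupancy = np.zeros(n_rep)
        for _ in range(n_frames - 1):
            u = rng.random(n_rep)
            turn = np.where(turn, u >= p_tr, u < p_rt)
            occupancy += turn
        oracle = occupancy.mean() / n_frames
        assert np.mean(fractions) == pytest.approx(oracle, abs=0.01)

    def test_turn_frames_bend_below_half_length_run_frames_above(self):
        for seed in range(5):
            track = simulate_behavior_track(BehaviorParams(activity_prob=1.0), 30, 30, seed=seed)
            frac = track.length_fraction
            assert np.all(frac[track.state == STATE_TURN] < 0.5)
            assert np.all(frac[track.state == STATE_RUN] >= 0.5)

    def test_identical_seed_gives_bit_identical_track(self):
        a = simulate_behavior_track(BehaviorParams(), 10, 30, seed=42)
        b = simulate_behavior_track(BehaviorParams(), 10, 30, seed=42)
        for attr in ("x", "y", "length_fraction", "state"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_ensemble_dose_monotonicity(self):
        # seed-averaged turn occupancy and displacement never rise with dose
        base = BehaviorParams()
        cfg = DoseEffectConfig()
        occ, disp = [], []
        for dose in (0.0, 3000.0, 10000.0):
            params = dose_effect_params(base, TreatmentSpec(0.0, dose, "AA"), cfg)
            o, d = [], []
            for seed in range(30):
                t = simulate_behavior_track(params, 20, 30, seed=seed)
                o.append((t.state == STATE_TURN).mean())
                d.append(np.hypot(np.diff(t.x), np.diff(t.y)).sum())
            occ.append(np.mean(o))
            disp.append(np.mean(d))
        assert np.all(np.diff(occ) <= 0)
        assert np.all(np.diff(disp) <= 0)


class TestRendering:
    def test_out_of_bounds_track_names_offending_frame(self):
        track = GroundTruthTrack(
            frame_index=[0, 1], x=[128.0, 5.0], y=[128.0, 5.0],
            length_fraction=[1.0, 1.0], state=["run", "run"], fps=30, body_length_px=100.0,
        )
        with pytest.raises(ValueError, match="frame 1"):
            render_video(track, RenderConfig(), seed=0)

    def test_absent_worm_renders_background_only(self):
        track = GroundTruthTrack(
            frame_index=[0], x=[128.0], y=[128.0],
            length_fraction=[1.0], state=["run"], fps=30, body_length_px=100.0,
        )
        frames = render_video(track, RenderConfig(noise_sd=0), seed=0, present=False)
        assert np.all(frames == 200)

    def test_same_seed_same_frames(self):
        track = simulate_behavior_track(BehaviorParams(), 0.5, 10, seed=8)
        a = render_video(track, RenderConfig(), seed=3)
        b = render_video(track, RenderConfig(), seed=3)
        assert np.array_equal(a, b)


class TestLethalityAssay:
    def test_zero_dose_zero_baseline_kills_nobody(self):
        dead, total = simulate_lethality_assay(
            TreatmentSpec(0.0, 0.0, "AA", n_worms=60),
            LethalityModel(lc50=3000, hill_slope=4),
            seed=1,
        )
        assert (dead, total) == (0, 60)

    def test_mortality_is_half_at_lc50(self):
        model = LethalityModel(lc50=3000, hill_slope=4)
        assert model.mortality(3000.0) == pytest.approx(0.5)
        dead, total = simulate_lethality_assay(
            TreatmentSpec(0.0, 3000.0, "AA", n_worms=100_000),
            model,
            seed=11,
        )
        assert dead / total == pytest.approx(0.5, abs=0.01)

    def test_counts_match_seeded_binomial_oracle(self):
        model = LethalityModel(lc50=3000, hill_slope=4)
        treatment = TreatmentSpec(0.0, 6000.0, "AA", n_worms=60)
        dead, total = simulate_lethality_assay(treatment, model, seed=7)
        p = 1.0 / (1.0 + (3000.0 / 6000.0) ** 4)
        oracle = np.random.default_rng(7).binomial(60, p)
        assert (dead, total) == (oracle, 60)


def test_treatment_grid_is_validated():
    with pytest.raises(ValueError):
        TreatmentSpec(asa_mM=7.0, nitrite_mg_L=0.0, food="AA")
    with pytest.raises(ValueError):
        TreatmentSpec(asa_mM=0.0, nitrite_mg_L=0.0, food="XX")
    off_grid = TreatmentSpec(asa_mM=7.0, nitrite_mg_L=500.0, food="AA", enforce_grid=False)
    assert off_grid.asa_mM == 7.0
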