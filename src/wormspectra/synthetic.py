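"""Ground-truthed synthetic worm behavior, video rendering and lethality assays.

The module emulates the study conditions of a single-worm microwell
exposure experiment: wild-type C. elegans pre-exposed to ascorbic acid
(0/5/10 mM) and then to sodium nitrite (0-10,000 mg/L) under three food
regimes (AA, PA, PP), filmed one minute at 30 fps on a bright field.

Locomotion is a two-state (run/turn) Markov chain. Runs advance the
centroid along a noisy heading; turns reorient it and bend the body.
Posture is encoded as a circular-arc bend amplitude whose chord/arc
ratio is the per-frame "% worm length": turn-state frames always fall
below 50% of body length and run-state frames at or above it, so the
generated ground truth respects the posture-zone semantics downstream
modules rely on. Nitrite dose depresses turn rate, bend amplitudes,
speed and the probability of moving at all; ascorbic acid attenuates
the nitrite effect multiplicatively toward baseline; mortality follows
a two-parameter log-logistic (Hill) dose-response.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._geometry import (
    HALF_LENGTH_BEND,
    arc_points,
    bend_to_length_fraction,
    length_fraction_to_bend,
)

ASA_LEVELS_MM = (0.0, 5.0, 10.0)
NITRITE_LEVELS_MG_L = (0.0, 1000.0, 3000.0, 6000.0, 10000.0)
FOOD_CONDITIONS = ("AA", "PA", "PP")

STATE_RUN = "run"
STATE_TURN = "turn"
STATE_INACTIVE = "inactive"


@dataclass(frozen=True)
class TreatmentSpec:
    """One exposure cell: ascorbic acid (mM), nitrite (mg/L), food regime."""

    asa_mM: float
    nitrite_mg_L: float
    food: str
    n_worms: int = 60
    enforce_grid: bool = True

    def __post_init__(self) -> None:
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")
        if self.food not in FOOD_CONDITIONS:
            raise ValueError(f"food must be one of {FOOD_CONDITIONS}, got {self.food!r}")
        if self.enforce_grid:
            if self.asa_mM not in ASA_LEVELS_MM:
                raise ValueError(
                    f"asa_mM {self.asa_mM} not on the grid {ASA_LEVELS_MM}; "
                    "pass enforce_grid=False to override"
                )
            if self.nitrite_mg_L not in NITRITE_LEVELS_MG_L:
                raise ValueError(
                    f"nitrite_mg_L {self.nitrite_mg_L} not on the grid "
                    f"{NITRITE_LEVELS_MG_L}; pass enforce_grid=False to override"
                )

    @property
    def label(self) -> str:
        return f"asa{self.asa_mM:g}_no2-{self.nitrite_mg_L:g}_{self.food}"


@dataclass(frozen=True)
class BehaviorParams:
    """Generative locomotion parameters for one worm cohort.

    run_speed        px/s advanced per run frame (before per-frame speed noise)
    turn_rate        per-second probability of entering the turn state
    run_bend_amp     circular-arc bend amplitude during runs (chord >= 50% body)
    turn_bend_amp    bend amplitude during turns (chord < 50% body)
    activity_prob    probability the worm moves at all during a capture
    body_length_px   worm arc length in pixels
    """

    run_speed: float = 40.0
    turn_rate: float = 0.20
    run_bend_amp: float = 0.40
    turn_bend_amp: float = 0.90
    activity_prob: float = 0.95
    body_length_px: float = 80.0

    def __post_init__(self) -> None:
        if self.run_speed < 0:
            raise ValueError("run_speed must be >= 0")
        if self.body_length_px <= 0:
            raise ValueError("body_length_px must be > 0")
        for name in ("turn_rate", "run_bend_amp", "turn_bend_amp", "activity_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.turn_bend_amp <= self.run_bend_amp:
            raise ValueError("turn_bend_amp must exceed run_bend_amp")
        # Zone semantics: turn postures must give chords < 50% of body length,
        # run postures >= 50%.
        if self.turn_bend_amp <= HALF_LENGTH_BEND:
            raise ValueError(
                "turn_bend_amp maps to a chord >= 50% of body length; "
                f"needs to exceed {HALF_LENGTH_BEND:.4f}"
            )
        if self.run_bend_amp > HALF_LENGTH_BEND:
            raise ValueError(
                "run_bend_amp maps to a chord < 50% of body length; "
                f"must not exceed {HALF_LENGTH_BEND:.4f}"
            )


@dataclass(frozen=True)
class LethalityModel:
    """Two-parameter log-logistic (Hill) mortality model, optional baseline."""

    lc50: float
    hill_slope: float
    baseline_mortality: float = 0.0

    def __post_init__(self) -> None:
        if self.lc50 <= 0:
            raise ValueError("lc50 must be > 0")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be > 0")
        if not 0.0 <= self.baseline_mortality < 1.0:
            raise ValueError("baseline_mortality must lie in [0, 1)")

    def mortality(self, dose):
        """P(death) at a given dose; equals 0.5 at dose = lc50 when baseline 0."""
        from .dose_response import loglogistic

        p = loglogistic(dose, self.lc50, self.hill_slope)
        return self.baseline_mortality + (1.0 - self.baseline_mortality) * p


@dataclass(frozen=True)
class RenderConfig:
    """Bright-field rendering geometry: dark worm on a light background."""

    width: int = 256
    height: int = 256
    background_intensity: float = 200.0
    worm_intensity: float = 60.0
    noise_sd: float = 4.0
    worm_half_width: float = 2.0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("frame must be at least 8x8 px")
        if not (0 <= self.worm_intensity < self.background_intensity <= 255):
            raise ValueError("need worm_intensity < background_intensity within 0-255")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.worm_half_width <= 0:
            raise ValueError("worm_half_width must be > 0")


@dataclass
class GroundTruthTrack:
    """Per-frame generator truth: centroid, posture fraction and behavior state."""

    frame_index: np.ndarray
    x: np.ndarray
    y: np.ndarray
    length_fraction: np.ndarray
    state: np.ndarray
    fps: float
    body_length_px: float

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.length_fraction = np.asarray(self.length_fraction, dtype=float)
        self.state = np.asarray(self.state, dtype="U8")
        n = len(self.frame_index)
        if not all(len(a) == n for a in (self.x, self.y, self.length_fraction, self.state)):
            raise ValueError("track arrays must share one length")
        if n and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        if np.any((self.length_fraction < 0) | (self.length_fraction > 1)):
            raise ValueError("length_fraction must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "x": self.x,
                "y": self.y,
                "length_fraction": self.length_fraction,
                "state": self.state,
            }
        )


def _default_slopes() -> dict:
    # Per-compound fractional reductions at the reference dose (10,000 mg/L
    # nitrite with no attenuation): turn rate and speed halve, activity drops
    # 40%, bend amplitudes shrink by 25%/20% (keeping turn postures < 50% chord).
    return {
        "turn_rate": 0.5,
        "run_speed": 0.5,
        "activity_prob": 0.4,
        "run_bend_amp": 0.25,
        "turn_bend_amp": 0.2,
    }


def _default_asa_attenuation() -> dict:
    # Multiplicative attenuation of the nitrite effect by ascorbic acid;
    # chosen so LC50 rises >2x at 5 mM and ~3x at 10 mM.
    return {0.0: 1.0, 5.0: 0.45, 10.0: 0.33}


def _default_food_dose_scale() -> dict:
    # Effective-dose scaling per food regime, matching the relative LC50s
    # (~2900 AA, ~3800 PP, ~6500 mg/L PA): food during the ascorbic-acid
    # phase only (PA) is most protective.
    return {"AA": 1.0, "PP": 0.76, "PA": 0.45}


@dataclass(frozen=True)
class DoseEffectConfig:
    """Linear per-compound effect slopes modulating :class:`BehaviorParams`.

    Each affected parameter is multiplied by
    ``1 - attenuation(asa) * food_scale(food) * slope * dose / dose_ref``.
    """

    slopes: Mapping[str, float] = field(default_factory=_default_slopes)
    dose_ref: float = 10000.0
    asa_attenuation: Mapping[float, float] = field(default_factory=_default_asa_attenuation)
    food_dose_scale: Mapping[str, float] = field(default_factory=_default_food_dose_scale)

    def __post_init__(self) -> None:
        valid = {f.name for f in dataclasses.fields(BehaviorParams)}
        for name, slope in self.slopes.items():
            if name not in valid:
                raise ValueError(f"unknown behavior parameter {name!r}")
            if slope < 0:
                raise ValueError("effect slopes must be >= 0 (dose never increases them)")
        if self.dose_ref <= 0:
            raise ValueError("dose_ref must be > 0")
        for v in self.asa_attenuation.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("asa attenuation factors must lie in [0, 1]")

    def effective_dose_fraction(self, treatment: TreatmentSpec) -> float:
        """Nitrite dose scaled by food regime and ascorbic-acid attenuation."""
        atten = self.asa_attenuation.get(treatment.asa_mM)
        if atten is None:
            raise ValueError(f"no attenuation factor for asa_mM={treatment.asa_mM}")
        scale = self.food_dose_scale.get(treatment.food)
        if scale is None:
            raise ValueError(f"no dose scale for food={treatment.food!r}")
        return atten * scale * treatment.nitrite_mg_L / self.dose_ref


def dose_effect_params(
    base: BehaviorParams, treatment: TreatmentSpec, effect_config: DoseEffectConfig | None = None
) -> BehaviorParams:
    """Modulate behavior parameters by the treatment's effective nitrite dose.

    Monotone by construction: higher nitrite never increases turn rate, bend
    amplitudes, speed or activity; ascorbic acid attenuates the nitrite effect
    multiplicatively toward baseline. Raises if modulation pushes a parameter
    out of its valid range.
    """
    cfg = effect_config if effect_config is not None else DoseEffectConfig()
    eff = cfg.effective_dose_fraction(treatment)
    updates = {}
    for name, slope in cfg.slopes.items():
        factor = 1.0 - slope * eff
        if factor < 0:
            raise ValueError(
                f"effect on {name!r} (slope {slope}, effective dose {eff:.3f}) "
                "drives the parameter negative"
            )
        updates[name] = getattr(base, name) * factor
    return dataclasses.replace(base, **updates)  # re-validates ranges/zones


def _geometric_duration(u: float, p: float) -> int:
    """Geometric sojourn on {1, 2, ...} via inverse CDF; monotone in p for fixed u."""
    if p >= 1.0:
        return 1
    return 1 + int(np.log(u) / np.log1p(-p))


def _state_sequence(n: int, p_enter_turn: float, p_exit_turn: float, rng) -> np.ndarray:
    """Alternating run/turn bouts with geometric sojourns; True marks turn frames."""
    turn = np.zeros(n, dtype=bool)
    i = 0
    in_turn = False
    while i < n:
        p = p_exit_turn if in_turn else p_enter_turn
        if p <= 0.0:
            d = n - i
        else:
            d = _geometric_duration(rng.random(), p)
        if in_turn:
            turn[i : i + d] = True
        i += d
        in_turn = not in_turn
    return turn


def _fold(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded coordinate path into [lo, hi] (triangle wave)."""
    span = hi - lo
    w = np.mod(values - lo, 2.0 * span)
    return lo + np.where(w > span, 2.0 * span - w, w)


def simulate_behavior_track(
    params: BehaviorParams,
    duration: float,
    fps: float,
    seed,
    *,
    arena: tuple[tuple[float, float], tuple[float, float]] = ((45.0, 211.0), (45.0, 211.0)),
    turn_exit_rate: float = 1.2,
    run_heading_sd: float = 0.15,
    turn_heading_sd: float = 1.0,
    turn_speed_factor: float = 0.2,
    speed_cv: float = 0.5,
    bend_amp_sd: float = 0.075,
) -> GroundTruthTrack:
    """Simulate one capture of a single worm.

    Draws are split over independent sub-streams (activity, states, headings,
    step sizes, bend noise) so tracks simulated from the same seed under
    different dose-modulated parameters stay tightly coupled — a paired-design
    choice that sharpens dose contrasts at small cohort sizes. Identical
    (params, seed) gives a bit-identical track.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be > 0")
    n = int(round(duration * fps))
    (xlo, xhi), (ylo, yhi) = arena
    if xhi <= xlo or yhi <= ylo:
        raise ValueError("arena bounds must be non-degenerate")

    ss = np.random.SeedSequence(seed)
    rng_act, rng_init, rng_state, rng_head, rng_step, rng_amp = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    frames = np.arange(n)
    x0 = rng_init.uniform(xlo + 0.25 * (xhi - xlo), xhi - 0.25 * (xhi - xlo))
    y0 = rng_init.uniform(ylo + 0.25 * (yhi - ylo), yhi - 0.25 * (yhi - ylo))
    heading0 = rng_init.uniform(-np.pi, np.pi)

    active = rng_act.random() < params.activity_prob
    if not active:
        frac = float(bend_to_length_fraction(params.run_bend_amp))
        return GroundTruthTrack(
            frame_index=frames,
            x=np.full(n, x0),
            y=np.full(n, y0),
            length_fraction=np.full(n, frac),
            state=np.full(n, STATE_INACTIVE, dtype="U8"),
            fps=fps,
            body_length_px=params.body_length_px,
        )

    p_rt = min(params.turn_rate / fps, 1.0)
    p_tr = min(turn_exit_rate / fps, 1.0)
    turn = _state_sequence(n, p_rt, p_tr, rng_state)

    dtheta = rng_head.normal(0.0, 1.0, n) * np.where(turn, turn_heading_sd, run_heading_sd)
    heading = heading0 + np.cumsum(dtheta)

    # Gamma per-frame speed multipliers (mean 1, cv = speed_cv) make the
    # above-threshold step fraction degrade smoothly with dose downstream.
    if speed_cv > 0:
        shape = 1.0 / speed_cv**2
        mult = rng_step.gamma(shape, 1.0 / shape, n)
    else:
        mult = np.ones(n)
    speed = params.run_speed * np.where(turn, turn_speed_factor, 1.0)
    step = speed / fps * mult
    step[0] = 0.0
    x = _fold(x0 + np.cumsum(step * np.cos(heading)), xlo, xhi)
    y = _fold(y0 + np.cumsum(step * np.sin(heading)), ylo, yhi)

    amp = np.where(turn, params.turn_bend_amp, params.run_bend_amp) + rng_amp.normal(
        0.0, bend_amp_sd, n
    )
    # Clip bend noise into the state's posture zone so ground truth always
    # honours turn < 50% body length <= run.
    amp = np.where(
        turn,
        np.clip(amp, HALF_LENGTH_BEND + 1e-6, 1.0),
        np.clip(amp, 0.0, HALF_LENGTH_BEND - 1e-6),
    )
    frac = bend_to_length_fraction(amp)

    state = np.where(turn, STATE_TURN, STATE_RUN).astype("U8")
    return GroundTruthTrack(
        frame_index=frames,
        x=x,
        y=y,
        length_fraction=frac,
        state=state,
        fps=fps,
        body_length_px=params.body_length_px,
    )


def render_video(
    track: GroundTruthTrack, cfg: RenderConfig, seed, *, present: bool = True
) -> np.ndarray:
    """Render a track as grayscale frames (n, height, width) uint8.

    The worm is a constant-arc-length ribbon: a circular-arc centerline of
    length body_length - 2*half_width stamped with round caps, so a straight
    worm's Feret extent equals the body length and the chord/arc ratio of the
    centerline equals the frame's length_fraction. ``present=False`` renders
    background only (dead/absent worm).
    """
    from skimage.draw import disk

    rng = np.random.default_rng(seed)
    h, w = cfg.height, cfg.width
    n = track.n_frames
    frames = np.empty((n, h, w), dtype=np.uint8)

    hw = cfg.worm_half_width
    s = track.body_length_px - 2.0 * hw
    if s <= 0:
        raise ValueError("body length too small for the configured half width")
    n_pts = max(int(np.ceil(s / 0.5)) + 1, 8)

    # Headings from displacements (constant when stationary).
    dx = np.diff(track.x, prepend=track.x[0])
    dy = np.diff(track.y, prepend=track.y[0])
    heading = np.zeros(n)
    cur = 0.0
    for i in range(n):
        if dx[i] ** 2 + dy[i] ** 2 > 1e-12:
            cur = np.arctan2(dy[i], dx[i])
        heading[i] = cur

    for i in range(n):
        img = np.full((h, w), cfg.background_intensity, dtype=float)
        if present:
            amp = length_fraction_to_bend(float(track.length_fraction[i]))
            pts = arc_points(s, amp, n_pts)
            c, si = np.cos(heading[i]), np.sin(heading[i])
            rot = pts @ np.array([[c, si], [-si, c]])
            px = rot[:, 0] + track.x[i]
            py = rot[:, 1] + track.y[i]
            if (
                px.min() < hw
                or py.min() < hw
                or px.max() > w - 1 - hw
                or py.max() > h - 1 - hw
            ):
                raise ValueError(
                    f"worm escapes frame bounds at frame {int(track.frame_index[i])}"
                )
            # +0.5 so pixels at distance exactly hw are filled: a straight
            # capsule then spans body_length_px between extreme pixel centers
            for j in range(n_pts):
                rr, cc = disk((py[j], px[j]), hw + 0.5, shape=(h, w))
                img[rr, cc] = cfg.worm_intensity
        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, (h, w))
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames


def simulate_lethality_assay(
    treatment: TreatmentSpec, model: LethalityModel, seed
) -> tuple[int, int]:
    """Binomial (dead, total) counts for one treatment under a Hill dose-response."""
    rng = np.random.default_rng(seed)
    p = float(model.mortality(treatment.nitrite_mg_L))
    dead = int(rng.binomial(treatment.n_worms, p))
    return dead, treatment.n_worms
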