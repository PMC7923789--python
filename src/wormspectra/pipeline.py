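"""End-to-end orchestration: simulate -> track -> metrics/spectra -> LC50 -> PCA/PLS.

A run is reproducible from its :class:`RunConfig` and seed alone. Worm-level
random streams are keyed by (seed, food, worm, capture) — deliberately not by
ascorbic-acid or nitrite level — so every treatment cell reuses the same
virtual worm cohort and dose contrasts are paired (common random numbers).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .dose_response import MortalityCurve, fit_lc50, mortality_percent
from .locomotion import merge_captures, treatment_block_a, worm_metrics
from .multivariate import AUTOSCALE, MEAN_CENTER, pca_fit, pls1_fit
from .posture import N_BINS, normalize_lengths, postural_spectrum, spectrum_zone_fractions
from .synthetic import (
    ASA_LEVELS_MM,
    FOOD_CONDITIONS,
    NITRITE_LEVELS_MG_L,
    BehaviorParams,
    DoseEffectConfig,
    GroundTruthTrack,
    LethalityModel,
    RenderConfig,
    TreatmentSpec,
    dose_effect_params,
    render_video,
    simulate_behavior_track,
    simulate_lethality_assay,
)
from .video import RawTrack, SegmentationConfig, extract_track, track_from_truth

logger = logging.getLogger("wormspectra")

BLOCK_A_DESCRIPTORS = ["M", "t", "V", "A_m", "ACT", "M_over_Am", "M_over_ACT"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one synthetic experiment."""

    asa_levels: tuple = ASA_LEVELS_MM
    nitrite_levels: tuple = NITRITE_LEVELS_MG_L
    foods: tuple = FOOD_CONDITIONS
    n_worms: int = 6
    n_assay_worms: int = 60
    n_captures: int = 2
    capture_duration_s: float = 60.0
    fps: float = 30.0
    seed: int = 1
    use_video: bool = False
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    effects: DoseEffectConfig = field(default_factory=DoseEffectConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    base_lc50_mg_L: float = 2900.0
    hill_slope: float = 4.0
    baseline_mortality: float = 0.0
    motion_threshold_px: float = 1.0
    activity_threshold_px: float = 5.0
    area_mode: str = "sum"
    n_lv: int = 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"]["slopes"] = dict(d["effects"]["slopes"])
        d["effects"]["asa_attenuation"] = {str(k): v for k, v in d["effects"]["asa_attenuation"].items()}
        d["effects"]["food_dose_scale"] = dict(d["effects"]["food_dose_scale"])
        for key in ("asa_levels", "nitrite_levels", "foods"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "behavior" in d:
            d["behavior"] = BehaviorParams(**d["behavior"])
        if "effects" in d:
            eff = dict(d["effects"])
            if "asa_attenuation" in eff:
                eff["asa_attenuation"] = {float(k): v for k, v in eff["asa_attenuation"].items()}
            d["effects"] = DoseEffectConfig(**eff)
        if "render" in d:
            d["render"] = RenderConfig(**d["render"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationConfig(**d["segmentation"])
        for key in ("asa_levels", "nitrite_levels", "foods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def enumerate_treatments(cfg: RunConfig) -> list[TreatmentSpec]:
    """Factorial grid of the configured ascorbic acid x nitrite x food levels."""
    return [
        TreatmentSpec(asa_mM=a, nitrite_mg_L=d, food=f, n_worms=cfg.n_assay_worms, enforce_grid=False)
        for a in cfg.asa_levels
        for d in cfg.nitrite_levels
        for f in cfg.foods
    ]


def _worm_seed(cfg: RunConfig, food: str, worm: int, capture: int) -> tuple:
    # Food indexes the cohort; asa/nitrite deliberately excluded (paired design).
    return (int(cfg.seed), FOOD_CONDITIONS.index(food) if food in FOOD_CONDITIONS else 17, worm, capture)


def simulate_worm_captures(cfg: RunConfig, treatment: TreatmentSpec) -> list[list[RawTrack]]:
    """Per worm, the list of capture tracks for one treatment."""
    params = dose_effect_params(cfg.behavior, treatment, cfg.effects)
    margin = cfg.behavior.body_length_px / 2.0 + cfg.render.worm_half_width + 2.0
    arena = (
        (margin, cfg.render.width - 1 - margin),
        (margin, cfg.render.height - 1 - margin),
    )
    worms = []
    for w in range(cfg.n_worms):
        captures = []
        for c in range(cfg.n_captures):
            seed = _worm_seed(cfg, treatment.food, w, c)
            truth = simulate_behavior_track(
                params, cfg.capture_duration_s, cfg.fps, seed, arena=arena
            )
            if cfg.use_video:
                frames = render_video(truth, cfg.render, seed=(*seed, 999))
                captures.append(extract_track(frames, cfg.segmentation, fps=cfg.fps))
            else:
                captures.append(track_from_truth(truth))
        worms.append(captures)
    return worms


def analyze_worm(captures: list[RawTrack], cfg: RunConfig):
    """Merge a worm's captures into Block A metrics and a pooled postural spectrum."""
    metrics = worm_metrics(captures[0], cfg.motion_threshold_px)
    for track in captures[1:]:
        metrics = merge_captures(metrics, worm_metrics(track, cfg.motion_threshold_px), cfg.area_mode)
    lengths = np.concatenate(
        [t.df.loc[t.df["valid"], "length_px"].to_numpy(dtype=float) for t in captures]
    )
    if len(lengths) == 0:
        return metrics, None
    reference = float(lengths.max())
    series = normalize_lengths(lengths, reference, fps=cfg.fps)
    return metrics, postural_spectrum(series)


@dataclass
class ExperimentResult:
    config: RunConfig
    treatments: pd.DataFrame      # treatment_id, asa_mM, nitrite_mg_L, food
    block_a: pd.DataFrame         # treatment means of the 7 descriptors
    spectra: pd.DataFrame         # treatment_id + bin_00..bin_99
    zones: pd.DataFrame           # treatment_id, turns_pct, runs_pct, m_runs_pct
    mortality: pd.DataFrame       # treatment_id, dose, dead, total, mortality_pct
    lc50: pd.DataFrame            # per (asa, food) LC50 fits
    pls_r2: pd.DataFrame          # response -> calibration R^2
    pca_block_a: object
    pca_block_b: object
    pls_models: dict
    timings: dict


def run_experiment(
    cfg: RunConfig, out_dir=None, tracks: dict | None = None
) -> ExperimentResult:
    """Execute all stages; optionally write the CSV/report bundle to ``out_dir``.

    ``tracks`` may supply pre-computed capture tracks keyed by treatment label
    (a cached-track rerun skips simulation/rendering and must reproduce the
    downstream outputs).
    """
    timings: dict[str, float] = {}
    treatments = enumerate_treatments(cfg)
    meta = pd.DataFrame(
        {
            "treatment_id": [t.label for t in treatments],
            "asa_mM": [t.asa_mM for t in treatments],
            "nitrite_mg_L": [t.nitrite_mg_L for t in treatments],
            "food": [t.food for t in treatments],
        }
    )

    t0 = time.perf_counter()
    if tracks is None:
        tracks = {t.label: simulate_worm_captures(cfg, t) for t in treatments}
    timings["simulate_and_track"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    block_rows, spectra_rows, zone_rows = [], [], []
    for t in treatments:
        worm_results = [analyze_worm(captures, cfg) for captures in tracks[t.label]]
        block = treatment_block_a(
            [m for m, _ in worm_results], cfg.activity_threshold_px, treatment_id=t.label
        )
        block_rows.append(
            {
                "treatment_id": t.label,
                "M": block.M,
                "t": block.t,
                "V": block.V,
                "A_m": block.A_m,
                "ACT": block.ACT,
                "M_over_Am": block.M_over_Am,
                "M_over_ACT": block.M_over_ACT,
            }
        )
        spectra = [s for _, s in worm_results if s is not None]
        mean_spec = np.mean(spectra, axis=0) if spectra else np.zeros(N_BINS)
        spectra_rows.append({"treatment_id": t.label, **{f"bin_{i:02d}": mean_spec[i] for i in range(N_BINS)}})
        turns, runs, m_runs = spectrum_zone_fractions(mean_spec)
        zone_rows.append(
            {"treatment_id": t.label, "turns_pct": turns, "runs_pct": runs, "m_runs_pct": m_runs}
        )
    block_a = pd.DataFrame(block_rows)
    spectra_df = pd.DataFrame(spectra_rows)
    zones = pd.DataFrame(zone_rows)
    timings["descriptors"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mort_rows = []
    for idx, t in enumerate(treatments):
        lc50_true = cfg.base_lc50_mg_L / max(
            cfg.effects.food_dose_scale[t.food] * cfg.effects.asa_attenuation[t.asa_mM], 1e-9
        )
        model = LethalityModel(
            lc50=lc50_true, hill_slope=cfg.hill_slope, baseline_mortality=cfg.baseline_mortality
        )
        dead, total = simulate_lethality_assay(t, model, seed=(int(cfg.seed), 91, idx))
        mort_rows.append(
            {
                "treatment_id": t.label,
                "asa_mM": t.asa_mM,
                "nitrite_mg_L": t.nitrite_mg_L,
                "food": t.food,
                "dead": dead,
                "total": total,
                "mortality_pct": 100.0 * dead / total,
            }
        )
    mortality = pd.DataFrame(mort_rows)

    lc50_rows = []
    for (asa, food), grp in mortality.groupby(["asa_mM", "food"]):
        grp = grp.sort_values("nitrite_mg_L")
        curve = MortalityCurve(
            doses=grp["nitrite_mg_L"].to_numpy(),
            dead=grp["dead"].to_numpy(),
            total=grp["total"].to_numpy(),
            treatment_id=f"asa{asa:g}_{food}",
        )
        est = fit_lc50(curve)
        lc50_rows.append(
            {
                "asa_mM": asa,
                "food": food,
                "lc50_mg_L": est.lc50,
                "hill_slope": est.hill_slope,
                "method": est.method,
                "converged": est.converged,
                "status": est.status,
            }
        )
    lc50 = pd.DataFrame(lc50_rows)
    timings["dose_response"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    n_rows = len(block_a)
    k = min(2, n_rows - 1)
    X_a = block_a[BLOCK_A_DESCRIPTORS]
    pca_a = pca_fit(X_a, n_components=k, preprocessing=AUTOSCALE)
    bin_cols = [f"bin_{i:02d}" for i in range(N_BINS)]
    X_b = spectra_df[bin_cols]
    pca_b = pca_fit(X_b, n_components=k, preprocessing=MEAN_CENTER)

    responses = {d: block_a[d].to_numpy() for d in BLOCK_A_DESCRIPTORS}
    responses["mortality"] = mortality["mortality_pct"].to_numpy()
    pls_models, r2_rows = {}, []
    n_lv = min(cfg.n_lv, n_rows - 1)
    for name, y in responses.items():
        if np.std(y) == 0:  # constant response (e.g. ACT 100% everywhere)
            logger.warning("response %s is constant; skipping PLS", name)
            r2_rows.append({"response": name, "r2_calibration": np.nan})
            continue
        model = pls1_fit(X_b, y, n_lv=n_lv, preprocessing=MEAN_CENTER)
        pls_models[name] = model
        r2_rows.append({"response": name, "r2_calibration": model.r2_calibration})
    pls_r2 = pd.DataFrame(r2_rows)
    timings["multivariate"] = time.perf_counter() - t0

    result = ExperimentResult(
        config=cfg,
        treatments=meta,
        block_a=block_a,
        spectra=spectra_df,
        zones=zones,
        mortality=mortality,
        lc50=lc50,
        pls_r2=pls_r2,
        pca_block_a=pca_a,
        pca_block_b=pca_b,
        pls_models=pls_models,
        timings=timings,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    for stage, dt in timings.items():
        logger.info("stage %s: %.2f s", stage, dt)
    return result


def write_bundle(result: ExperimentResult, out_dir) -> None:
    """Write the per-stage CSVs, LC50 table, multivariate outputs and a report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.treatments.to_csv(out / "treatments.csv", index=False)
    result.block_a.to_csv(out / "block_a.csv", index=False)
    result.spectra.to_csv(out / "spectra.csv", index=False, float_format="%.6g")
    result.zones.to_csv(out / "zone_fractions.csv", index=False)
    result.mortality.to_csv(out / "mortality.csv", index=False)
    result.lc50.to_csv(out / "lc50.csv", index=False)
    result.pls_r2.to_csv(out / "pls_r2.csv", index=False)

    pca_b = result.pca_block_b
    pd.DataFrame(
        result.pca_block_a.scores, columns=["PC1", "PC2"], index=result.block_a["treatment_id"]
    ).to_csv(out / "pca_block_a_scores.csv")
    pd.DataFrame(
        pca_b.scores, columns=["PC1", "PC2"], index=result.spectra["treatment_id"]
    ).to_csv(out / "pca_block_b_scores.csv")

    lv1 = pd.DataFrame({"bin": np.arange(N_BINS)})
    for name in ("M", "A_m", "mortality"):
        if name in result.pls_models:
            lv1[f"lv1_{name}"] = result.pls_models[name].x_loadings[:, 0]
    lv1.to_csv(out / "pls_lv1_loadings.csv", index=False, float_format="%.6g")

    report = [
        "# wormspectra run report",
        "",
        f"- seed: {result.config.seed}",
        f"- treatments: {len(result.treatments)}",
        f"- worms per treatment (behavior / assay): "
        f"{result.config.n_worms} / {result.config.n_assay_worms}",
        f"- captures: {result.config.n_captures} x {result.config.capture_duration_s:g} s "
        f"at {result.config.fps:g} fps"
        + (" (rendered + segmented)" if result.config.use_video else " (ground-truth tracks)"),
        "",
        "## Stage timings (s)",
        *[f"- {k}: {v:.2f}" for k, v in result.timings.items()],
        "",
        "## LC50 (mg/L)",
        result.lc50.to_string(index=False),
        "",
        "## Block A PCA explained variance (%)",
        f"PC1 {result.pca_block_a.explained_variance_pct[0]:.1f}, "
        f"PC2 {result.pca_block_a.explained_variance_pct[1]:.1f}",
        "",
        "## Block B PCA explained variance (%)",
        f"PC1 {pca_b.explained_variance_pct[0]:.1f}, "
        f"PC2 {pca_b.explained_variance_pct[1]:.1f}",
        "",
        "## PLS calibration R2 (postural spectra vs. each response)",
        result.pls_r2.to_string(index=False),
        "",
    ]
    (out / "report.md").write_text("\n".join(report))


FIXTURE_MANIFEST = ["counts.csv", "frames.tif", "manifest.json", "track.csv", "truth.csv"]


def generate_fixtures(seed: int, out_dir) -> Path:
    """Write a small versioned fixture dataset (frames + truth + counts)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = BehaviorParams(body_length_px=40.0)
    cfg = RenderConfig(width=128, height=128, worm_half_width=1.5)
    truth = simulate_behavior_track(
        params, duration=0.5, fps=30.0, seed=int(seed), arena=((30.0, 98.0), (30.0, 98.0))
    )
    frames = render_video(truth, cfg, seed=int(seed) + 1)
    wio.write_frames(frames, out / "frames.tif", fmt="tiff")
    wio.write_truth_csv(truth, out / "truth.csv")
    track = extract_track(frames, SegmentationConfig(min_area=8), fps=truth.fps)
    wio.write_track_csv(track, out / "track.csv")

    run = RunConfig(seed=int(seed), n_assay_worms=60)
    rows = []
    for idx, t in enumerate(enumerate_treatments(run)):
        lc50_true = run.base_lc50_mg_L / (
            run.effects.food_dose_scale[t.food] * run.effects.asa_attenuation[t.asa_mM]
        )
        model = LethalityModel(lc50=lc50_true, hill_slope=run.hill_slope)
        dead, total = simulate_lethality_assay(t, model, seed=(int(seed), 91, idx))
        rows.append(
            {
                "treatment_id": t.label,
                "asa_mM": t.asa_mM,
                "nitrite_mg_L": t.nitrite_mg_L,
                "food": t.food,
                "dead": dead,
                "total": total,
            }
        )
    wio.write_counts_csv(pd.DataFrame(rows), out / "counts.csv")
    (out / "manifest.json").write_text(json.dumps({"files": FIXTURE_MANIFEST, "seed": int(seed)}, indent=1))
    return out
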