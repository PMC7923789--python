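"""Block A locomotion descriptors.

Per worm: M (summed displacement, px), t (movement time, s — the time
spent on above-threshold steps, not elapsed time), V = M/t (px/s) and
A_m, the effective area of movement, defined as the axis-aligned
bounding rectangle of the visited centroids,

    A_m = (Px_max - Px_min) * (Py_max - Py_min).

Per treatment: means of M, t, V, A_m over worms, ACT (the percentage of
worms with recorded movement), M/A_m of the treatment means, and M/ACT,
the summed displacement per active nematode.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video import RawTrack


@dataclass(frozen=True)
class WormMetrics:
    M: float
    t: float
    V: float
    A_m: float
    active: bool
    bbox: tuple[float, float, float, float] | None = None  # xmin, xmax, ymin, ymax
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.M < 0 or self.t < 0 or self.A_m < 0:
            raise ValueError("M, t and A_m must be non-negative")


@dataclass(frozen=True)
class TreatmentBlockA:
    treatment_id: str
    M: float
    t: float
    V: float
    A_m: float
    ACT: float
    M_over_Am: float
    M_over_ACT: float
    n_worms: int
    n_active: int


def _steps(track: RawTrack):
    """Euclidean steps between consecutive valid frames (gaps skipped)."""
    df = track.df
    valid = df["valid"].to_numpy(dtype=bool)
    frames = df["frame"].to_numpy()
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    ok = valid[:-1] & valid[1:] & (np.diff(frames) == 1)
    return np.hypot(np.diff(x), np.diff(y))[ok]


def displacement_metrics(
    track: RawTrack, motion_threshold: float = 1.0
) -> tuple[float, float, float]:
    """(M, t, V) from a track; (0, 0, 0) when fewer than 2 valid frames.

    Only steps of at least ``motion_threshold`` px count toward M and its
    movement time t; V = M/t, defined as 0 when t = 0.
    """
    if int(track.df["valid"].sum()) < 2:
        return 0.0, 0.0, 0.0
    steps = _steps(track)
    moving = steps[steps >= motion_threshold]
    M = float(moving.sum())
    t = len(moving) / track.fps
    V = M / t if t > 0 else 0.0
    return M, t, V


def effective_area(track: RawTrack) -> float:
    """Bounding-rectangle area of all valid centroids, px^2."""
    df = track.df[track.df["valid"]]
    if df.empty:
        raise ValueError("effective_area needs at least one valid observation")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    return float((x.max() - x.min()) * (y.max() - y.min()))


def _bbox(track: RawTrack):
    df = track.df[track.df["valid"]]
    if df.empty:
        return None
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    return (float(x.min()), float(x.max()), float(y.min()), float(y.max()))


def worm_metrics(track: RawTrack, motion_threshold: float = 1.0) -> WormMetrics:
    """All per-worm Block A quantities for a single capture."""
    M, t, V = displacement_metrics(track, motion_threshold)
    box = _bbox(track)
    A_m = 0.0 if box is None else (box[1] - box[0]) * (box[3] - box[2])
    return WormMetrics(M=M, t=t, V=V, A_m=A_m, active=M > 0, bbox=box, fps=track.fps)


def merge_captures(a: WormMetrics, b: WormMetrics, area_mode: str = "sum") -> WormMetrics:
    """Combine the two 1-minute captures of one worm (results summed).

    M and t add; V is recomputed as total M over total t. A_m adds by default;
    ``area_mode="union"`` instead uses the bounding box of the union of both
    captures' boxes.
    """
    if a.fps != b.fps:
        raise ValueError("cannot merge captures with different frame rates")
    if area_mode == "sum":
        A_m = a.A_m + b.A_m
        box = None
    elif area_mode == "union":
        boxes = [box for box in (a.bbox, b.bbox) if box is not None]
        if not boxes:
            A_m, box = 0.0, None
        else:
            box = (
                min(bb[0] for bb in boxes),
                max(bb[1] for bb in boxes),
                min(bb[2] for bb in boxes),
                max(bb[3] for bb in boxes),
            )
            A_m = (box[1] - box[0]) * (box[3] - box[2])
    else:
        raise ValueError("area_mode must be 'sum' or 'union'")
    M = a.M + b.M
    t = a.t + b.t
    return WormMetrics(
        M=M,
        t=t,
        V=M / t if t > 0 else 0.0,
        A_m=A_m,
        active=a.active or b.active,
        bbox=box,
        fps=a.fps,
    )


def treatment_block_a(
    worms, activity_threshold_px: float = 5.0, treatment_id: str = ""
) -> TreatmentBlockA:
    """Aggregate per-worm metrics into the treatment-level Block A descriptors."""
    worms = list(worms)
    if not worms:
        raise ValueError("treatment_block_a needs at least one worm")
    M_arr = np.array([w.M for w in worms])
    active = M_arr >= activity_threshold_px
    n_active = int(active.sum())
    mean_M = float(M_arr.mean())
    mean_Am = float(np.mean([w.A_m for w in worms]))
    return TreatmentBlockA(
        treatment_id=treatment_id,
        M=mean_M,
        t=float(np.mean([w.t for w in worms])),
        V=float(np.mean([w.V for w in worms])),
        A_m=mean_Am,
        ACT=100.0 * n_active / len(worms),
        M_over_Am=mean_M / mean_Am if mean_Am > 0 else 0.0,
        M_over_ACT=float(M_arr.sum()) / n_active if n_active > 0 else 0.0,
        n_worms=len(worms),
        n_active=n_active,
    )
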