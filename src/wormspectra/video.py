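"""Worm segmentation and per-frame tracking.

Each frame holds a single dark worm on a bright background (one worm
per microwell). Segmentation inverts the frame, thresholds it (Otsu by
default, fixed value on request), labels 8-connected components,
discards sub-minimum blobs and keeps the largest survivor. The worm's
per-frame "length" is the maximum Feret diameter of the blob — the
caliper extent — which shrinks as the body bends and therefore carries
the postural signal downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class SegmentationConfig:
    """Settings for :func:`segment_frame`.

    threshold          fixed threshold on the *inverted* frame; None = Otsu
    min_area           reject blobs smaller than this (noise specks), px
    max_fill_fraction  declare no-detection if the foreground covers more of
                       the frame than this (a single worm is small; a larger
                       fill means thresholding latched onto noise/background)
    min_contrast       declare no-detection below this intensity range
    """

    threshold: float | None = None
    min_area: int = 15
    max_fill_fraction: float = 0.25
    min_contrast: float = 20.0


@dataclass(frozen=True)
class WormObservation:
    frame_index: int
    x: float = np.nan
    y: float = np.nan
    length_px: float = 0.0
    area_px: int = 0
    valid: bool = False


@dataclass
class RawTrack:
    """Ordered per-frame worm observations with frame rate.

    ``df`` columns: frame, x, y, length_px, area_px, valid. Invalid frames
    (no blob passed the filters) are retained with valid=False.
    """

    df: pd.DataFrame
    fps: float

    def __post_init__(self) -> None:
        required = {"frame", "x", "y", "length_px", "area_px", "valid"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        frames = self.df["frame"].to_numpy()
        if len(frames) and np.any(np.diff(frames) <= 0):
            raise ValueError("frame numbers must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @classmethod
    def from_observations(cls, observations, fps: float) -> "RawTrack":
        df = pd.DataFrame(
            {
                "frame": [o.frame_index for o in observations],
                "x": [o.x for o in observations],
                "y": [o.y for o in observations],
                "length_px": [o.length_px for o in observations],
                "area_px": [o.area_px for o in observations],
                "valid": [o.valid for o in observations],
            }
        )
        return cls(df=df, fps=fps)

    @property
    def n_frames(self) -> int:
        return len(self.df)

    def valid_mask(self) -> np.ndarray:
        return self.df["valid"].to_numpy(dtype=bool)


def max_feret(mask) -> float:
    """Maximum Euclidean distance between pixel centers of a blob.

    Computed on the convex hull for efficiency; equals the brute-force
    pairwise maximum exactly (the farthest pair lies on the hull).
    """
    pts = np.asarray(sorted(mask) if isinstance(mask, set) else mask, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("mask must be a non-empty set of pixel coordinates")
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (e.g. collinear) blob: fall back to all points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def segment_frame(
    frame, cfg: SegmentationConfig = SegmentationConfig(), index: int = 0
) -> WormObservation:
    """Segment the single worm from one grayscale frame.

    Never raises on content: frames without a surviving blob come back with
    ``valid=False``. Multiple surviving blobs keep the largest with a warning
    (single-worm wells).
    """
    pixels = np.asarray(frame, dtype=float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale array")
    inverted = 255.0 - pixels
    if inverted.max() - inverted.min() < cfg.min_contrast:
        return WormObservation(frame_index=index)
    thr = threshold_otsu(inverted) if cfg.threshold is None else cfg.threshold
    mask = inverted > thr
    if mask.mean() > cfg.max_fill_fraction:
        return WormObservation(frame_index=index)

    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return WormObservation(frame_index=index)
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= cfg.min_area) + 1
    if keep.size == 0:
        return WormObservation(frame_index=index)
    if keep.size > 1:
        warnings.warn(
            f"frame {index}: {keep.size} blobs passed filters; keeping the largest",
            stacklevel=2,
        )
    best = keep[np.argmax(areas[keep - 1])]
    rows, cols = np.nonzero(labels == best)
    coords = np.column_stack([rows, cols])
    return WormObservation(
        frame_index=index,
        x=float(cols.mean()),
        y=float(rows.mean()),
        length_px=max_feret(coords),
        area_px=int(len(rows)),
        valid=True,
    )


def extract_track(
    frames, cfg: SegmentationConfig = SegmentationConfig(), fps: float = 30.0
) -> RawTrack:
    """Segment every frame of a capture into a :class:`RawTrack`."""
    observations = []
    n = 0
    for i, frame in enumerate(frames):
        observations.append(segment_frame(frame, cfg, index=i))
        n += 1
    if n == 0:
        raise ValueError("need at least one frame")
    return RawTrack.from_observations(observations, fps=fps)


def track_from_truth(truth) -> RawTrack:
    """Convert generator ground truth into the RawTrack a segmenter would emit.

    The per-frame length is the chord of the bent body,
    length_fraction * body_length_px; all frames are valid. Used for
    desk-scale runs that skip pixel rendering.
    """
    df = pd.DataFrame(
        {
            "frame": truth.frame_index,
            "x": truth.x,
            "y": truth.y,
            "length_px": truth.length_fraction * truth.body_length_px,
            "area_px": 0,
            "valid": True,
        }
    )
    return RawTrack(df=df, fps=truth.fps)
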