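"""Readers/writers for the pipeline's on-disk formats.

Tracks, spectra and assay counts travel as plain CSV; rendered frames as
multi-page TIFF or a numbered PNG sequence.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruthTrack
from .video import RawTrack

TRACK_COLUMNS = ["frame", "x", "y", "length_px", "area_px", "valid"]
TRUTH_COLUMNS = ["frame", "x", "y", "length_fraction", "state"]
COUNTS_COLUMNS = ["treatment_id", "asa_mM", "nitrite_mg_L", "food", "dead", "total"]


def write_track_csv(track: RawTrack, path) -> None:
    df = track.df[TRACK_COLUMNS].copy()
    df.insert(0, "fps", track.fps)
    df.to_csv(path, index=False)


def read_track_csv(path) -> RawTrack:
    df = pd.read_csv(path, float_precision="round_trip")
    fps = float(df["fps"].iloc[0])
    return RawTrack(df=df[TRACK_COLUMNS].copy(), fps=fps)


def write_truth_csv(truth: GroundTruthTrack, path) -> None:
    df = truth.to_dataframe()
    df.insert(0, "fps", truth.fps)
    df.insert(1, "body_length_px", truth.body_length_px)
    df.to_csv(path, index=False)


def read_truth_csv(path) -> GroundTruthTrack:
    df = pd.read_csv(path, float_precision="round_trip")
    return GroundTruthTrack(
        frame_index=df["frame"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        length_fraction=df["length_fraction"].to_numpy(),
        state=df["state"].to_numpy(dtype="U8"),
        fps=float(df["fps"].iloc[0]),
        body_length_px=float(df["body_length_px"].iloc[0]),
    )


def write_frames(frames: np.ndarray, path, fmt: str = "tiff") -> None:
    """Write a (n, h, w) uint8 stack as multi-page TIFF or a PNG sequence."""
    path = Path(path)
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, frames)
    elif fmt == "png":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
    else:
        raise ValueError("fmt must be 'tiff' or 'png'")


def read_frames(path) -> np.ndarray:
    """Read frames from a TIFF stack, video file, or a directory of PNGs."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("frame_*.png")) or sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames under {path}")
        return np.stack([iio.imread(f) for f in files])
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path)
        return frames[None] if frames.ndim == 2 else frames
    import imageio.v3 as iio

    frames = iio.imread(path)
    if frames.ndim == 4:  # color video: collapse to grayscale
        frames = frames.mean(axis=-1).astype(np.uint8)
    return frames[None] if frames.ndim == 2 else frames


def write_counts_csv(rows: pd.DataFrame, path) -> None:
    missing = set(COUNTS_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    rows[COUNTS_COLUMNS].to_csv(path, index=False)


def read_counts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
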