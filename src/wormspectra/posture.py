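"""Block B postural dynamics: % worm length series, postural spectra and zones.

The per-frame maximum worm length, normalized to the worm's reference
(unbent) length, is a proxy for body-bend amplitude: tight bends give
short chords. The distribution of these % lengths over a capture is the
worm's postural spectrum — a 100-bin histogram in % time. Three posture
zones partition the axis: turns (< 50% length, high-bend reorientation
postures), runs (50-85%), and M-runs (>= 85%, near-maximal extension).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .video import RawTrack

ZONE_TURN = "turn"
ZONE_RUN = "run"
ZONE_M_RUN = "m_run"

TURN_UPPER = 50.0
M_RUN_LOWER = 85.0

N_BINS = 100


@dataclass
class LengthSeries:
    """Per-valid-frame % worm length values in [0, 100]."""

    values: np.ndarray
    fps: float
    worm_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("length series must be 1-D")
        if len(self.values) and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("% worm length values must lie in [0, 100]")


def normalize_lengths(
    length_px, reference: float, fps: float = 30.0, worm_id: str = ""
) -> LengthSeries:
    """Convert raw per-frame lengths (px) to % of a reference length.

    The default reference upstream is the worm's own maximum observed length
    across both captures, which removes worm-size variation. Values are
    clipped to [0, 100] (measurement jitter can exceed the reference).
    """
    if reference <= 0:
        raise ValueError("reference length must be > 0")
    values = np.clip(100.0 * np.asarray(length_px, dtype=float) / reference, 0.0, 100.0)
    return LengthSeries(values=values, fps=fps, worm_id=worm_id)


def series_from_track(track: RawTrack, reference: float | None = None, worm_id: str = "") -> LengthSeries:
    """Length series of a track's valid frames; reference defaults to its max length."""
    lengths = track.df.loc[track.df["valid"], "length_px"].to_numpy(dtype=float)
    if len(lengths) == 0:
        raise ValueError("track has no valid frames")
    ref = float(lengths.max()) if reference is None else reference
    return normalize_lengths(lengths, ref, fps=track.fps, worm_id=worm_id)


def postural_spectrum(series: LengthSeries) -> np.ndarray:
    """100-bin histogram of % worm length in % time; sums to 100.

    Bins are [i, i+1) for i = 0..98 and [99, 100] for the last.
    """
    if len(series.values) == 0:
        raise ValueError("cannot build a spectrum from an empty series")
    counts, _ = np.histogram(series.values, bins=np.arange(N_BINS + 1, dtype=float))
    return 100.0 * counts / len(series.values)


def classify_zone(length_pct: float) -> str:
    """Posture zone of one % worm length value (half-open boundaries)."""
    if not 0.0 <= length_pct <= 100.0:
        raise ValueError(f"% worm length must lie in [0, 100], got {length_pct}")
    if length_pct < TURN_UPPER:
        return ZONE_TURN
    if length_pct < M_RUN_LOWER:
        return ZONE_RUN
    return ZONE_M_RUN


def classify_zones(length_pct) -> np.ndarray:
    """Vectorized :func:`classify_zone`."""
    v = np.asarray(length_pct, dtype=float)
    if v.size and (v.min() < 0 or v.max() > 100):
        raise ValueError("% worm length values must lie in [0, 100]")
    out = np.full(v.shape, ZONE_RUN, dtype="U8")
    out[v < TURN_UPPER] = ZONE_TURN
    out[v >= M_RUN_LOWER] = ZONE_M_RUN
    return out


def zone_fractions(series: LengthSeries) -> tuple[float, float, float]:
    """(turns %, runs %, M-runs %) — disjoint, summing to 100.

    Equals summing the postural spectrum over bins 0-49, 50-84 and 85-99.
    """
    if len(series.values) == 0:
        raise ValueError("cannot compute zone fractions of an empty series")
    # computed through the histogram so the result equals summing the
    # spectrum over bins 0-49 / 50-84 / 85-99 bit-exactly
    return spectrum_zone_fractions(postural_spectrum(series))


def spectrum_zone_fractions(spectrum: np.ndarray) -> tuple[float, float, float]:
    """Zone occupancy directly from a spectrum (bins 0-49 / 50-84 / 85-99)."""
    s = np.asarray(spectrum, dtype=float)
    if s.shape != (N_BINS,):
        raise ValueError(f"spectrum must have {N_BINS} bins")
    return (
        float(s[:50].sum()),
        float(s[50:85].sum()),
        float(s[85:].sum()),
    )


def colored_track_export(track: RawTrack, series: LengthSeries) -> pd.DataFrame:
    """Per-valid-frame (frame, x, y, zone) records for zone-colored trajectories."""
    df = track.df[track.df["valid"]]
    if len(df) != len(series.values):
        raise ValueError(
            f"track has {len(df)} valid frames but series has {len(series.values)} values"
        )
    return pd.DataFrame(
        {
            "frame": df["frame"].to_numpy(),
            "x": df["x"].to_numpy(dtype=float),
            "y": df["y"].to_numpy(dtype=float),
            "zone": classify_zones(series.values),
        }
    )
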