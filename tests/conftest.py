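import numpy as np
import pandas as pd
import pytest

from wormspectra.video import RawTrack


def make_track(x, y, valid=None, length_px=None, fps=30.0, frames=None):
    """Build a RawTrack from coordinate arrays (test helper)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    df = pd.DataFrame(
        {
            "frame": np.arange(n) if frames is None else frames,
            "x": x,
            "y": np.asarray(y, dtype=float),
            "length_px": np.ones(n) if length_px is None else np.asarray(length_px, dtype=float),
            "area_px": 40,
            "valid": np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
        }
    )
    return RawTrack(df=df, fps=fps)


@pytest.fixture
def rng():
    return np.random.default_rng(20240531)


@pytest.fixture
def rectangle_frame():
    """10x4 px dark rectangle on a white 60x60 field."""
    frame = np.full((60, 60), 255, dtype=np.uint8)
    frame[20:24, 30:40] = 0
    return frame


def random_track(rng, n=50, scale=30.0):
    x = np.cumsum(rng.normal(0, scale / 10, n))
    y = np.cumsum(rng.normal(0, scale / 10, n))
    return make_track(x, y)
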