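"""Circular-arc worm geometry.

A worm of fixed arc length bent into a circular arc of total angle
theta has chord/arc ratio sin(theta/2)/(theta/2). Parameterizing the
bend by ``amp`` in [0, 1] with theta = 2*pi*amp gives

    length_fraction(amp) = sin(pi*amp)/(pi*amp) = sinc(amp)

so amp = 0 is a straight worm (fraction 1), amp = 0.5 a semicircle
(fraction 2/pi) and amp = 1 a closed circle (fraction 0). The mapping
is strictly decreasing, which makes the posture zones invertible.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def bend_to_length_fraction(amp):
    """Chord/arc ratio of a circular arc with bend amplitude ``amp`` in [0, 1]."""
    return np.sinc(amp)  # np.sinc(x) = sin(pi x)/(pi x)


# Bend amplitude whose chord is exactly half the body length: the
# turn/run posture boundary in generator coordinates.
HALF_LENGTH_BEND: float = brentq(lambda a: np.sinc(a) - 0.5, 0.01, 0.999)


def length_fraction_to_bend(fraction: float) -> float:
    """Invert ``bend_to_length_fraction`` for a scalar fraction in [0, 1]."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"length fraction must be in [0, 1], got {fraction}")
    if fraction >= 1.0 - 1e-12:
        return 0.0
    if fraction <= 1e-12:
        return 1.0
    return brentq(lambda a: np.sinc(a) - fraction, 1e-9, 1.0 - 1e-12)


def arc_points(arc_length: float, bend_amp: float, n_points: int) -> np.ndarray:
    """Sample ``n_points`` along a centered circular arc of given arc length.

    Returns an (n_points, 2) array of (x, y) coordinates whose mean is the
    origin and whose mid-arc tangent points along +x. ``bend_amp`` follows the
    ``bend_to_length_fraction`` convention.
    """
    if arc_length <= 0:
        raise ValueError("arc_length must be positive")
    if n_points < 2:
        raise ValueError("need at least 2 sample points")
    if bend_amp < 1e-9:
        x = np.linspace(-arc_length / 2.0, arc_length / 2.0, n_points)
        pts = np.column_stack([x, np.zeros_like(x)])
    else:
        theta = 2.0 * np.pi * bend_amp
        radius = arc_length / theta
        phi = np.linspace(-theta / 2.0, theta / 2.0, n_points)
        pts = np.column_stack([radius * np.sin(phi), radius * (1.0 - np.cos(phi))])
    return pts - pts.mean(axis=0)
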