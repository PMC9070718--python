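"""Closed-form Gaussian-blurred primitive shapes.

These evaluate the continuum convolution of indicator functions (ball, axis
aligned box) with an isotropic Gaussian, exactly, at arbitrary points. The
phantom generator composes volumes from these instead of discretely
convolving a rasterized field, so synthetic gray values agree with the
continuum model to floating-point precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["ball_gauss", "box_gauss_1d", "erf_step"]

_SQRT2 = np.sqrt(2.0)
_SQRT_2PI = np.sqrt(2.0 * np.pi)


def ball_gauss(d: np.ndarray | float, radius: float, sigma: float) -> np.ndarray:
    """Fraction of an isotropic 3D Gaussian (std ``sigma``) whose center lies
    at distance ``d`` from the center of a ball of ``radius`` that falls
    inside the ball — equivalently, the blurred ball's gray profile (0..1).

    For ``sigma == 0`` this degenerates to the ball indicator.
    """
    d = np.asarray(d, dtype=np.float64)
    if sigma == 0:
        return (d <= radius).astype(np.float64)
    a = (radius - d) / (_SQRT2 * sigma)
    b = (radius + d) / (_SQRT2 * sigma)
    core = 0.5 * (erf(a) + erf(b))
    # (exp(-(d-R)^2/2s^2) - exp(-(d+R)^2/2s^2)) / d, with the d -> 0 limit
    num = np.exp(-((d - radius) ** 2) / (2 * sigma**2)) - np.exp(
        -((d + radius) ** 2) / (2 * sigma**2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = np.where(d > 1e-9, num / np.where(d > 1e-9, d, 1.0), 0.0)
    limit = (2 * radius / sigma**2) * np.exp(-(radius**2) / (2 * sigma**2))
    tail = np.where(d > 1e-9, tail, limit)
    return core - (sigma / _SQRT_2PI) * tail


def box_gauss_1d(x: np.ndarray, lo: float, hi: float, sigma: float) -> np.ndarray:
    """1D factor of a Gaussian-blurred axis-aligned box: the blurred indicator
    of the interval [lo, hi] evaluated at ``x``. The 3D blurred box is the
    product of the three per-axis factors (the Gaussian is separable)."""
    x = np.asarray(x, dtype=np.float64)
    if sigma == 0:
        return ((x >= lo) & (x <= hi)).astype(np.float64)
    return 0.5 * (erf((hi - x) / (_SQRT2 * sigma)) - erf((lo - x) / (_SQRT2 * sigma)))


def erf_step(d: np.ndarray | float, sigma: float) -> np.ndarray:
    """Ideal planar edge-spread response 0.5*(1 + erf(d / (sqrt(2)*sigma))),
    rising from 0 to 1; a unit step at d=0 when sigma == 0."""
    d = np.asarray(d, dtype=np.float64)
    if sigma == 0:
        return (d >= 0).astype(np.float64)
    return 0.5 * (1.0 + erf(d / (_SQRT2 * sigma)))
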