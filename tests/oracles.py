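"""Independent brute-force / quadrature oracles used across the test suite.

Everything here is deliberately naive and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def rasterize_ball(radius: float, grid: int, center: tuple[float, float, float] | None = None) -> np.ndarray:
    """Binary ball: voxel centers within Euclidean ``radius`` (inclusive)."""
    if center is None:
        c = ((grid - 1) / 2.0,) * 3
    else:
        c = center
    zz, yy, xx = np.mgrid[0:grid, 0:grid, 0:grid].astype(float)
    d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
    return d2 <= radius**2


def brute_force_erosion(mask: np.ndarray, radius: int) -> np.ndarray:
    """All-offsets erosion with the inclusive digital ball; out-of-bounds
    voxels count as background."""
    r = int(radius)
    offsets = [
        (dz, dy, dx)
        for dz in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dz * dz + dy * dy + dx * dx <= r * r
    ]
    out = np.zeros_like(mask)
    nz, ny, nx = mask.shape
    for v in np.argwhere(mask):
        ok = True
        for dz, dy, dx in offsets:
            z, y, x = v[0] + dz, v[1] + dy, v[2] + dx
            if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx) or not mask[z, y, x]:
                ok = False
                break
        out[tuple(v)] = ok
    return out


def brute_force_signed_distance(mask: np.ndarray) -> np.ndarray:
    """All-pairs signed Euclidean distance to the mask surface: for each
    voxel the minimum distance to the complementary set, shifted by the
    half-voxel surface offset, positive inside."""
    fg = np.argwhere(mask).astype(float)
    bg = np.argwhere(~mask).astype(float)
    out = np.empty(mask.shape)
    for v in np.ndindex(mask.shape):
        p = np.array(v, dtype=float)
        if mask[v]:
            d2 = np.min(np.sum((bg - p) ** 2, axis=1))
            out[v] = np.sqrt(d2) - 0.5
        else:
            d2 = np.min(np.sum((fg - p) ** 2, axis=1))
            out[v] = 0.5 - np.sqrt(d2)
    return out


def quad_erf(x: float) -> float:
    """Error function by direct quadrature of the Gaussian (independent of
    scipy.special.erf)."""
    val, _ = quad(lambda t: np.exp(-t * t), 0.0, x, epsabs=1e-14, epsrel=1e-14)
    return 2.0 / np.sqrt(np.pi) * val


def quad_blurred_ball(d: float, radius: float, sigma: float) -> float:
    """Gaussian mass inside a ball at center offset ``d``, by radial
    quadrature over spherical shells (independent of the closed form)."""
    if sigma == 0:
        return float(d <= radius)

    def shell_fraction(r: float) -> float:
        if d == 0:
            return 1.0 if r <= radius else 0.0
        if r == 0:
            return 1.0 if d <= radius else 0.0
        c = (d * d + r * r - radius * radius) / (2 * d * r)
        if c <= -1:
            return 1.0
        if c >= 1:
            return 0.0
        return (1.0 - c) / 2.0

    def integrand(r: float) -> float:
        dens = (2 * np.pi * sigma**2) ** -1.5 * np.exp(-(r * r) / (2 * sigma**2))
        return 4 * np.pi * r * r * dens * shell_fraction(r)

    val, _ = quad(integrand, 0.0, d + radius + 10 * sigma, limit=400)
    return val


def prolate_spheroid_area_volume(a: float, b: float) -> tuple[float, float]:
    """Closed-form surface area and volume of a prolate spheroid with long
    semi-axis ``a`` and equatorial semi-axis ``b`` (a > b)."""
    e = np.sqrt(1.0 - (b / a) ** 2)
    area = 2 * np.pi * b**2 * (1.0 + (a / (b * e)) * np.arcsin(e))
    volume = 4.0 / 3.0 * np.pi * a * b**2
    return area, volume
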