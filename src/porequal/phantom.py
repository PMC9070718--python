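"""Synthetic nanoCT phantoms with known ground truth.

The generator emulates the features of a reconstructed holotomography volume
of a porous ceramic scaffold that the quality metrics operate on:

* a solid matrix at a scaffold gray level containing roughly spherical
  closed pores of higher gray value;
* a main connected pore space (a box-shaped channel) reaching the volume
  boundary, so the isolated/main-pore distinction is exercised;
* isotropic Gaussian edge blur of known width (the resolution target);
* additive i.i.d. Gaussian noise of known amplitude (the SNR target);
* a slow multiplicative background drift of configurable peak-to-peak
  amplitude, emulating the low-frequency gray-value variation that local
  tomography and changing beam intensity produce.

Blur is synthesized analytically: each pore contributes the closed-form
radial profile of a ball convolved with a Gaussian, and the channel/bone
boxes contribute separable products of 1D Gaussian-CDF factors. Pores are
placed far enough apart that the superposition is exact, so noiseless
phantom gray values match the continuum model to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._analytic import ball_gauss, box_gauss_1d, erf_step
from .volume_io import GrayVolume, PoreLabelVolume

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "analytic_edge_profile",
    "PlacementError",
    "GAUSS_FWHM_FACTOR",
]

#: FWHM of a Gaussian of unit standard deviation.
GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class PlacementError(RuntimeError):
    """Raised when the requested pores cannot be placed without contact."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic two/three-phase volume.

    Gray levels are arbitrary reconstruction units; pores are brighter than
    the scaffold. ``drift_amplitude`` is peak-to-peak, as a fraction of
    ``gray_scaffold``. ``blur_sigma`` is in voxels, ``noise_sigma`` in gray
    units.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 50.0  # nm
    gray_scaffold: float = 100.0
    gray_pore: float = 200.0
    gray_bone: float | None = None
    n_closed_pores: int = 20
    pore_radius_range: tuple[float, float] = (9.0, 12.0)
    blur_sigma: float = 2.0
    noise_sigma: float = 0.0
    drift_amplitude: float = 0.0
    include_main_pore_space: bool = True
    include_bone_block: bool = False
    seed: int = 0
    max_placement_attempts: int = 50_000

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.gray_pore <= self.gray_scaffold:
            raise ValueError("gray_pore must exceed gray_scaffold")
        if self.n_closed_pores < 0:
            raise ValueError("n_closed_pores must be non-negative")
        rmin, rmax = self.pore_radius_range
        if self.n_closed_pores > 0 and rmin < 2:
            raise ValueError("pore radii must be at least 2 voxels")
        if rmax < rmin:
            raise ValueError("pore_radius_range must be (min, max)")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be non-negative")
        if not (0 <= self.drift_amplitude < 1):
            raise ValueError("drift_amplitude must lie in [0, 1)")

    @property
    def blur_support_radius(self) -> float:
        """Effective support radius of the blur kernel (3 sigma)."""
        return 3.0 * self.blur_sigma

    @property
    def true_fwhm_nm(self) -> float:
        return GAUSS_FWHM_FACTOR * self.blur_sigma * self.voxel_size

    @property
    def true_snr(self) -> float:
        if self.noise_sigma == 0:
            return np.inf
        return (self.gray_pore - self.gray_scaffold) / self.noise_sigma


@dataclass
class PhantomGroundTruth:
    """What the generator actually placed, for metric-recovery checks."""

    true_label_volume: PoreLabelVolume
    centers: np.ndarray  # (K, 3) float, (z, y, x) voxel coordinates
    radii: np.ndarray  # (K,) float, voxels
    true_fwhm_nm: float
    true_snr: float


def _drift_field(shape: tuple[int, int, int], amplitude: float,
                 gray_scaffold: float) -> np.ndarray:
    """Smooth multiplicative drift, peak-to-peak = amplitude * gray_scaffold
    on a scaffold-level background. Deterministic so that matched seeds with
    and without drift share identical geometry and noise."""
    nz, ny, nx = shape
    z = np.linspace(0.0, 1.0, nz)[:, None, None]
    y = np.linspace(0.0, 1.0, ny)[None, :, None]
    x = np.linspace(0.0, 1.0, nx)[None, None, :]
    raw = z + y + x + 0.6 * np.sin(np.pi * z) * np.sin(np.pi * y)
    g = (raw - raw.min()) / (raw.max() - raw.min())  # exactly spans [0, 1]
    return 1.0 + amplitude * (g - 0.5)


def _channel_box(shape: tuple[int, int, int]) -> tuple[tuple[float, float], ...]:
    """Main-pore-space rod: square cross-section near one corner, spanning
    the full z extent (touches the z faces)."""
    nz, ny, nx = shape
    w = max(6, min(ny, nx) // 12)
    lo = 4
    return ((-2.0, nz + 1.0), (float(lo), float(lo + w)), (float(lo), float(lo + w)))


def _bone_box(shape: tuple[int, int, int]) -> tuple[tuple[float, float], ...]:
    nz, ny, nx = shape
    w = max(6, min(ny, nx) // 12)
    return (
        (nz * 0.3, nz * 0.7),
        (ny - 4.0 - w, ny - 4.0),
        (nx - 4.0 - w, nx - 4.0),
    )


def _box_margin_ok(center: np.ndarray, r: float, box, margin: float) -> bool:
    """True if a sphere keeps at least ``margin`` surface distance from an
    axis-aligned box."""
    d2 = 0.0
    for c, (lo, hi) in zip(center, box):
        gap = max(lo - c, c - hi, 0.0)
        d2 += gap * gap
    return np.sqrt(d2) >= r + margin


def _place_pores(spec: PhantomSpec, rng: np.random.Generator,
                 boxes: list) -> tuple[np.ndarray, np.ndarray]:
    nz, ny, nx = spec.grid_shape
    shape_arr = np.array([nz, ny, nx], dtype=float)
    sep = max(2.0 * spec.blur_support_radius, 4.0)
    boundary_margin = max(spec.blur_support_radius, 2.0) + 1.0
    centers: list[np.ndarray] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < spec.n_closed_pores:
        if attempts >= spec.max_placement_attempts:
            raise PlacementError(
                f"placed only {len(centers)}/{spec.n_closed_pores} pores after "
                f"{attempts} attempts; reduce count/radii or enlarge the grid"
            )
        attempts += 1
        r = rng.uniform(*spec.pore_radius_range)
        lo = r + boundary_margin
        c = rng.uniform(lo, shape_arr - 1.0 - lo)
        if any(
            np.linalg.norm(c - c2) < r + r2 + sep
            for c2, r2 in zip(centers, radii)
        ):
            continue
        if not all(_box_margin_ok(c, r, b, sep) for b in boxes):
            continue
        centers.append(c)
        radii.append(r)
    return np.array(centers).reshape(-1, 3), np.array(radii)


def generate_phantom(spec: PhantomSpec) -> tuple[GrayVolume, PhantomGroundTruth]:
    """Generate a seeded phantom volume and its ground truth.

    The noiseless volume is the continuum Gaussian-blurred phase field
    (scaffold level everywhere, pore level inside spheres and the main
    channel, optional bone level in a bone block), modulated by the drift
    field, with i.i.d. Gaussian noise added last. Identical specs (including
    seed) produce bit-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape

    boxes = []
    bone_box = None
    if spec.include_main_pore_space:
        boxes.append(_channel_box(spec.grid_shape))
    if spec.gray_bone is not None and spec.include_bone_block:
        bone_box = _bone_box(spec.grid_shape)
        boxes.append(bone_box)

    centers, radii = _place_pores(spec, rng, boxes)

    vol = np.full(spec.grid_shape, float(spec.gray_scaffold))
    zz = np.arange(nz, dtype=float)
    yy = np.arange(ny, dtype=float)
    xx = np.arange(nx, dtype=float)

    contrast = spec.gray_pore - spec.gray_scaffold
    if spec.include_main_pore_space:
        (zl, zh), (yl, yh), (xl, xh) = _channel_box(spec.grid_shape)
        prof = (
            box_gauss_1d(zz, zl, zh, spec.blur_sigma)[:, None, None]
            * box_gauss_1d(yy, yl, yh, spec.blur_sigma)[None, :, None]
            * box_gauss_1d(xx, xl, xh, spec.blur_sigma)[None, None, :]
        )
        vol += contrast * prof
    if bone_box is not None:
        (zl, zh), (yl, yh), (xl, xh) = bone_box
        prof = (
            box_gauss_1d(zz, zl, zh, spec.blur_sigma)[:, None, None]
            * box_gauss_1d(yy, yl, yh, spec.blur_sigma)[None, :, None]
            * box_gauss_1d(xx, xl, xh, spec.blur_sigma)[None, None, :]
        )
        vol += (spec.gray_bone - spec.gray_scaffold) * prof

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    pad = int(np.ceil(spec.blur_support_radius)) + 2
    for k, (c, r) in enumerate(zip(centers, radii), start=1):
        lo = np.maximum(np.floor(c - r - pad).astype(int), 0)
        hi = np.minimum(np.ceil(c + r + pad).astype(int) + 1,
                        np.array(spec.grid_shape))
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        grids = np.meshgrid(
            zz[sl[0]] - c[0], yy[sl[1]] - c[1], xx[sl[2]] - c[2],
            indexing="ij",
        )
        d = np.sqrt(grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2)
        vol[sl] += contrast * ball_gauss(d, r, spec.blur_sigma)
        labels[sl][d <= r] = k

    if spec.drift_amplitude > 0:
        vol *= _drift_field(spec.grid_shape, spec.drift_amplitude,
                            spec.gray_scaffold)
    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=spec.grid_shape)

    gt = PhantomGroundTruth(
        true_label_volume=PoreLabelVolume(labels, spec.voxel_size),
        centers=centers,
        radii=radii,
        true_fwhm_nm=spec.true_fwhm_nm,
        true_snr=spec.true_snr,
    )
    return GrayVolume(vol, spec.voxel_size), gt


def analytic_edge_profile(blur_sigma: float, distances: np.ndarray) -> np.ndarray:
    """Ideal planar step response at signed distances (positive = bright side):
    0.5*(1 + erf(d / (sqrt(2)*blur_sigma))); a unit step when blur_sigma=0.

    Serves as the reference curve the measured step-up profiles are checked
    against.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    return erf_step(np.asarray(distances, dtype=float), blur_sigma)
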