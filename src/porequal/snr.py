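"""Erosion-based per-pore signal-to-noise ratio.

The interface (and its partial-volume blur) is excluded by eroding both the
pore and the surrounding scaffold with a spherical structuring element of
radius 5 voxels; the SNR is then

    SNR = (mu_pore - mu_scaffold) / max(sigma_pore, sigma_scaffold)

over the raw gray values of the voxels remaining after erosion. Pores with
100 or fewer voxels remaining are excluded from statistical aggregation.

By default the scaffold region is restricted to eroded scaffold voxels
within a configurable distance of the pore surface (a local shell): slow
gray-value drifts across the reconstructed volume — a known artifact of
local tomography and beam-intensity variation — would otherwise inflate the
global scaffold standard deviation and masquerade as noise. A global mode
is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, GrayVolume

__all__ = [
    "SNRResult",
    "ball_element",
    "erode_ball",
    "local_scaffold_shell",
    "pore_snr",
    "aggregate_quality",
    "QualitySummary",
]


def ball_element(radius: int) -> np.ndarray:
    """Digital ball structuring element: voxel centers with ||v||_2 <= radius
    (inclusive), on a (2r+1)^3 grid."""
    if radius < 0:
        raise ValueError("radius must be a non-negative integer")
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zz**2 + yy**2 + xx**2) <= r**2


def erode_ball(mask: BinaryMask | np.ndarray, radius: int = 5) -> np.ndarray:
    """Binary erosion with the inclusive digital ball of ``radius`` voxels.

    Out-of-bounds voxels count as background, so foreground touching the
    array edge erodes inward from the edge as well. Radius 0 is the
    identity.
    """
    m = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if radius == 0:
        return m.copy()
    # A voxel survives erosion by the inclusive ball iff no background voxel
    # lies within Euclidean distance ``radius`` of it, i.e. iff its exact
    # Euclidean distance transform exceeds ``radius``. Padding with
    # background first realizes the out-of-bounds-is-background convention.
    # This is exact (squared distances are integers) and much faster than a
    # structure-based erosion for large balls.
    padded = np.pad(m, 1)
    dt = ndimage.distance_transform_edt(padded)
    return dt[1:-1, 1:-1, 1:-1] > radius


def local_scaffold_shell(
    scaffold_mask: np.ndarray,
    pore_mask_single: np.ndarray,
    shell_radius: float = 15.0,
) -> np.ndarray:
    """Scaffold voxels within ``shell_radius`` voxels of the pore surface."""
    d_out = ndimage.distance_transform_edt(~np.asarray(pore_mask_single, bool))
    return np.asarray(scaffold_mask, bool) & (d_out > 0) & (d_out <= shell_radius)


@dataclass
class SNRResult:
    """Region statistics and SNR of one pore; invalid results carry the
    reason and are excluded from aggregation."""

    label: int
    mu_pore: float
    mu_scaffold: float
    sigma_pore: float
    sigma_scaffold: float
    snr: float
    n_pore_voxels: int
    n_scaffold_voxels: int
    valid: bool
    reason: str = ""


def pore_snr(
    volume: GrayVolume,
    pore_eroded: BinaryMask | np.ndarray,
    scaffold_eroded_local: BinaryMask | np.ndarray,
    min_voxels: int = 100,
    label: int = 0,
) -> SNRResult:
    """SNR of one pore from its eroded pore and local eroded scaffold regions.

    Valid only if strictly more than ``min_voxels`` pore voxels remain after
    erosion and the dividing standard deviation is nonzero; a noiseless
    two-level input yields an infinite-SNR sentinel marked invalid.
    """
    pm = pore_eroded.values if isinstance(pore_eroded, BinaryMask) else np.asarray(pore_eroded, bool)
    sm = (scaffold_eroded_local.values if isinstance(scaffold_eroded_local, BinaryMask)
          else np.asarray(scaffold_eroded_local, bool))
    if np.any(pm & sm):
        raise ValueError("pore and scaffold regions must be disjoint")
    n_p, n_s = int(pm.sum()), int(sm.sum())
    nan = float("nan")
    if n_p == 0 or n_s == 0:
        return SNRResult(label, nan, nan, nan, nan, nan, n_p, n_s,
                         valid=False, reason="empty region after erosion")
    v = volume.values
    mu_p, mu_s = float(v[pm].mean()), float(v[sm].mean())
    sd_p = float(v[pm].std(ddof=1)) if n_p > 1 else 0.0
    sd_s = float(v[sm].std(ddof=1)) if n_s > 1 else 0.0
    denom = max(sd_p, sd_s)
    if denom == 0.0:
        snr = np.inf if mu_p != mu_s else nan
        return SNRResult(label, mu_p, mu_s, sd_p, sd_s, snr, n_p, n_s,
                         valid=False, reason="zero standard deviation")
    snr = (mu_p - mu_s) / denom
    if n_p <= min_voxels:
        return SNRResult(label, mu_p, mu_s, sd_p, sd_s, snr, n_p, n_s,
                         valid=False,
                         reason=f"{n_p} voxels after erosion (need > {min_voxels})")
    return SNRResult(label, mu_p, mu_s, sd_p, sd_s, snr, n_p, n_s, valid=True)


@dataclass
class QualitySummary:
    """Aggregate of valid per-pore metrics, in the shape the per-scan
    comparison tables use: mean +/- sample STD and pore count."""

    n_pores: int
    snr_mean: float | None = None
    snr_std: float | None = None
    n_snr: int = 0
    resolution_mean_nm: float | None = None
    resolution_std_nm: float | None = None
    n_resolution: int = 0
    single_sample: bool = False


def _mean_std(x: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def aggregate_quality(records: Sequence) -> QualitySummary:
    """Mean +/- sample standard deviation (n-1 denominator) of SNR and
    resolution over the valid per-pore records, with counts.

    ``records`` are objects exposing ``snr``/``snr_valid`` and
    ``resolution_nm`` attributes (e.g. PoreQualityRecord); invalid or
    undefined entries are skipped, never counted as zero.
    """
    snrs = [r.snr for r in records
            if getattr(r, "snr_valid", False) and r.snr is not None
            and np.isfinite(r.snr)]
    ress = [r.resolution_nm for r in records
            if getattr(r, "resolution_nm", None) is not None
            and np.isfinite(r.resolution_nm)]
    out = QualitySummary(n_pores=len(list(records)))
    if snrs:
        out.snr_mean, out.snr_std = _mean_std(snrs)
        out.n_snr = len(snrs)
    if ress:
        out.resolution_mean_nm, out.resolution_std_nm = _mean_std(ress)
        out.n_resolution = len(ress)
    out.single_sample = (out.n_snr == 1) or (out.n_resolution == 1)
    return out
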