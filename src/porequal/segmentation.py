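"""Isolated-pore identification and shape-based selection.

An *isolated* (closed) pore is a pore-phase connected component that is not
part of the main pore space — the boundary-reaching pore network — and, when
a mineralized-tissue mask is supplied, is not in contact with that tissue.
Wrongly segmented objects are removed with the size/sphericity rule: only
pores with more than ``min_voxels`` voxels and sphericity S below
``max_sphericity`` enter the analysis (both inequalities strict).

Sphericity here is the scale-free factor S = A / (36 pi V^2)^(1/3) with A a
triangulated-isosurface area and V the voxel-count volume: S = 1 for a
perfect sphere and grows as the object becomes more irregular (note this is
the inverse of the common <=1 sphericity convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._surface import mesh_surface_area
from .volume_io import BinaryMask, GrayVolume, PoreLabelVolume

__all__ = [
    "PoreShape",
    "binarize",
    "find_isolated_pores",
    "pore_shape",
    "sphericity",
    "filter_pores",
    "connectivity_structure",
]

NM_PER_UM = 1.0e3


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D structuring element for 6-, 18- or 26-connectivity."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def binarize(volume: GrayVolume, threshold: float,
             smooth_sigma: float = 0.0) -> BinaryMask:
    """Threshold the gray volume; the pore phase is the brighter phase.

    ``smooth_sigma`` (voxels) optionally applies a Gaussian pre-filter before
    thresholding, to obtain a clean segmentation from a noisy reconstruction;
    the gray values used by the quality metrics are never smoothed.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = volume.values
    if smooth_sigma > 0:
        values = ndimage.gaussian_filter(values.astype(np.float64), smooth_sigma)
    return BinaryMask(values > threshold, volume.voxel_size)


def find_isolated_pores(
    pore_mask: BinaryMask,
    bone_mask: BinaryMask | None = None,
    connectivity: int = 26,
) -> PoreLabelVolume:
    """Label pore components that are isolated from the main pore space.

    Components connected to the volume boundary form the main pore space and
    are dropped; when ``bone_mask`` is given, components whose 1-voxel
    dilation intersects mineralized tissue are dropped too (such pores are
    open to tissue ingrowth). Survivors are relabeled 1..K in scan order.
    """
    if bone_mask is not None and bone_mask.shape != pore_mask.shape:
        raise ValueError("bone mask shape differs from pore mask shape")
    structure = connectivity_structure(connectivity)
    lab, n = ndimage.label(pore_mask.values, structure=structure)
    if n == 0:
        return PoreLabelVolume(lab.astype(np.int32), pore_mask.voxel_size)

    boundary_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(lab, sl, axis=axis)
            boundary_labels.update(np.unique(face[face > 0]).tolist())

    bone_labels: set[int] = set()
    if bone_mask is not None and bone_mask.values.any():
        near_bone = ndimage.binary_dilation(
            bone_mask.values, structure=connectivity_structure(6)
        )
        bone_labels = set(np.unique(lab[near_bone & (lab > 0)]).tolist())

    drop = boundary_labels | bone_labels
    keep = [l for l in range(1, n + 1) if l not in drop]
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    return PoreLabelVolume(remap[lab], pore_mask.voxel_size)


def sphericity(surface_area: float, volume: float) -> float:
    """S = A / (36 pi V^2)^(1/3); 1 for a sphere, > 1 when irregular."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("surface area and volume must be positive")
    return surface_area / (36.0 * np.pi * volume**2) ** (1.0 / 3.0)


@dataclass
class PoreShape:
    """Size and shape descriptors of one labeled pore."""

    label: int
    voxel_count: int
    volume_um3: float
    surface_area_um2: float
    sphericity: float


def pore_shape(labels: PoreLabelVolume, label: int,
               voxel_size: float | None = None) -> PoreShape:
    """Volume (voxel count x voxel volume), triangulated-isosurface area and
    sphericity of one labeled pore. Lengths convert from nm to um."""
    if voxel_size is None:
        voxel_size = labels.voxel_size
    support = labels.values == label
    count = int(support.sum())
    if count == 0:
        raise KeyError(f"label {label} not present")
    # crop to the bounding box; the mesh only needs the local support
    obj = ndimage.find_objects(support.astype(np.int8), max_label=1)[0]
    sub = support[obj]
    vox_um = voxel_size / NM_PER_UM
    volume = count * vox_um**3
    area = mesh_surface_area(sub, vox_um, pad=True)
    return PoreShape(
        label=int(label),
        voxel_count=count,
        volume_um3=volume,
        surface_area_um2=area,
        sphericity=sphericity(area, volume),
    )


def filter_pores(
    shapes: list[PoreShape],
    min_voxels: int = 1000,
    max_sphericity: float = 1.3,
) -> list[int]:
    """Labels of pores with strictly more than ``min_voxels`` voxels and
    sphericity strictly below ``max_sphericity``."""
    return [
        s.label
        for s in shapes
        if s.voxel_count > min_voxels and s.sphericity < max_sphericity
    ]
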