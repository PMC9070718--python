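"""Three-phase morphometry of scaffold / mineralized tissue / pore volumes.

Quantities with direct biological reading for a bone-substitute scaffold:

* per-phase volume;
* scaffold surface area, with and without the surfaces of closed porosities
  (cavities fully enclosed by the scaffold, inaccessible to tissue);
* specific surface area — surface area per unit *bulk* volume (um^-1) — and
  the surface-to-volume ratio normalized by the *phase* volume instead (both
  normalizations are reported, explicitly labeled);
* the fraction of the available scaffold surface covered by mineralized
  tissue.

Areas use the same triangulated-isosurface estimator as the pore shape
code; faces on the boundary of the analyzed cube are excluded everywhere
(they are truncation artifacts of imaging a region smaller than the
sample). Coverage, by contrast, is a topological adjacency question and is
counted on voxel faces (6-neighborhood), not on the mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._surface import mesh_surface_area
from .volume_io import GrayVolume

__all__ = [
    "PhaseMap",
    "MorphometryReport",
    "PHASE_PORE",
    "PHASE_SCAFFOLD",
    "PHASE_BONE",
    "three_phase_segment",
    "specific_surface",
    "surface_coverage",
    "closed_pore_mask",
    "morphometry_report",
]

PHASE_PORE = 0
PHASE_SCAFFOLD = 1
PHASE_BONE = 2

NM_PER_UM = 1.0e3


@dataclass
class PhaseMap:
    """Voxel phase codes: 0 pore/void, 1 scaffold, 2 mineralized tissue."""

    values: np.ndarray
    voxel_size: float  # nm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("phase map must be 3D")
        bad = set(np.unique(self.values)) - {PHASE_PORE, PHASE_SCAFFOLD, PHASE_BONE}
        if bad:
            raise ValueError(f"unknown phase codes {sorted(bad)}")

    def mask(self, phase: int) -> np.ndarray:
        return self.values == phase

    @property
    def voxel_um(self) -> float:
        return self.voxel_size / NM_PER_UM


def three_phase_segment(
    volume: GrayVolume,
    t_low: float,
    t_high: float,
    mapping: tuple[int, int, int] = (PHASE_BONE, PHASE_SCAFFOLD, PHASE_PORE),
) -> PhaseMap:
    """Two-threshold segmentation into three phases.

    ``mapping`` assigns phase codes to the (below t_low, between, above
    t_high) gray bands; the default puts mineralized tissue darkest and the
    pore phase brightest, but the brightness ordering of phases depends on
    the reconstruction convention, so any permutation may be supplied.
    """
    if not (np.isfinite(t_low) and np.isfinite(t_high)):
        raise ValueError("thresholds must be finite")
    if not t_low < t_high:
        raise ValueError("t_low must be below t_high")
    if sorted(mapping) != [PHASE_PORE, PHASE_SCAFFOLD, PHASE_BONE]:
        raise ValueError("mapping must be a permutation of the three phase codes")
    v = volume.values
    out = np.full(v.shape, mapping[1], dtype=np.int8)
    out[v < t_low] = mapping[0]
    out[v >= t_high] = mapping[2]
    if not (out == PHASE_SCAFFOLD).any():
        warnings.warn("segmentation produced an empty scaffold phase")
    return PhaseMap(out, volume.voxel_size)


def closed_pore_mask(phase_map: PhaseMap, connectivity: int = 26) -> np.ndarray:
    """Pore-phase components that do not reach the volume boundary — the
    closed porosities, inaccessible to tissue ingrowth."""
    from .segmentation import connectivity_structure

    pore = phase_map.mask(PHASE_PORE)
    lab, n = ndimage.label(pore, structure=connectivity_structure(connectivity))
    if n == 0:
        return np.zeros_like(pore)
    open_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(lab, sl, axis=axis)
            open_labels.update(np.unique(face[face > 0]).tolist())
    closed = np.isin(lab, [l for l in range(1, n + 1) if l not in open_labels])
    return closed & pore


def specific_surface(
    phase_map: PhaseMap,
    phase: int = PHASE_SCAFFOLD,
    include_closed: bool = True,
) -> dict[str, float]:
    """Surface measures of one phase.

    Returns a dict with the raw triangulated area (um^2), the specific
    surface area (area / bulk volume of the analyzed region, um^-1) and the
    surface-to-volume ratio (area / phase volume, um^-1). With
    ``include_closed=False`` interior cavities fully enclosed by the phase
    are filled before meshing, removing their surfaces. Boundary faces of
    the analyzed cube never contribute.
    """
    mask = phase_map.mask(phase)
    if not mask.any():
        raise ValueError(f"phase {phase} absent from the volume")
    if not include_closed:
        mask = ndimage.binary_fill_holes(mask)
    vox_um = phase_map.voxel_um
    area = mesh_surface_area(mask, vox_um, pad=False)
    bulk_volume = float(np.prod(mask.shape)) * vox_um**3
    phase_volume = float(mask.sum()) * vox_um**3
    return {
        "surface_area_um2": area,
        "specific_surface_um_inv": area / bulk_volume,
        "surface_to_volume_um_inv": area / phase_volume,
        "phase_volume_um3": phase_volume,
        "bulk_volume_um3": bulk_volume,
    }


_FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def surface_coverage(phase_map: PhaseMap) -> float:
    """Fraction of the available scaffold surface covered by mineralized
    tissue.

    Counted on scaffold voxel faces (6-adjacency): a face is *available* if
    its neighbor is open pore or mineralized tissue — faces toward closed
    porosities are excluded (tissue cannot reach them), as are faces on the
    analyzed-cube boundary. Coverage is the covered (tissue-adjacent)
    fraction of the available faces.
    """
    scaffold = phase_map.mask(PHASE_SCAFFOLD)
    if not scaffold.any():
        raise ValueError("scaffold phase absent")
    closed = closed_pore_mask(phase_map)
    bone = phase_map.mask(PHASE_BONE)
    open_pore = phase_map.mask(PHASE_PORE) & ~closed

    available = 0
    covered = 0
    for dz, dy, dx in _FACE_OFFSETS:
        nb_bone = _shift(bone, dz, dy, dx)
        nb_open = _shift(open_pore, dz, dy, dx)
        available += int((scaffold & (nb_bone | nb_open)).sum())
        covered += int((scaffold & nb_bone).sum())
    if available == 0:
        raise ValueError("scaffold has no available surface faces")
    return covered / available


def _shift(mask: np.ndarray, dz: int, dy: int, dx: int) -> np.ndarray:
    """Neighbor lookup with out-of-bounds treated as 'no neighbor' (False)."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, d in enumerate((dz, dy, dx)):
        if d == 1:
            src[axis], dst[axis] = slice(1, None), slice(None, -1)
        elif d == -1:
            src[axis], dst[axis] = slice(None, -1), slice(1, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


@dataclass
class MorphometryReport:
    """Complete three-phase morphometric summary."""

    voxel_size_nm: float
    phase_volumes_um3: dict[str, float]
    scaffold_surface_incl_closed_um2: float
    scaffold_surface_excl_closed_um2: float
    specific_surface_incl_closed_um_inv: float
    specific_surface_excl_closed_um_inv: float
    surface_to_volume_incl_closed_um_inv: float
    surface_to_volume_excl_closed_um_inv: float
    coverage_fraction: float | None

    def as_dict(self) -> dict:
        return {
            "voxel_size_nm": self.voxel_size_nm,
            "phase_volumes_um3": self.phase_volumes_um3,
            "scaffold_surface_incl_closed_um2": self.scaffold_surface_incl_closed_um2,
            "scaffold_surface_excl_closed_um2": self.scaffold_surface_excl_closed_um2,
            "specific_surface_incl_closed_um_inv": self.specific_surface_incl_closed_um_inv,
            "specific_surface_excl_closed_um_inv": self.specific_surface_excl_closed_um_inv,
            "surface_to_volume_incl_closed_um_inv": self.surface_to_volume_incl_closed_um_inv,
            "surface_to_volume_excl_closed_um_inv": self.surface_to_volume_excl_closed_um_inv,
            "coverage_fraction": self.coverage_fraction,
        }


def morphometry_report(phase_map: PhaseMap) -> MorphometryReport:
    """Run the full morphometric analysis on a three-phase segmentation."""
    vox_um = phase_map.voxel_um
    names = {PHASE_PORE: "pore", PHASE_SCAFFOLD: "scaffold", PHASE_BONE: "mineralized_tissue"}
    volumes = {
        name: float(phase_map.mask(code).sum()) * vox_um**3
        for code, name in names.items()
    }
    incl = specific_surface(phase_map, PHASE_SCAFFOLD, include_closed=True)
    excl = specific_surface(phase_map, PHASE_SCAFFOLD, include_closed=False)
    try:
        coverage = surface_coverage(phase_map)
    except ValueError:
        coverage = None
    return MorphometryReport(
        voxel_size_nm=phase_map.voxel_size,
        phase_volumes_um3=volumes,
        scaffold_surface_incl_closed_um2=incl["surface_area_um2"],
        scaffold_surface_excl_closed_um2=excl["surface_area_um2"],
        specific_surface_incl_closed_um_inv=incl["specific_surface_um_inv"],
        specific_surface_excl_closed_um_inv=excl["specific_surface_um_inv"],
        surface_to_volume_incl_closed_um_inv=incl["surface_to_volume_um_inv"],
        surface_to_volume_excl_closed_um_inv=excl["surface_to_volume_um_inv"],
        coverage_fraction=coverage,
    )
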