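"""Triangulated-isosurface area estimation shared by shape and morphometry code.

Voxel-face counting overestimates the area of smooth objects (by ~1.5x for a
sphere) and would distort any surface-derived shape factor, so all areas are
measured on a marching-cubes mesh at level 0.5. A mild Gaussian smoothing of
the binary support (sigma 0.7 voxel) precedes meshing: marching cubes applied
to a raw 0/1 field produces a stair-stepped mesh that overestimates a
digitized sphere's area by ~9%, while the smoothed field meshes to ~1%. The
0.5 level of a symmetrically smoothed interface stays on the original
surface, so the smoothing does not displace it; the width is kept small so
that sharp edges (cube-like objects) lose under 3% of their area to corner
rounding at half-widths of 10 voxels and above.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = ["mesh_surface_area"]


def mesh_surface_area(mask: np.ndarray, voxel_size: float = 1.0,
                      pad: bool = True, smooth_sigma: float = 0.7) -> float:
    """Area of the triangulated isosurface of a binary mask.

    With ``pad=True`` the mask is zero-padded so objects touching the array
    edge are closed by the mesh; with ``pad=False`` no surface is generated
    at the array boundary (used where boundary faces must be excluded).
    Structures too thin to survive the smoothing fall back to the unsmoothed
    mesh. Returns the area in units of ``voxel_size**2``.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0.0
    vol = np.pad(m, 2).astype(np.float32) if pad else m.astype(np.float32)
    for sigma in (smooth_sigma, 0.0):
        field = ndimage.gaussian_filter(vol, sigma, mode="nearest") if sigma else vol
        if field.min() >= 0.5 or field.max() < 0.5:
            continue  # no 0.5-crossing (uniform phase, or over-smoothed)
        try:
            verts, faces, _, _ = measure.marching_cubes(field, level=0.5)
        except (ValueError, RuntimeError):
            continue
        area = float(measure.mesh_surface_area(verts, faces))
        if area > 0:
            return area * voxel_size**2
    return 0.0
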