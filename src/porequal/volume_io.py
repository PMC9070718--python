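"""Containers and I/O for gray volumes, masks, label volumes and per-pore tables.

Index convention is (z, y, x), 0-based, with voxel centers on the integer
lattice. ``voxel_size`` is the isotropic voxel edge length in nanometres;
every physical length reported by the package derives from it.

Supported on-disk formats:

* multi-page TIFF (one page per z-slice), voxel size carried in the ImageJ
  ``spacing`` tag and mirrored in an optional JSON sidecar;
* a directory of numbered single-slice TIFFs, assembled in numeric order;
* raw binary with a mandatory JSON sidecar declaring shape, dtype, byte
  order and voxel size (z-slowest index order).

Tables of per-pore records are plain CSV with a stable header.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GrayVolume",
    "BinaryMask",
    "PoreLabelVolume",
    "read_volume",
    "write_volume",
    "write_pore_table",
    "read_pore_table",
    "to_8bit",
    "PORE_TABLE_COLUMNS",
]


@dataclass
class GrayVolume:
    """A reconstructed 3D scalar field with physical voxel size.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Gray values; floating point or integer.
    voxel_size : float
        Isotropic voxel edge length in nanometres (> 0).
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0); informational only.
    """

    values: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("gray values must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A boolean phase mask sharing the geometry of its parent volume."""

    values: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class PoreLabelVolume:
    """Integer-labeled isolated pores; 0 is background, labels are 1..K."""

    values: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if self.values.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present in the volume."""
        u = np.unique(self.values)
        return u[u > 0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


# --------------------------------------------------------------------------
# volume I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_volume(volume: GrayVolume | BinaryMask | PoreLabelVolume, path: str | Path) -> None:
    """Write a volume to disk.

    ``.tif``/``.tiff`` paths produce a multi-page TIFF with the voxel size in
    the ImageJ metadata plus a JSON sidecar; ``.raw`` paths produce raw
    binary (C order, z-slowest) with a mandatory JSON sidecar.
    """
    path = Path(path)
    values = volume.values
    if isinstance(volume, BinaryMask):
        values = values.astype(np.uint8)
    voxel_size = float(getattr(volume, "voxel_size", 1.0))
    meta = {
        "shape": list(values.shape),
        "dtype": values.dtype.str,  # carries byte order, e.g. '<f4'
        "voxel_size_nm": voxel_size,
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values, imagej=values.dtype in
                         (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
                         metadata={"spacing": voxel_size, "unit": "nm"})
    elif path.suffix.lower() == ".raw":
        values.tofile(path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


_SLICE_NUM = re.compile(r"(\d+)")


def _read_slice_dir(path: Path) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise FileNotFoundError(f"no TIFF slices in {path}")
    keyed = []
    for p in files:
        m = _SLICE_NUM.findall(p.stem)
        if not m:
            raise ValueError(f"slice file {p.name} carries no numeric index")
        keyed.append((int(m[-1]), p))
    keyed.sort(key=lambda kp: kp[0])
    nums = [k for k, _ in keyed]
    if len(set(nums)) != len(nums):
        raise ValueError("non-monotonic slice numbering: duplicate indices")
    planes = [tifffile.imread(p) for _, p in keyed]
    return np.stack(planes, axis=0)


def read_volume(path: str | Path, voxel_size: float | None = None) -> GrayVolume:
    """Read a gray volume from TIFF stack, slice directory, or raw + sidecar.

    ``voxel_size`` (nm) overrides any value found in metadata; for raw files
    the sidecar is mandatory and declares shape/dtype/byte order.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists() and sidecar != path:
        meta = json.loads(sidecar.read_text())

    if path.is_dir():
        values = _read_slice_dir(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
        if values.ndim == 2:
            values = values[None]
        if voxel_size is None and not meta:
            with tifffile.TiffFile(path) as tf:
                ij = tf.imagej_metadata or {}
                if "spacing" in ij:
                    meta["voxel_size_nm"] = float(ij["spacing"])
    elif path.suffix.lower() == ".raw":
        if not meta:
            raise FileNotFoundError(
                f"raw volume {path} requires a JSON sidecar {sidecar} "
                "declaring shape, dtype and voxel size"
            )
        shape = tuple(meta["shape"])
        dtype = np.dtype(meta["dtype"])
        values = np.fromfile(path, dtype=dtype)
        if values.size != int(np.prod(shape)):
            raise ValueError(
                f"raw file holds {values.size} voxels, sidecar declares {shape}"
            )
        values = values.reshape(shape)
    else:
        raise ValueError(f"unsupported volume format: {path}")

    if voxel_size is None:
        voxel_size = float(meta.get("voxel_size_nm", 1.0))
    return GrayVolume(values=values, voxel_size=voxel_size)


def to_8bit(volume: GrayVolume) -> GrayVolume:
    """Linear min-max rescale to uint8. Explicit, never applied implicitly."""
    v = volume.values.astype(np.float64)
    lo, hi = v.min(), v.max()
    if hi == lo:
        out = np.zeros_like(v, dtype=np.uint8)
    else:
        out = np.round((v - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return GrayVolume(out, volume.voxel_size, volume.origin)


# --------------------------------------------------------------------------
# per-pore tables

PORE_TABLE_COLUMNS = [
    "id",
    "voxel_count",
    "volume_um3",
    "surface_area_um2",
    "sphericity",
    "snr",
    "resolution_nm",
    "passed_size_filter",
    "passed_shape_filter",
    "passed_erosion_filter",
]


def write_pore_table(records: Sequence, path: str | Path) -> None:
    """Write per-pore quality records as CSV with the stable documented header.

    Undefined quantities (e.g. resolution for a failed fit) are written as
    empty cells, never as 0.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.label,
                "voxel_count": r.voxel_count,
                "volume_um3": r.volume_um3,
                "surface_area_um2": r.surface_area_um2,
                "sphericity": r.sphericity,
                "snr": r.snr if r.snr is not None and np.isfinite(r.snr) else None,
                "resolution_nm": r.resolution_nm,
                "passed_size_filter": r.passed_size_filter,
                "passed_shape_filter": r.passed_shape_filter,
                "passed_erosion_filter": r.passed_erosion_filter,
            }
        )
    df = pd.DataFrame(rows, columns=PORE_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_pore_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
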