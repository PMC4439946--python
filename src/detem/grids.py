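"""Voxel raster containers shared by the whole pipeline.

All volumes live on a common axis convention: array index ``[ix, iy, iz]``
maps to physical ``x`` (lateral), ``y`` (anterior-posterior) and ``z``
(superior-inferior).  ``origin`` is the physical coordinate (mm) of the
*center* of voxel ``(0, 0, 0)``; ``spacing`` is the per-axis voxel size in mm.
Volumes are serialized as MetaImage (.mhd header + little-endian .raw payload)
through SimpleITK, densities and doses as 32-bit float, masks as 8-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "DensityVolume",
    "DoseGrid",
    "StructureSet",
    "write_mhd",
    "read_density",
    "read_dose",
    "read_mask",
]


@dataclass
class _Raster:
    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.data.ndim != 3:
            raise ValueError("raster data must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_geometry(self, other: "_Raster", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def voxel_centers(self, flat_index: np.ndarray) -> np.ndarray:
        """Physical (n, 3) coordinates of voxel centers for flat C-order indices."""
        idx = np.stack(np.unravel_index(np.asarray(flat_index), self.shape), axis=-1)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class DensityVolume(_Raster):
    """3D mass-density raster (g/cm^3) representing the patient/phantom."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if any(n < 8 for n in self.shape):
            raise ValueError("density volume must be at least 8 voxels per axis")
        if np.any(self.data < 0):
            raise ValueError("mass density must be nonnegative")
        self.data = np.ascontiguousarray(self.data, dtype=np.float32)


@dataclass
class DoseGrid(_Raster):
    """3D dose-to-water raster (Gy) on the phantom geometry."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dose values must be finite")
        if np.any(self.data < 0):
            raise ValueError("dose values must be nonnegative")
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)


REQUIRED_STRUCTURES = ("CTV", "PTV", "ring", "body")


@dataclass
class StructureSet:
    """Named boolean masks (CTV, PTV, ring, body, ...) on a shared grid."""

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    validate: bool = True

    def __post_init__(self) -> None:
        self.masks = {k: np.ascontiguousarray(v, dtype=bool) for k, v in self.masks.items()}
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.validate:
            self.check()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def check(self) -> None:
        """Enforce the construction invariants of a planning structure set."""
        for name in REQUIRED_STRUCTURES:
            if name not in self.masks:
                raise ValueError(f"structure set is missing required mask {name!r}")
            if not self.masks[name].any():
                raise ValueError(f"required structure {name!r} is empty")
        ctv, ptv, ring, body = (self.masks[n] for n in REQUIRED_STRUCTURES)
        if ctv.shape != ptv.shape or ptv.shape != body.shape or ring.shape != body.shape:
            raise ValueError("all structure masks must share one grid")
        if np.any(ctv & ~ptv):
            raise ValueError("CTV must be contained in PTV")
        if np.any(ptv & ~body):
            raise ValueError("PTV must be contained in body")
        if np.any(ring & ptv):
            raise ValueError("ring must be disjoint from PTV")

    def volume_cc(self, name: str) -> float:
        """Structure volume in cm^3."""
        return float(self.masks[name].sum()) * float(np.prod(self.spacing)) / 1000.0


# ---------------------------------------------------------------------------
# MetaImage I/O.  SimpleITK arrays are indexed [z, y, x]; ours are [x, y, z].
# ---------------------------------------------------------------------------

def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_mhd(path: str | Path, raster: _Raster | np.ndarray, *, spacing=None,
              origin=None, dtype=None) -> Path:
    """Write a raster (or raw mask array) as an uncompressed .mhd/.raw pair."""
    path = Path(path)
    if isinstance(raster, _Raster):
        data, spacing, origin = raster.data, raster.spacing, raster.origin
        if dtype is None:
            dtype = np.float32
    else:
        data = np.asarray(raster)
        if spacing is None:
            raise ValueError("spacing required when writing a bare array")
        origin = origin if origin is not None else (0.0, 0.0, 0.0)
        if dtype is None:
            dtype = np.uint8 if data.dtype == bool else np.float32
    img = _to_sitk(data.astype(dtype), spacing, origin)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


def _read(path: str | Path):
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_density(path: str | Path) -> DensityVolume:
    data, spacing, origin = _read(path)
    return DensityVolume(data=data, spacing=spacing, origin=origin)


def read_dose(path: str | Path) -> DoseGrid:
    data, spacing, origin = _read(path)
    return DoseGrid(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    data, spacing, origin = _read(path)
    return data.astype(bool), spacing, origin
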