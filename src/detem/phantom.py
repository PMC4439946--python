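"""Synthetic voxel phantoms with planning structures and material assignment.

The default phantom emulates a challenging head-and-neck geometry: a
water-density cylindrical body with an air cavity directly abutting a
spherical CTV, so that pencil beams from some directions traverse a large
low-density heterogeneity just upstream of the target.  The CTV is expanded
by an isotropic setup margin into a PTV, and a surrounding shell ("ring")
acts as a worst-case normal-tissue surrogate.

Materials are assigned from mass density by fixed thresholds (air, adipose,
water, muscle, dense bone), and each material carries a nominal relative
proton stopping power (RSP).  A voxel's RSP is the material RSP scaled by the
ratio of its density to the material's nominal density, which reduces exactly
to 1.0 for water and 0.0012 for air in the synthetic phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import DensityVolume, StructureSet

__all__ = [
    "MATERIAL_NAMES",
    "MaterialMap",
    "PhantomSpec",
    "assign_materials",
    "expand_margin",
    "make_ring",
    "make_phantom",
]

MATERIAL_NAMES = ("Air", "Adipose", "Water", "Muscle", "DenseBone")

# Density partition (g/cm^3).  The published thresholds use strict
# inequalities on both sides; we close each interval at its lower bound so
# every nonnegative density maps to exactly one material:
#   Air: rho < 0.207; Adipose: 0.207 <= rho < 0.979; Water: 0.979 <= rho < 1.0;
#   Muscle: 1.0 <= rho < 1.109; DenseBone: rho >= 1.109.
# float32 so a density stored in single precision at a printed threshold
# compares equal to the edge and lands in the lower-closed interval
DENSITY_EDGES = np.array([0.207, 0.979, 1.0, 1.109], dtype=np.float32)

# Relative stopping power per material, with nominal densities chosen equal
# to the RSP values so the density-ratio scaling is continuous across the
# threshold boundaries (a voxel of density 1.0 then has RSP exactly 1.0 even
# though the lower-closed convention labels it Muscle).
NOMINAL_DENSITY = np.array([0.0012, 0.96, 1.0, 1.04, 1.6])
RSP_TABLE = np.array([0.0012, 0.96, 1.0, 1.04, 1.6])

AIR_DENSITY = 0.0012
WATER_DENSITY = 1.0


@dataclass
class MaterialMap:
    """Per-voxel material labels plus the material -> RSP lookup."""

    labels: np.ndarray  # uint8, index into MATERIAL_NAMES
    rsp_table: np.ndarray = field(default_factory=lambda: RSP_TABLE.copy())
    nominal_density: np.ndarray = field(default_factory=lambda: NOMINAL_DENSITY.copy())

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        self._rsp_cache: np.ndarray | None = None

    def material_name(self, label: int) -> str:
        return MATERIAL_NAMES[label]

    def relative_stopping_power(self, dv: DensityVolume) -> np.ndarray:
        """Voxelwise RSP: material RSP scaled by density / nominal density."""
        if self._rsp_cache is None:
            rsp = self.rsp_table[self.labels] * (
                dv.data.astype(np.float64) / self.nominal_density[self.labels]
            )
            self._rsp_cache = np.ascontiguousarray(rsp)
        return self._rsp_cache


def assign_materials(dv: DensityVolume) -> MaterialMap:
    """Label every voxel by its density interval.

    The partition is total: every finite nonnegative density maps to exactly
    one of Air, Adipose, Water, Muscle, DenseBone (intervals closed at the
    lower bound).
    """
    if np.any(dv.data < 0):
        raise ValueError("densities must be nonnegative")
    labels = np.searchsorted(
        DENSITY_EDGES, dv.data.astype(np.float32), side="right"
    ).astype(np.uint8)
    return MaterialMap(labels=labels)


def expand_margin(mask: np.ndarray, margin_mm: float,
                  spacing: tuple[float, float, float]) -> np.ndarray:
    """Isotropic expansion of a boolean mask by a physical margin.

    A voxel belongs to the result iff the Euclidean distance from its center
    to the nearest voxel center of the input mask is <= ``margin_mm``
    (anisotropic spacing respected).  Monotone in the margin and always a
    superset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if margin_mm < 0:
        raise ValueError("margin must be nonnegative")
    if not mask.any():
        raise ValueError("cannot expand an empty mask")
    if margin_mm == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm + 1e-9


def make_ring(ptv: np.ndarray, thickness_mm: float,
              spacing: tuple[float, float, float],
              body: np.ndarray | None = None) -> np.ndarray:
    """Shell of given thickness around the PTV, clipped to the body."""
    if thickness_mm <= 0:
        raise ValueError("ring thickness must be positive")
    ring = expand_margin(ptv, thickness_mm, spacing) & ~np.asarray(ptv, dtype=bool)
    if body is not None:
        ring &= np.asarray(body, dtype=bool)
    return ring


@dataclass
class PhantomSpec:
    """Geometry of the synthetic phantom (all lengths in mm).

    Defaults give a 160 mm diameter water cylinder (axis along z), a 25 mm
    radius spherical CTV at the isocenter, and a 20 mm radius spherical air
    cavity tangent to the CTV on the lateral (-x) side.
    """

    body_radius: float = 80.0
    body_length: float = 108.0
    ctv_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ctv_radius: float = 25.0
    cavity_center: tuple[float, float, float] | None = (-45.0, 0.0, 0.0)
    cavity_radius: float = 20.0
    ptv_margin: float = 5.0
    ring_thickness: float = 10.0
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    air_pad: float = 6.0
    body_density: float = WATER_DENSITY
    air_density: float = AIR_DENSITY

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        kwargs = dict(d)
        for key in ("ctv_center", "cavity_center", "spacing"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)

    @property
    def ctv_volume_cc(self) -> float:
        return 4.0 / 3.0 * np.pi * self.ctv_radius**3 / 1000.0


def _sphere(x, y, z, center, radius) -> np.ndarray:
    cx, cy, cz = center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2


def make_phantom(spec: PhantomSpec) -> tuple[DensityVolume, StructureSet]:
    """Rasterize a phantom spec into a density volume plus structure set.

    Raises if the CTV is not entirely inside the body, or if the air cavity
    overlaps the CTV interior (it must abut, not intersect).
    """
    sx, sy, sz = spec.spacing
    half_xy = spec.body_radius + spec.air_pad
    half_z = spec.body_length / 2.0 + spec.air_pad
    nx = int(np.ceil(2 * half_xy / sx))
    ny = int(np.ceil(2 * half_xy / sy))
    nz = int(np.ceil(2 * half_z / sz))
    origin = (-(nx - 1) / 2.0 * sx, -(ny - 1) / 2.0 * sy, -(nz - 1) / 2.0 * sz)

    cx, cy, cz = spec.ctv_center
    if np.hypot(cx, cy) + spec.ctv_radius > spec.body_radius:
        raise ValueError("CTV extends outside the body cylinder radially")
    if abs(cz) + spec.ctv_radius > spec.body_length / 2.0:
        raise ValueError("CTV extends outside the body cylinder axially")
    if spec.cavity_center is not None:
        gap = float(np.linalg.norm(np.subtract(spec.cavity_center, spec.ctv_center)))
        if gap < spec.ctv_radius + spec.cavity_radius - 1e-9:
            raise ValueError("air cavity overlaps the CTV; it must abut the CTV")
        if (np.hypot(*spec.cavity_center[:2]) + spec.cavity_radius > spec.body_radius
                or abs(spec.cavity_center[2]) + spec.cavity_radius > spec.body_length / 2.0):
            raise ValueError("air cavity extends outside the body")

    x = (origin[0] + sx * np.arange(nx))[:, None, None]
    y = (origin[1] + sy * np.arange(ny))[None, :, None]
    z = (origin[2] + sz * np.arange(nz))[None, None, :]

    body = (x**2 + y**2 <= spec.body_radius**2) & (np.abs(z) <= spec.body_length / 2.0)
    body = np.broadcast_to(body, (nx, ny, nz)).copy()

    density = np.full((nx, ny, nz), spec.air_density, dtype=np.float32)
    density[body] = spec.body_density
    if spec.cavity_center is not None:
        cavity = _sphere(x, y, z, spec.cavity_center, spec.cavity_radius)
        density[cavity & body] = spec.air_density

    ctv = _sphere(x, y, z, spec.ctv_center, spec.ctv_radius) & body
    if not ctv.any():
        raise ValueError("CTV rasterized to an empty mask; check spacing vs radius")
    ptv = expand_margin(ctv, spec.ptv_margin, spec.spacing) & body
    ring = make_ring(ptv, spec.ring_thickness, spec.spacing, body=body)

    dv = DensityVolume(data=density, spacing=spec.spacing, origin=origin)
    structures = StructureSet(
        masks={"CTV": ctv, "PTV": ptv, "ring": ring, "body": body},
        spacing=spec.spacing,
        origin=origin,
    )
    return dv, structures
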