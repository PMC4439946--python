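"""Fractionated delivery under random rigid setup shifts.

Per-fraction translational setup errors are drawn independently per axis
from a zero-mean Gaussian (sigma 2 mm) truncated by rejection at +/-4 mm per
axis, with an additional rejection of whole vectors whose 3D norm exceeds
6 mm (so both printed bounds of the uncertainty model hold simultaneously;
the 3D bound can be disabled).  A shift is applied as a translation of every
beam's isocenter by the negated shift - the exact rigid equivalent of moving
the patient, with no resampling - and each fraction's dose is a full
recomputation through the shifted geometry, so pencil-beam ranges respond to
the shifted water-equivalent path lengths (the undershoot/overshoot
mechanism the energy margin exists to counter).  One shift set is shared by
the ORG and EM deliveries so the comparison is paired by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._engine import DoseCalculator, EngineParams
from .fluence_opt import TreatmentPlan
from .grids import DensityVolume, DoseGrid
from .phantom import MaterialMap

__all__ = [
    "ShiftSet",
    "FractionDoseSet",
    "sample_shifts",
    "deliver_fraction",
    "simulate_course",
]


@dataclass
class ShiftSet:
    """Per-fraction rigid translations (mm): columns x (lateral), y (AP), z (SI)."""

    shifts: np.ndarray
    sigma: float = 2.0
    cutoff: float = 4.0
    max_3d: float | None = 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.shifts = np.ascontiguousarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 3:
            raise ValueError("shifts must be an (n, 3) array")
        if np.any(np.abs(self.shifts) > self.cutoff + 1e-12):
            raise ValueError("shift component exceeds the per-axis cutoff")

    @property
    def n_fractions(self) -> int:
        return self.shifts.shape[0]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} sigma={self.sigma} cutoff={self.cutoff} "
                     f"max_3d={self.max_3d}\n")
            fh.write("fraction,dx,dy,dz\n")
            for i, (dx, dy, dz) in enumerate(self.shifts):
                fh.write(f"{i},{float(dx)!r},{float(dy)!r},{float(dz)!r}\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "ShiftSet":
        path = Path(path)
        text = path.read_text().splitlines()
        header = dict(kv.split("=") for kv in text[0].lstrip("# ").split())
        data = np.loadtxt(io.StringIO("\n".join(text[2:])), delimiter=",")
        data = np.atleast_2d(data)
        seed = None if header["seed"] == "None" else int(header["seed"])
        max_3d = None if header["max_3d"] == "None" else float(header["max_3d"])
        return cls(shifts=data[:, 1:4], sigma=float(header["sigma"]),
                   cutoff=float(header["cutoff"]), max_3d=max_3d, seed=seed)


def sample_shifts(n_fractions: int = 30, sigma: float = 2.0, cutoff: float = 4.0,
                  seed: int | None = None, max_3d: float | None = 6.0) -> ShiftSet:
    """Rejection-sampled truncated-Gaussian setup shifts.

    Components with |value| > ``cutoff`` are redrawn (rejection, not
    clipping, so no probability mass piles up at the bound); if ``max_3d``
    is set, whole vectors with 3D norm above it are redrawn as well.
    Reproducible under a fixed seed.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rng = np.random.default_rng(seed)
    shifts = np.empty((n_fractions, 3))
    for i in range(n_fractions):
        while True:
            vec = rng.normal(0.0, sigma, size=3)
            while np.any(np.abs(vec) > cutoff):
                bad = np.abs(vec) > cutoff
                vec[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
            if max_3d is None or np.linalg.norm(vec) <= max_3d:
                break
        shifts[i] = vec
    return ShiftSet(shifts=shifts, sigma=sigma, cutoff=cutoff, max_3d=max_3d,
                    seed=seed)


@dataclass
class FractionDoseSet:
    """Per-fraction dose values, optionally restricted to evaluation voxels.

    ``values`` is (n_fractions, n_voxels); ``voxel_flat`` holds the flat grid
    indices the values refer to (None means the full grid in C order).
    """

    values: np.ndarray
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    voxel_flat: np.ndarray | None = None

    @property
    def n_fractions(self) -> int:
        return self.values.shape[0]

    def total(self) -> np.ndarray:
        """Summed physical dose per evaluation voxel."""
        return self.values.sum(axis=0)

    def values_in(self, mask: np.ndarray) -> np.ndarray:
        """Per-fraction values restricted to a boolean grid mask."""
        want = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
        if self.voxel_flat is None:
            return self.values[:, want]
        pos = np.searchsorted(self.voxel_flat, want)
        if np.any(pos >= self.voxel_flat.size) or np.any(self.voxel_flat[pos] != want):
            raise ValueError("mask is not contained in the evaluated voxel set")
        return self.values[:, pos]


def deliver_fraction(dv: DensityVolume, mm: MaterialMap, plan: TreatmentPlan,
                     shift, n_fractions: int = 30,
                     params: EngineParams | None = None,
                     calculator: DoseCalculator | None = None) -> DoseGrid:
    """Full recomputation of one fraction's dose under a rigid shift,
    scaled to 1/n_fractions of the plan weights."""
    if plan.weights is None:
        raise ValueError("treatment plan has no optimized weights")
    calc = calculator or DoseCalculator(dv, mm, plan.spot_plan.spots,
                                        energy_column=plan.energy, params=params)
    return calc.dose_grid(np.asarray(plan.weights) / n_fractions, shift=shift)


def _course(calc: DoseCalculator, weights: np.ndarray, shift_set: ShiftSet,
            voxel_flat: np.ndarray | None, dv: DensityVolume) -> FractionDoseSet:
    n = shift_set.n_fractions
    per_fraction = np.asarray(weights, dtype=float) / n
    n_vox = int(np.prod(dv.shape)) if voxel_flat is None else voxel_flat.size
    values = np.empty((n, n_vox), dtype=np.float32)
    for i in range(n):
        values[i] = calc.dose_flat(per_fraction, shift=shift_set.shifts[i],
                                   voxel_flat=voxel_flat)
    return FractionDoseSet(values=values, grid_shape=dv.shape,
                           spacing=dv.spacing, origin=dv.origin,
                           voxel_flat=voxel_flat)


def simulate_course(dv: DensityVolume, mm: MaterialMap, org: TreatmentPlan,
                    em: TreatmentPlan, shift_set: ShiftSet,
                    eval_mask: np.ndarray | None = None,
                    params: EngineParams | None = None,
                    calculators: tuple[DoseCalculator, DoseCalculator] | None = None,
                    ) -> tuple[FractionDoseSet, FractionDoseSet]:
    """Deliver both plans over the *same* shift set, fraction by fraction.

    ``eval_mask`` restricts the computed voxels (e.g. CTV plus ring) for
    desk-scale course simulation; None computes full grids.
    """
    for plan in (org, em):
        if plan.weights is None:
            raise ValueError(f"{plan.label} plan has no optimized weights")
    voxel_flat = (None if eval_mask is None
                  else np.flatnonzero(np.asarray(eval_mask, dtype=bool).ravel()))
    if calculators is None:
        calc_org = DoseCalculator(dv, mm, org.spot_plan.spots,
                                  energy_column=org.energy, params=params)
        calc_em = DoseCalculator(dv, mm, em.spot_plan.spots,
                                 energy_column=em.energy, params=params)
    else:
        calc_org, calc_em = calculators
    course_org = _course(calc_org, org.weights, shift_set, voxel_flat, dv)
    course_em = _course(calc_em, em.weights, shift_set, voxel_flat, dv)
    return course_org, course_em
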