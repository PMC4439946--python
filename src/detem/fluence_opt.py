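"""Nonnegative fluence-weight optimization against plan objectives.

The plan objectives mirror a 60 Gy / 30 fraction prescription: PTV dose
between 58 and 60 Gy, ring (normal-tissue shell) maximum 60 Gy, and a
dose-volume constraint that at most 3% of the ring may exceed 54 Gy.  The
objective is a sum of structure-weighted one-sided quadratic penalties; the
DVH constraint uses iterative worst-voxel selection (the hottest 3% of the
ring are exempt, remaining voxels above 54 Gy are penalized toward 54 Gy).
Weights are found by a monotone projected-gradient iterative least-squares
scheme with backtracking, so the objective is nonincreasing over iterations
and every iterate is nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from ._engine import DoseCalculator, EngineParams
from .det_planning import SpotPlan
from .grids import DensityVolume, DoseGrid, StructureSet
from .phantom import MaterialMap

__all__ = [
    "PlanObjectives",
    "InfluenceMatrix",
    "TreatmentPlan",
    "build_influence",
    "optimize_weights",
    "plan_dose",
]

TAG_PTV, TAG_RING, TAG_BODY = 0, 1, 2


@dataclass(frozen=True)
class PlanObjectives:
    """Dose objectives (Gy) and penalty weights."""

    ptv_min: float = 58.0
    ptv_max: float = 60.0
    ring_max: float = 60.0
    ring_dvh_dose: float = 54.0
    ring_dvh_frac: float = 0.03
    # target coverage dominates: the PTV-minimum penalty must outweigh the
    # ring penalties by ~100x for the optimizer to actually reach the 58 Gy
    # floor against the penumbra cost in the adjacent ring
    w_ptv_min: float = 1000.0
    w_ptv_max: float = 10.0
    w_ring_max: float = 10.0
    w_ring_dvh: float = 10.0

    def __post_init__(self) -> None:
        if self.ptv_min > self.ptv_max:
            raise ValueError("ptv_min must not exceed ptv_max")
        if not 0.0 < self.ring_dvh_frac <= 1.0:
            raise ValueError("ring DVH volume fraction must be in (0, 1]")


@dataclass
class InfluenceMatrix:
    """Sampled-voxel x spot dose matrix with structure tags per row."""

    A: sparse.csr_matrix
    voxel_flat: np.ndarray     # flat grid indices of sampled voxels
    tags: np.ndarray           # int8: 0 = PTV, 1 = ring, 2 = body
    threshold: float
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.A.min() < 0:
            raise ValueError("influence entries must be nonnegative")
        row_max = np.asarray(self.A[self.tags == TAG_PTV].max(axis=1).todense()).ravel()
        if np.any(row_max <= 0):
            warnings.warn(
                f"{int(np.sum(row_max <= 0))} sampled PTV voxels receive no dose "
                "from any spot", stacklevel=2)


@dataclass
class TreatmentPlan:
    """A spot plan bound to an energy column (E0 = ORG, E1 = EM) and weights."""

    spot_plan: SpotPlan
    energy: str = "E0"
    weights: np.ndarray | None = None

    @property
    def label(self) -> str:
        return "ORG" if self.energy == "E0" else "EM"


def build_influence(dv: DensityVolume, mm: MaterialMap, plan: SpotPlan,
                    structures: StructureSet, sample_fraction: float = 0.1,
                    threshold: float = 0.005, energy: str = "E0",
                    seed: int = 0, params: EngineParams | None = None,
                    calculator: DoseCalculator | None = None) -> InfluenceMatrix:
    """Influence matrix over all PTV and ring voxels plus a random body sample.

    ``sample_fraction`` applies only to body voxels outside PTV and ring.
    """
    if len(plan) == 0:
        raise ValueError("spot plan is empty")
    ptv = structures["PTV"]
    ring = structures["ring"]
    body = structures["body"] & ~ptv & ~ring
    ptv_flat = np.flatnonzero(ptv.ravel())
    ring_flat = np.flatnonzero(ring.ravel())
    body_flat = np.flatnonzero(body.ravel())
    if 0 < sample_fraction < 1:
        rng = np.random.default_rng(seed)
        n_keep = int(round(sample_fraction * body_flat.size))
        body_flat = np.sort(rng.choice(body_flat, size=n_keep, replace=False))
    voxel_flat = np.concatenate([ptv_flat, ring_flat, body_flat])
    tags = np.concatenate([
        np.full(ptv_flat.size, TAG_PTV, dtype=np.int8),
        np.full(ring_flat.size, TAG_RING, dtype=np.int8),
        np.full(body_flat.size, TAG_BODY, dtype=np.int8),
    ])
    calc = calculator or DoseCalculator(dv, mm, plan.spots, energy_column=energy,
                                        params=params)
    A = calc.influence(voxel_flat, threshold=threshold)
    return InfluenceMatrix(A=A, voxel_flat=voxel_flat, tags=tags,
                           threshold=threshold, grid_shape=dv.shape)


@dataclass
class OptimizationResult:
    weights: np.ndarray
    objective: list[float]
    n_iter: int
    converged: bool


def _objective(dose, tags, obj: PlanObjectives):
    """One-sided quadratic penalty value and per-voxel residual weights."""
    r = np.zeros_like(dose)
    f = 0.0
    ptv = tags == TAG_PTV
    ring = tags == TAG_RING
    under = np.clip(obj.ptv_min - dose[ptv], 0.0, None)
    over = np.clip(dose[ptv] - obj.ptv_max, 0.0, None)
    f += obj.w_ptv_min * float(under @ under) + obj.w_ptv_max * float(over @ over)
    r[ptv] = -2.0 * obj.w_ptv_min * under + 2.0 * obj.w_ptv_max * over

    ring_dose = dose[ring]
    rover = np.clip(ring_dose - obj.ring_max, 0.0, None)
    f += obj.w_ring_max * float(rover @ rover)
    r_ring = 2.0 * obj.w_ring_max * rover

    # DVH term: exempt the hottest 3% of the ring, penalize the rest above 54
    k_allow = int(np.floor(obj.ring_dvh_frac * ring_dose.size))
    hot = np.flatnonzero(ring_dose > obj.ring_dvh_dose)
    if hot.size > k_allow:
        if k_allow > 0:
            part = np.argpartition(ring_dose[hot], hot.size - k_allow)
            penalized = hot[part[: hot.size - k_allow]]
        else:
            penalized = hot
        excess = ring_dose[penalized] - obj.ring_dvh_dose
        f += obj.w_ring_dvh * float(excess @ excess)
        r_ring[penalized] += 2.0 * obj.w_ring_dvh * excess
    r[ring] = r_ring
    return f, r


def _dvh_selection(ring_dose: np.ndarray, obj: PlanObjectives) -> np.ndarray:
    """Worst-voxel selection: indices of ring voxels penalized toward the DVH
    dose (all above it except the allowed hottest fraction)."""
    k_allow = int(np.floor(obj.ring_dvh_frac * ring_dose.size))
    hot = np.flatnonzero(ring_dose > obj.ring_dvh_dose)
    if hot.size <= k_allow:
        return np.empty(0, dtype=np.int64)
    if k_allow == 0:
        return hot
    part = np.argpartition(ring_dose[hot], hot.size - k_allow)
    return hot[part[: hot.size - k_allow]]


def optimize_weights(influence: InfluenceMatrix, obj: PlanObjectives | None = None,
                     iters: int = 200, tol: float = 1e-6,
                     w0: np.ndarray | None = None,
                     stage_iters: int = 25) -> OptimizationResult:
    """Iterative linear least-squares weight optimization.

    Runs stages of bound-constrained quasi-Newton (L-BFGS-B, weights >= 0)
    on the quadratic one-sided penalties with the DVH worst-voxel selection
    frozen per stage and refreshed between stages; because the selection
    itself minimizes the DVH term, the logged stage objectives are
    nonincreasing.  ``iters`` bounds the total inner iterations.
    """
    from scipy.optimize import minimize

    obj = obj or PlanObjectives()
    if influence.A.nnz == 0 or influence.A.max() == 0:
        raise ValueError("influence matrix is all zero")
    # body voxels carry no objective term; drop their rows for the solve
    keep = influence.tags <= TAG_RING
    A = influence.A[keep].tocsr()
    tags = influence.tags[keep]
    ptv = tags == TAG_PTV
    ring = tags == TAG_RING
    n_spots = A.shape[1]

    if w0 is None:
        mean_dose = float(A[ptv].sum()) / max(int(ptv.sum()), 1)
        target = 0.5 * (obj.ptv_min + obj.ptv_max)
        w = np.full(n_spots, target / max(mean_dose, 1e-12))
    else:
        w = np.clip(np.asarray(w0, dtype=float), 0.0, None)

    def full_objective(dose):
        f, _ = _objective(dose, tags, obj)
        return f

    def frozen_fun(wv, dvh_set):
        dose = A @ wv
        r = np.zeros_like(dose)
        under = np.clip(obj.ptv_min - dose[ptv], 0.0, None)
        over = np.clip(dose[ptv] - obj.ptv_max, 0.0, None)
        f = obj.w_ptv_min * float(under @ under) + obj.w_ptv_max * float(over @ over)
        r[ptv] = -2.0 * obj.w_ptv_min * under + 2.0 * obj.w_ptv_max * over
        rover = np.clip(dose[ring] - obj.ring_max, 0.0, None)
        f += obj.w_ring_max * float(rover @ rover)
        r_ring = 2.0 * obj.w_ring_max * rover
        if dvh_set.size:
            excess = np.clip(dose[ring][dvh_set] - obj.ring_dvh_dose, 0.0, None)
            f += obj.w_ring_dvh * float(excess @ excess)
            r_ring[dvh_set] += 2.0 * obj.w_ring_dvh * excess
        r[ring] = r_ring
        return f, A.T @ r

    trace = [full_objective(A @ w)]
    total_inner = 0
    converged = False
    bounds = [(0.0, None)] * n_spots
    while total_inner < iters:
        dvh_set = _dvh_selection((A @ w)[ring], obj)
        budget = min(stage_iters, iters - total_inner)
        res = minimize(frozen_fun, w, args=(dvh_set,), jac=True,
                       method="L-BFGS-B", bounds=bounds,
                       options=dict(maxiter=budget, ftol=1e-14, gtol=1e-12))
        w = np.clip(res.x, 0.0, None)
        total_inner += max(res.nit, 1)
        f_now = full_objective(A @ w)
        prev = trace[-1]
        trace.append(f_now)
        if prev - f_now < tol * max(prev, 1e-30):
            converged = True
            break
    return OptimizationResult(weights=w, objective=trace, n_iter=total_inner,
                              converged=converged)


def plan_dose(dv: DensityVolume, mm: MaterialMap, plan: SpotPlan,
              weights: np.ndarray, energy: str = "E0",
              params: EngineParams | None = None,
              calculator: DoseCalculator | None = None) -> DoseGrid:
    """Full-grid planned dose: weighted superposition of unit-spot doses."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(plan),):
        raise ValueError(f"expected {len(plan)} weights, got {weights.shape}")
    calc = calculator or DoseCalculator(dv, mm, plan.spots, energy_column=energy,
                                        params=params)
    return calc.dose_grid(weights)
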