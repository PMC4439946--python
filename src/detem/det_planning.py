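"""Distal-edge-tracking spot placement and per-spot energy margins.

A DET plan places one spot per beam's-eye-view (BEV) lattice ray that
intersects the PTV; the spot's nominal energy ``E0`` is the smallest
deliverable energy whose water-equivalent range reaches the distal PTV
surface along that ray.  The energy-margin (EM) step then raises each spot
to ``E1``: the maximum nominal energy over all spots within a BEV
neighborhood of half-width ``d`` (the maximum setup shift projected onto the
BEV plane), so that the spot still reaches its target point when the patient
is rigidly shifted by up to ``d`` laterally.  Shift components parallel to
the beam axis do not change a pencil beam's range and play no role here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import DensityVolume
from .phantom import MaterialMap
from .proton_dose import RangeEnergyModel, beam_frame, wepl_trace

__all__ = [
    "BeamArrangement",
    "SpotPlan",
    "make_arrangement",
    "place_det_spots",
    "plan_spots",
    "apply_energy_margin",
    "plan_info",
]

ARRANGEMENT_KINDS = ("full_arc", "half_arc", "two_fan")


@dataclass(frozen=True)
class BeamArrangement:
    """A set of static gantry angles (degrees)."""

    angles: tuple[float, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.angles)) != len(self.angles):
            raise ValueError("beam angles must be unique")


def make_arrangement(kind: str, start_angle: float = 0.0) -> BeamArrangement:
    """Standard arrangements: 24 beams over 360 deg (full arc), 12 over
    180 deg (half arc), or 12 over two opposing 90 deg fans."""
    if kind == "full_arc":
        angles = start_angle + 15.0 * np.arange(24)
    elif kind == "half_arc":
        angles = start_angle + 15.0 * np.arange(12)
    elif kind == "two_fan":
        first = start_angle + 15.0 * np.arange(6)
        angles = np.concatenate([first, first + 180.0])
    else:
        raise ValueError(f"unknown arrangement kind {kind!r}")
    return BeamArrangement(angles=tuple(float(a) % 360.0 for a in angles), label=kind)


@dataclass
class SpotPlan:
    """Per-beam spot table plus planning metadata.

    ``spots`` columns: ``beam`` (index into the arrangement), ``angle``
    (degrees), ``u``/``v`` (BEV lattice position, mm), ``E0`` and ``E1``
    (MeV, integers after 1 MeV quantization) and ``weight``.
    """

    spots: pd.DataFrame
    spacing: float = 3.0
    d: float | None = None
    arrangement: str = "custom"
    neighborhood: str = "box"
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spots)

    def check(self) -> None:
        s = self.spots
        if len(s) == 0:
            raise ValueError("spot plan is empty")
        if np.any(s["E0"] <= 0) or ("E1" in s and np.any(s["E1"] <= 0)):
            raise ValueError("spot energies must be positive")
        if "E1" in s and np.any(s["E1"] < s["E0"]):
            raise ValueError("margined energy E1 must be >= E0")

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        header = dict(spacing=self.spacing, d=self.d, arrangement=self.arrangement,
                      neighborhood=self.neighborhood, **self.meta)
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
            self.spots.to_csv(fh, index=False, lineterminator="\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "SpotPlan":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# "):
                raise ValueError(f"{path} is missing the JSON header line")
            header = json.loads(first[2:])
            spots = pd.read_csv(fh)
        spacing = header.pop("spacing", 3.0)
        d = header.pop("d", None)
        arrangement = header.pop("arrangement", "custom")
        neighborhood = header.pop("neighborhood", "box")
        return cls(spots=spots, spacing=spacing, d=d, arrangement=arrangement,
                   neighborhood=neighborhood, meta=header)


def place_det_spots(dv: DensityVolume, mm: MaterialMap, ptv: np.ndarray,
                    angle: float, spacing: float = 3.0,
                    model: RangeEnergyModel | None = None,
                    isocenter=(0.0, 0.0, 0.0)) -> pd.DataFrame:
    """DET spots for one gantry angle.

    Lays a BEV lattice of the given pitch over the PTV footprint; each ray
    that traverses at least one PTV voxel yields one spot whose ``E0`` is the
    energy of range equal to the WEPL from phantom entry to the ray's distal
    PTV exit, quantized *up* to the next whole MeV so quantization never
    causes undershoot.
    """
    model = model or RangeEnergyModel()
    if spacing <= 0:
        raise ValueError("spot spacing must be positive")
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise ValueError("PTV mask is empty")
    iso = np.asarray(isocenter, dtype=float)
    e_hat, u_hat, v_hat = beam_frame(angle)

    centers = dv.voxel_centers(np.flatnonzero(ptv.ravel())) - iso[None, :]
    u_pts = centers @ u_hat
    v_pts = centers @ v_hat
    pad = 0.5 * float(max(dv.spacing))
    ulat = spacing * np.arange(math.floor((u_pts.min() - pad) / spacing),
                               math.ceil((u_pts.max() + pad) / spacing) + 1)
    vlat = spacing * np.arange(math.floor((v_pts.min() - pad) / spacing),
                               math.ceil((v_pts.max() + pad) / spacing) + 1)

    half_diag = 0.5 * float(np.linalg.norm(np.asarray(dv.shape) * np.asarray(dv.spacing)))
    t_back = half_diag + 2.0
    rows = []
    for su in ulat:
        for sv in vlat:
            origin = iso + su * u_hat + sv * v_hat - t_back * e_hat
            tr = wepl_trace(dv, mm, origin, e_hat)
            if tr.is_empty:
                continue
            inside = ptv[tr.indices[:, 0], tr.indices[:, 1], tr.indices[:, 2]]
            if not inside.any():
                continue
            distal = int(np.flatnonzero(inside)[-1])
            wepl = float(tr.wepl[distal + 1])
            e0 = int(math.ceil(float(model.energy_mev(max(wepl, 1e-6)))))
            rows.append((float(angle), float(su), float(sv), e0))
    if not rows:
        raise ValueError(f"no lattice ray at angle {angle} intersects the PTV")
    df = pd.DataFrame(rows, columns=["angle", "u", "v", "E0"])
    df["E0"] = df["E0"].astype(int)
    return df


def plan_spots(dv: DensityVolume, mm: MaterialMap, ptv: np.ndarray,
               arrangement: BeamArrangement, spacing: float = 3.0,
               model: RangeEnergyModel | None = None,
               isocenter=(0.0, 0.0, 0.0)) -> SpotPlan:
    """DET spots for every beam of an arrangement (E1 initialized to E0)."""
    frames = []
    for b, angle in enumerate(arrangement.angles):
        df = place_det_spots(dv, mm, ptv, angle, spacing=spacing, model=model,
                             isocenter=isocenter)
        df.insert(0, "beam", b)
        frames.append(df)
    spots = pd.concat(frames, ignore_index=True)
    spots["E1"] = spots["E0"]
    spots["weight"] = 0.0
    return SpotPlan(spots=spots, spacing=spacing, d=None,
                    arrangement=arrangement.label)


def _margin_1beam(u, v, e0, d: float, neighborhood: str) -> np.ndarray:
    du = np.abs(u[:, None] - u[None, :])
    dv_ = np.abs(v[:, None] - v[None, :])
    eps = 1e-9
    if neighborhood == "box":
        near = (du <= d + eps) & (dv_ <= d + eps)
    elif neighborhood == "disc":
        near = du**2 + dv_**2 <= d**2 + eps
    else:
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    return np.where(near, e0[None, :], 0).max(axis=1)


def apply_energy_margin(plan: SpotPlan, d: float = 6.0,
                        neighborhood: str = "box") -> SpotPlan:
    """Assign the margined energy E1 to every spot.

    ``E1(x0) = max E0(x)`` over existing spots with ``|x_k - x0_k| <= d`` on
    each BEV axis (axis-aligned box; a disc of radius ``d`` is available as
    the physically motivated alternative).  ``d = 0`` is the identity, and
    E1 is monotone nondecreasing in ``d``.
    """
    if d < 0:
        raise ValueError("margin distance d must be nonnegative")
    spots = plan.spots.copy()
    e1 = np.empty(len(spots), dtype=int)
    for _, grp in spots.groupby("beam", sort=False):
        idx = grp.index.to_numpy()
        e1[idx] = _margin_1beam(
            grp["u"].to_numpy(float), grp["v"].to_numpy(float),
            grp["E0"].to_numpy(int), float(d), neighborhood)
    spots["E1"] = e1
    return SpotPlan(spots=spots, spacing=plan.spacing, d=float(d),
                    arrangement=plan.arrangement, neighborhood=neighborhood,
                    meta=dict(plan.meta))


def plan_info(plan: SpotPlan) -> dict:
    """Spot count and unweighted mean nominal/margined energies (MeV)."""
    s = plan.spots
    if len(s) == 0:
        raise ValueError("spot plan is empty")
    info = {
        "n_spots": int(len(s)),
        "n_beams": int(s["beam"].nunique()) if "beam" in s else 1,
        "mean_E0": float(s["E0"].mean()),
        "mean_E1": float(s["E1"].mean()) if "E1" in s else float(s["E0"].mean()),
    }
    info["mean_em"] = info["mean_E1"] - info["mean_E0"]
    return info
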