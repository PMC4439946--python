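"""Vectorized multi-spot dose calculator.

Shared by plan optimization (influence matrices), planned-dose computation
and per-fraction delivery under rigid setup shifts.  All spots of one beam
are parallel rays; the calculator precomputes, per beam, a lattice of
central-axis WEPL profiles (one exact Siddon trace per lattice node,
resampled on a uniform geometric-depth grid).  A rigid patient shift ``s``
is applied as a beam translation by ``-s``: a spot's effective BEV position
becomes ``(u - s.u_hat, v - s_z)`` and its axis WEPL profile is read from
the lattice by bilinear interpolation at that effective position.  With zero
shift, spots coincide with lattice nodes, so planned and delivered doses
follow the identical code path.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from . import _kernels
from .grids import DensityVolume, DoseGrid
from .phantom import MaterialMap
from .proton_dose import (
    DEFAULT_ENERGY_SPREAD,
    DEFAULT_MCS_FRACTION,
    DEFAULT_SIGMA_AIR,
    RangeEnergyModel,
    beam_frame,
    build_depth_dose_table,
    wepl_trace,
)

__all__ = ["EngineParams", "DoseCalculator"]


@dataclass(frozen=True)
class EngineParams:
    """Numerical and physical settings of the pencil-beam engine."""

    model: RangeEnergyModel = field(default_factory=RangeEnergyModel)
    sigma_air: float = DEFAULT_SIGMA_AIR
    energy_spread: float = DEFAULT_ENERGY_SPREAD
    mcs_fraction: float = DEFAULT_MCS_FRACTION
    dd_step: float = 0.5        # mm, depth-dose table resolution
    t_step: float = 1.0         # mm, axis-WEPL resampling step
    table_margin: float = 9.0   # mm, WEPL lattice margin beyond spot extent
    table_du: float = 3.0       # mm, WEPL lattice pitch; keep equal to the spot
                                # pitch so zero-shift spots sit on lattice nodes
    cutoff_sigma: float = 3.5   # lateral Gaussian truncation


class DoseCalculator:
    """Dose engine bound to one phantom and one spot list.

    ``spots`` is a DataFrame with columns ``angle``, ``u``, ``v`` and the
    chosen ``energy_column``; the row order defines the weight vector order.
    """

    def __init__(self, dv: DensityVolume, mm: MaterialMap, spots: pd.DataFrame,
                 energy_column: str = "E0", params: EngineParams | None = None,
                 isocenter=(0.0, 0.0, 0.0)) -> None:
        self.dv = dv
        self.mm = mm
        self.params = params or EngineParams()
        self.isocenter = np.asarray(isocenter, dtype=float)
        self.spots = spots.reset_index(drop=True)
        self.energy_column = energy_column
        self.n_spots = len(self.spots)
        if self.n_spots == 0:
            raise ValueError("spot list is empty")

        self._vox_cache: dict = {}
        self._energy_tables()
        self._build_beams()

    # -- precomputation ----------------------------------------------------

    def _energy_tables(self) -> None:
        p = self.params
        energies = np.asarray(self.spots[self.energy_column], dtype=float)
        if np.any(energies <= 0):
            raise ValueError("spot energies must be positive")
        self._unique_e = np.unique(energies)
        rows, wmaxs, norms, ranges = [], [], [], []
        for e in self._unique_e:
            table, wed_max = build_depth_dose_table(
                e, p.energy_spread * e, p.model, p.dd_step)
            R = float(p.model.range_mm(e))
            wpk = p.dd_step * int(np.argmax(table))
            frac = min(wpk / R, 1.0)
            sig2_pk = p.sigma_air**2 + (p.mcs_fraction * R) ** 2 * frac**3
            norms.append(2.0 * np.pi * sig2_pk / float(table.max()))
            rows.append(table)
            wmaxs.append(wed_max)
            ranges.append(R)
        L = max(r.size for r in rows)
        self._dd_table = np.zeros((len(rows), L), dtype=np.float32)
        for i, r in enumerate(rows):
            self._dd_table[i, : r.size] = r
        self._wed_max = np.asarray(wmaxs, dtype=np.float32)
        self._e_norm = np.asarray(norms, dtype=np.float64)
        self._e_range = np.asarray(ranges, dtype=np.float64)
        self._spot_row = np.searchsorted(self._unique_e, energies).astype(np.int32)
        self._spot_range = self._e_range[self._spot_row]
        self._spot_norm = self._e_norm[self._spot_row]
        self._spot_mcs2 = ((self.params.mcs_fraction * self._spot_range) ** 2)
        self._max_cut = float(
            self.params.cutoff_sigma
            * np.sqrt(self.params.sigma_air**2 + self._spot_mcs2.max())
        )

    def _build_beams(self) -> None:
        p = self.params
        dv = self.dv
        half_diag = 0.5 * float(np.linalg.norm(np.asarray(dv.shape) * np.asarray(dv.spacing)))
        tlim = half_diag + 2.0
        self._t0 = -tlim
        self._tgrid = np.arange(-tlim, tlim + p.t_step, p.t_step)
        self._nt = self._tgrid.size

        spot_u = np.asarray(self.spots["u"], dtype=float)
        spot_v = np.asarray(self.spots["v"], dtype=float)
        angles = np.asarray(self.spots["angle"], dtype=float)

        du = float(p.table_du)
        self._table_du = du

        self._beams = []
        for angle in pd.unique(angles):
            sel = np.flatnonzero(angles == angle)
            e_hat, u_hat, v_hat = beam_frame(float(angle))
            su, sv = spot_u[sel], spot_v[sel]
            tu = np.arange(su.min() - p.table_margin, su.max() + p.table_margin + du, du)
            tv = np.arange(sv.min() - p.table_margin, sv.max() + p.table_margin + du, du)
            wtab = np.zeros((tu.size, tv.size, self._nt), dtype=np.float32)
            for i, ui in enumerate(tu):
                for j, vj in enumerate(tv):
                    o = self.isocenter + ui * u_hat + vj * v_hat + self._t0 * e_hat
                    tr = wepl_trace(self.dv, self.mm, o, e_hat)
                    if not tr.is_empty:
                        wtab[i, j] = np.interp(
                            self._tgrid - self._t0, tr.t, tr.wepl,
                            left=0.0, right=tr.wepl[-1],
                        )
            self._beams.append(
                dict(angle=float(angle), sel=sel, e_hat=e_hat, u_hat=u_hat,
                     v_hat=v_hat, su=su, sv=sv, tu0=float(tu[0]), tv0=float(tv[0]),
                     ntu=tu.size, ntv=tv.size, wtab=wtab)
            )

    # -- voxel bucketing ---------------------------------------------------

    def _voxels_for(self, beam: dict, voxel_flat: np.ndarray | None):
        if voxel_flat is None:
            key = ("full", beam["angle"])
            n_total = int(np.prod(self.dv.shape))
            flat = None
        else:
            key = (hashlib.sha1(voxel_flat.tobytes()).hexdigest(), beam["angle"])
            flat = voxel_flat
        if key in self._vox_cache:
            return self._vox_cache[key]
        if flat is None:
            flat = np.arange(int(np.prod(self.dv.shape)), dtype=np.int64)
        centers = self.dv.voxel_centers(flat) - self.isocenter[None, :]
        u = (centers @ beam["u_hat"]).astype(np.float32)
        v = (centers @ beam["v_hat"]).astype(np.float32)
        t = (centers @ beam["e_hat"]).astype(np.float32)

        binw = self._max_cut + 1e-3
        u0 = float(u.min())
        v0 = float(v.min())
        nbu = int(np.floor((float(u.max()) - u0) / binw)) + 1
        nbv = int(np.floor((float(v.max()) - v0) / binw)) + 1
        iu = np.minimum(((u - u0) / binw).astype(np.int64), nbu - 1)
        iv = np.minimum(((v - v0) / binw).astype(np.int64), nbv - 1)
        b = iu * nbv + iv
        order = np.argsort(b, kind="stable").astype(np.int64)
        counts = np.bincount(b, minlength=nbu * nbv)
        start = np.zeros(nbu * nbv + 1, dtype=np.int64)
        np.cumsum(counts, out=start[1:])
        entry = dict(u=u, v=v, t=t, bucket_start=start, bucket_idx=order,
                     u0=u0, v0=v0, binw=binw, nbu=nbu, nbv=nbv)
        self._vox_cache[key] = entry
        return entry

    # -- per-beam spot axis WEPL -------------------------------------------

    def _axis_wepl(self, beam: dict, shift: np.ndarray):
        """Bilinear read of the beam's WEPL lattice at the effective spot
        positions; exact at lattice nodes (zero shift)."""
        du = self._table_du
        su_eff = beam["su"] - float(shift @ beam["u_hat"])
        sv_eff = beam["sv"] - float(shift @ beam["v_hat"])
        fu = np.clip((su_eff - beam["tu0"]) / du, 0.0, beam["ntu"] - 1 - 1e-9)
        fv = np.clip((sv_eff - beam["tv0"]) / du, 0.0, beam["ntv"] - 1 - 1e-9)
        iu = fu.astype(np.intp)
        iv = fv.astype(np.intp)
        au = (fu - iu)[:, None].astype(np.float32)
        av = (fv - iv)[:, None].astype(np.float32)
        w = beam["wtab"]
        wepl = ((1 - au) * (1 - av) * w[iu, iv]
                + au * (1 - av) * w[iu + 1, iv]
                + (1 - au) * av * w[iu, iv + 1]
                + au * av * w[iu + 1, iv + 1])
        return su_eff.astype(np.float32), sv_eff.astype(np.float32), wepl

    # -- public computations ------------------------------------------------

    def dose_flat(self, weights: np.ndarray, shift=(0.0, 0.0, 0.0),
                  voxel_flat: np.ndarray | None = None) -> np.ndarray:
        """Dose (Gy) at the given flat voxel indices (all voxels if None)."""
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.n_spots,):
            raise ValueError(
                f"expected {self.n_spots} weights, got shape {weights.shape}")
        shift = np.asarray(shift, dtype=float)
        n_out = int(np.prod(self.dv.shape)) if voxel_flat is None else voxel_flat.size
        out = np.zeros(n_out, dtype=np.float64)
        p = self.params
        for beam in self._beams:
            vox = self._voxels_for(beam, voxel_flat)
            su_eff, sv_eff, wepl = self._axis_wepl(beam, shift)
            sel = beam["sel"]
            _kernels.accumulate_spots(
                vox["u"], vox["v"], vox["t"],
                vox["bucket_start"], vox["bucket_idx"],
                vox["u0"], vox["v0"], vox["binw"], vox["nbu"], vox["nbv"],
                su_eff, sv_eff, wepl,
                np.float32(self._t0), np.float32(p.t_step),
                self._dd_table, np.float32(p.dd_step), self._wed_max,
                self._spot_row[sel], self._spot_range[sel],
                self._spot_norm[sel], weights[sel],
                p.sigma_air**2, self._spot_mcs2[sel],
                p.cutoff_sigma**2, out,
            )
        return out

    def dose_grid(self, weights: np.ndarray, shift=(0.0, 0.0, 0.0)) -> DoseGrid:
        data = self.dose_flat(weights, shift=shift).reshape(self.dv.shape)
        return DoseGrid(data=data, spacing=self.dv.spacing, origin=self.dv.origin)

    def influence(self, voxel_flat: np.ndarray, threshold: float = 0.0) -> sparse.csr_matrix:
        """Sparse (n_voxel x n_spot) dose-per-unit-weight matrix.

        Entries below ``threshold`` times the spot's maximum sampled dose are
        dropped for sparsity.
        """
        voxel_flat = np.asarray(voxel_flat, dtype=np.int64)
        p = self.params
        scratch = np.zeros(voxel_flat.size, dtype=np.float64)
        cols_idx: list[np.ndarray] = []
        cols_val: list[np.ndarray] = []
        one = np.ones(1, dtype=float)
        for beam in self._beams:
            vox = self._voxels_for(beam, voxel_flat)
            su_eff, sv_eff, wepl = self._axis_wepl(beam, np.zeros(3))
            sel = beam["sel"]
            for k in range(sel.size):
                s = slice(k, k + 1)
                _kernels.accumulate_spots(
                    vox["u"], vox["v"], vox["t"],
                    vox["bucket_start"], vox["bucket_idx"],
                    vox["u0"], vox["v0"], vox["binw"], vox["nbu"], vox["nbv"],
                    su_eff[s], sv_eff[s], wepl[s],
                    np.float32(self._t0), np.float32(p.t_step),
                    self._dd_table, np.float32(p.dd_step), self._wed_max,
                    self._spot_row[sel][s], self._spot_range[sel][s],
                    self._spot_norm[sel][s], one,
                    p.sigma_air**2, self._spot_mcs2[sel][s],
                    p.cutoff_sigma**2, scratch,
                )
                nz = np.flatnonzero(scratch)
                vals = scratch[nz]
                if threshold > 0 and vals.size:
                    keep = vals >= threshold * vals.max()
                    nz, vals = nz[keep], vals[keep]
                cols_idx.append(nz.astype(np.int32))
                cols_val.append(vals.astype(np.float32))
                scratch[np.flatnonzero(scratch)] = 0.0
        # columns were produced beam by beam; restore global spot order
        order = np.concatenate([b["sel"] for b in self._beams])
        reordered_idx = [None] * self.n_spots
        reordered_val = [None] * self.n_spots
        for pos, g in enumerate(order):
            reordered_idx[g] = cols_idx[pos]
            reordered_val[g] = cols_val[pos]
        indptr = np.zeros(self.n_spots + 1, dtype=np.int64)
        indptr[1:] = np.cumsum([c.size for c in reordered_idx])
        indices = (np.concatenate(reordered_idx) if indptr[-1] else
                   np.empty(0, dtype=np.int32))
        data = (np.concatenate(reordered_val) if indptr[-1] else
                np.empty(0, dtype=np.float32))
        A = sparse.csc_matrix((data, indices, indptr),
                              shape=(voxel_flat.size, self.n_spots))
        return A.tocsr()
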