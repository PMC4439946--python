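"""Normalized total dose (NTD), DVHs, and dose-volume-variation reporting.

NTD converts a fractionated course into its 2 Gy-per-fraction equivalent via
the linear-quadratic model:

    NTD = sum_i  d_i * (alpha/beta + d_i) / (alpha/beta + d_ref)

with d_ref = 2 Gy, alpha/beta = 10 Gy for tumor (CTV) and 1.5 Gy for normal
tissue (ring).  If every fraction delivers exactly d_ref the NTD equals the
physical dose; hypofractionated voxels are penalized more strongly at low
alpha/beta.  Dose-volume variation is reported as
``(delivered - planned) / prescription * 100`` at standard DVH points, so
target underdose is negative; a plan is considered acceptably robust when no
CTV volume point falls below -3% of the prescription.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import DoseGrid
from .uncertainty_sim import FractionDoseSet

__all__ = [
    "NTDGrid",
    "DVHCurve",
    "VariationReport",
    "ntd_accumulate",
    "ntd_uniform_course",
    "compute_dvh",
    "dvh_metric",
    "variation_report",
    "plot_dvh",
    "plot_variation",
]

DEFAULT_DREF = 2.0
ALPHA_BETA_CTV = 10.0
ALPHA_BETA_RING = 1.5
DEFAULT_METRICS = {"CTV": (98, 95, 50, 2), "ring": (2, 20, 50)}


@dataclass
class NTDGrid:
    """Accumulated NTD (Gy) per evaluation voxel."""

    values: np.ndarray
    alpha_beta: float
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    voxel_flat: np.ndarray | None = None
    dref: float = DEFAULT_DREF
    n_fractions: int = 30

    def values_in(self, mask: np.ndarray) -> np.ndarray:
        want = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
        if self.voxel_flat is None:
            return self.values.ravel()[want]
        pos = np.searchsorted(self.voxel_flat, want)
        if np.any(pos >= self.voxel_flat.size) or np.any(self.voxel_flat[pos] != want):
            raise ValueError("mask is not contained in the evaluated voxel set")
        return self.values[pos]


def ntd_accumulate(fractions: FractionDoseSet, alpha_beta: float,
                   dref: float = DEFAULT_DREF) -> NTDGrid:
    """Accumulate per-fraction doses into NTD, voxel by voxel."""
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be positive")
    d = fractions.values.astype(np.float64)
    if np.any(d < 0):
        raise ValueError("fraction doses must be nonnegative")
    ntd = np.sum(d * (alpha_beta + d) / (alpha_beta + dref), axis=0)
    return NTDGrid(values=ntd, alpha_beta=alpha_beta,
                   grid_shape=fractions.grid_shape, spacing=fractions.spacing,
                   origin=fractions.origin, voxel_flat=fractions.voxel_flat,
                   dref=dref, n_fractions=fractions.n_fractions)


def ntd_uniform_course(total_dose, n_fractions: int, alpha_beta: float,
                       dref: float = DEFAULT_DREF):
    """Closed-form NTD of a total dose split into equal fractions."""
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be positive")
    total_dose = np.asarray(total_dose, dtype=np.float64)
    per = total_dose / n_fractions
    return total_dose * (alpha_beta + per) / (alpha_beta + dref)


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose: np.ndarray        # bin edges, Gy
    volume_pct: np.ndarray  # % of structure volume receiving >= dose
    structure: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_Gy": self.dose, "volume_pct": self.volume_pct})


def _extract_values(dose, mask) -> np.ndarray:
    if isinstance(dose, DoseGrid):
        return dose.data[np.asarray(mask, dtype=bool)]
    if isinstance(dose, NTDGrid):
        return dose.values_in(mask)
    dose = np.asarray(dose)
    return dose[np.asarray(mask, dtype=bool)]


def compute_dvh(dose, mask, bin_width: float = 0.1, structure: str = "") -> DVHCurve:
    """Cumulative DVH: percentage of the masked volume with dose >= D."""
    vals = _extract_values(dose, mask)
    if vals.size == 0:
        raise ValueError("structure mask is empty")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    top = float(vals.max()) + 2 * bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=np.append(edges, np.inf))
    above = counts[::-1].cumsum()[::-1]
    volume_pct = 100.0 * above / vals.size
    return DVHCurve(dose=edges, volume_pct=volume_pct, structure=structure)


def dvh_metric(curve: DVHCurve, volume_pct: float) -> float:
    """Dx%: the minimum dose received by the hottest x% of the structure.

    The dose level at which the cumulative volume falls below ``volume_pct``,
    linearly interpolated between DVH bins; plateau ties resolve to the larger
    dose, matching the sort-based definition of Dx.
    """
    if not 0.0 < volume_pct <= 100.0:
        raise ValueError("volume percentage must be in (0, 100]")
    v = curve.volume_pct
    d = curve.dose
    below = np.flatnonzero(v < volume_pct)
    if below.size == 0:
        return float(d[-1])
    i = int(below[0])
    if i == 0:
        return float(d[0])
    v0, v1 = v[i - 1], v[i]
    if v0 == v1:
        return float(d[i])
    f = (v0 - volume_pct) / (v0 - v1)
    return float(d[i - 1] + f * (d[i] - d[i - 1]))


@dataclass
class VariationReport:
    """Planned vs delivered DVH metrics and their variation (% of prescription)."""

    table: pd.DataFrame
    prescription: float

    def variation(self, structure: str, metric: int) -> float:
        row = self.table[(self.table.structure == structure)
                         & (self.table.metric == f"D{metric}")]
        if row.empty:
            raise KeyError(f"no entry for {structure} D{metric}")
        return float(row.variation_pct.iloc[0])

    def value(self, structure: str, metric: int, which: str) -> float:
        row = self.table[(self.table.structure == structure)
                         & (self.table.metric == f"D{metric}")]
        if row.empty:
            raise KeyError(f"no entry for {structure} D{metric}")
        return float(row[f"{which}_Gy"].iloc[0])

    def write(self, stem: str | Path) -> None:
        stem = Path(stem)
        self.table.to_csv(stem.with_suffix(".csv"), index=False)
        stem.with_suffix(".json").write_text(
            self.table.to_json(orient="records", indent=2) + "\n")


def variation_report(planned: DoseGrid, delivered: dict[str, NTDGrid],
                     structures, prescription: float = 60.0,
                     metrics: dict[str, tuple[int, ...]] | None = None,
                     bin_width: float = 0.1,
                     convert_planned: bool = True) -> VariationReport:
    """Planned-vs-delivered DVH variation per structure.

    ``delivered`` maps structure name -> NTD grid accumulated with that
    structure's alpha/beta.  The planned dose is converted to its own
    uniform-fractionation NTD on the same alpha/beta so that a delivery with
    zero shifts reports exactly zero variation.  Variation is
    ``(delivered - planned) / prescription * 100`` (underdose negative).
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    metrics = metrics or DEFAULT_METRICS
    rows = []
    for name, ntd in delivered.items():
        mask = structures[name] if not isinstance(structures, dict) else structures[name]
        if isinstance(planned, DoseGrid):
            if planned.data.shape != np.asarray(mask).shape:
                raise ValueError("planned grid and structure masks disagree in shape")
            planned_vals = planned.data[np.asarray(mask, dtype=bool)]
        else:
            planned_vals = _extract_values(planned, mask)
        if convert_planned:
            planned_vals = ntd_uniform_course(planned_vals, ntd.n_fractions,
                                              ntd.alpha_beta, ntd.dref)
        delivered_vals = ntd.values_in(mask)
        curve_p = compute_dvh(planned_vals, np.ones(planned_vals.size, dtype=bool),
                              bin_width, structure=name)
        curve_d = compute_dvh(delivered_vals, np.ones(delivered_vals.size, dtype=bool),
                              bin_width, structure=name)
        for m in metrics.get(name, ()):
            dp = dvh_metric(curve_p, m)
            dd = dvh_metric(curve_d, m)
            rows.append(dict(structure=name, metric=f"D{m}", planned_Gy=dp,
                             delivered_Gy=dd,
                             variation_pct=(dd - dp) / prescription * 100.0))
    table = pd.DataFrame(rows)
    return VariationReport(table=table, prescription=prescription)


def plot_dvh(curves: dict[str, DVHCurve], path: str | Path,
             title: str = "") -> Path:
    """Overlay cumulative DVH curves (dashed = names containing 'planned')."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        style = "--" if "planned" in name.lower() else "-"
        ax.plot(curve.dose, curve.volume_pct, style, label=name)
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Volume (%)")
    ax.set_ylim(0, 102)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_variation(reports: dict[str, VariationReport], path: str | Path,
                   threshold_pct: float = 3.0) -> Path:
    """Bar chart of dose-volume variation per structure metric and plan."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    labels = None
    width = 0.8 / max(len(reports), 1)
    for k, (name, rep) in enumerate(reports.items()):
        tab = rep.table
        labels = [f"{s} {m}" for s, m in zip(tab.structure, tab.metric)]
        x = np.arange(len(tab)) + k * width
        ax.bar(x, tab.variation_pct, width=width, label=name)
    if labels is not None:
        ax.set_xticks(np.arange(len(labels)) + 0.4 - width / 2)
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
    for y in (threshold_pct, -threshold_pct):
        ax.axhline(y, color="gray", linestyle=":", linewidth=1)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel("Dose-volume variation (% of prescription)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
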