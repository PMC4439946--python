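"""End-to-end experiment orchestration.

Stages: phantom -> DET planning (nominal E0 and margined E1 energies) ->
fluence optimization of the ORG and EM plans against the same objectives ->
shared-shift fractionated course simulation -> NTD/DVH evaluation.  Every
stage can run standalone on the serialized artifacts of the previous stage,
and a full run under a fixed seed is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from ._engine import DoseCalculator
from .config import ExperimentConfig
from .det_planning import SpotPlan, apply_energy_margin, make_arrangement, plan_info, plan_spots
from .fluence_opt import TreatmentPlan, build_influence, optimize_weights
from .grids import StructureSet, read_density, read_mask, write_mhd
from .phantom import assign_materials, make_phantom
from .plan_eval import (ALPHA_BETA_CTV, ALPHA_BETA_RING, compute_dvh,
                        ntd_accumulate, ntd_uniform_course, plot_dvh,
                        plot_variation, variation_report)
from .uncertainty_sim import ShiftSet, sample_shifts, simulate_course

__all__ = ["PipelineError", "run_pipeline", "stage_phantom", "stage_plan",
           "stage_optimize", "stage_simulate", "stage_evaluate"]

log = logging.getLogger("detem")

STRUCTURES = ("CTV", "PTV", "ring", "body")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise PipelineError(stage, f"missing expected artifact {path}")
    return path


def _load_phantom(stage: str, out: Path):
    dv = read_density(_require(stage, out / "density.mhd"))
    masks = {}
    for name in STRUCTURES:
        mask, _, _ = read_mask(_require(stage, out / f"mask_{name}.mhd"))
        masks[name] = mask
    structures = StructureSet(masks=masks, spacing=dv.spacing, origin=dv.origin)
    return dv, assign_materials(dv), structures


def stage_phantom(cfg: ExperimentConfig, out: Path) -> None:
    t0 = time.time()
    try:
        dv, structures = make_phantom(cfg.phantom)
    except ValueError as err:
        raise PipelineError("phantom", str(err)) from err
    write_mhd(out / "density.mhd", dv, dtype=np.float32)
    for name in STRUCTURES:
        write_mhd(out / f"mask_{name}.mhd", structures[name],
                  spacing=dv.spacing, origin=dv.origin, dtype=np.uint8)
    log.info("phantom: grid %s, CTV %.1f cc, ring %.1f cc (%.1f s)",
             dv.shape, structures.volume_cc("CTV"), structures.volume_cc("ring"),
             time.time() - t0)


def stage_plan(cfg: ExperimentConfig, out: Path) -> SpotPlan:
    t0 = time.time()
    dv, mm, structures = _load_phantom("plan", out)
    arrangement = make_arrangement(cfg.planning.arrangement, cfg.planning.start_angle)
    plan = plan_spots(dv, mm, structures["PTV"], arrangement,
                      spacing=cfg.planning.spot_spacing,
                      model=cfg.engine_params().model)
    plan = apply_energy_margin(plan, d=cfg.planning.d,
                               neighborhood=cfg.planning.neighborhood)
    plan.meta["config"] = cfg.digest
    plan.write(out / "spots.csv")
    info = plan_info(plan)
    log.info("plan: %d spots over %d beams, mean E0 %.2f MeV, mean E1 %.2f MeV "
             "(%.1f s)", info["n_spots"], info["n_beams"], info["mean_E0"],
             info["mean_E1"], time.time() - t0)
    return plan


def stage_optimize(cfg: ExperimentConfig, out: Path) -> dict[str, TreatmentPlan]:
    t0 = time.time()
    dv, mm, structures = _load_phantom("optimize", out)
    plan = SpotPlan.read(_require("optimize", out / "spots.csv"))
    plans = {}
    for label, energy in (("org", "E0"), ("em", "E1")):
        infl = build_influence(
            dv, mm, plan, structures,
            sample_fraction=cfg.optimizer.sample_fraction,
            threshold=cfg.optimizer.threshold, energy=energy,
            seed=cfg.optimizer.sample_seed, params=cfg.engine_params())
        res = optimize_weights(infl, cfg.objectives, iters=cfg.optimizer.iters,
                               tol=cfg.optimizer.tol)
        optimized = plan.spots.copy()
        optimized["weight"] = res.weights
        splan = SpotPlan(spots=optimized, spacing=plan.spacing, d=plan.d,
                         arrangement=plan.arrangement,
                         neighborhood=plan.neighborhood,
                         meta={**plan.meta, "energy": energy})
        splan.write(out / f"plan_{label}.csv")
        np.savetxt(out / f"convergence_{label}.csv",
                   np.column_stack([np.arange(len(res.objective)), res.objective]),
                   delimiter=",", header="iteration,objective", comments="")
        plans[label] = TreatmentPlan(spot_plan=splan, energy=energy,
                                     weights=res.weights)
        log.info("optimize[%s]: objective %.4g -> %.4g in %d iters",
                 label, res.objective[0], res.objective[-1], res.n_iter)
    log.info("optimize: done (%.1f s)", time.time() - t0)
    return plans


def _load_plans(stage: str, out: Path) -> dict[str, TreatmentPlan]:
    plans = {}
    for label, energy in (("org", "E0"), ("em", "E1")):
        splan = SpotPlan.read(_require(stage, out / f"plan_{label}.csv"))
        if "weight" not in splan.spots or not np.any(splan.spots["weight"] > 0):
            raise PipelineError(stage, f"plan_{label}.csv has no optimized weights")
        plans[label] = TreatmentPlan(spot_plan=splan, energy=energy,
                                     weights=splan.spots["weight"].to_numpy(float))
    return plans


def stage_simulate(cfg: ExperimentConfig, out: Path,
                   seed: int | None = None) -> None:
    t0 = time.time()
    dv, mm, structures = _load_phantom("simulate", out)
    plans = _load_plans("simulate", out)
    shift_set = sample_shifts(cfg.course.n_fractions, cfg.course.sigma,
                              cfg.course.cutoff,
                              seed=cfg.course.seed if seed is None else seed,
                              max_3d=cfg.course.max_3d)
    shift_set.write(out / "shifts.csv")
    eval_mask = structures["CTV"] | structures["ring"] | structures["PTV"]
    course_org, course_em = simulate_course(
        dv, mm, plans["org"], plans["em"], shift_set, eval_mask=eval_mask,
        params=cfg.engine_params())
    np.savetxt(out / "course_org.csv", course_org.values, delimiter=",")
    np.savetxt(out / "course_em.csv", course_em.values, delimiter=",")
    np.savetxt(out / "course_voxels.csv", course_org.voxel_flat, fmt="%d")
    log.info("simulate: %d fractions x 2 plans on %d voxels (%.1f s)",
             shift_set.n_fractions, course_org.values.shape[1], time.time() - t0)


def stage_evaluate(cfg: ExperimentConfig, out: Path) -> dict:
    from .uncertainty_sim import FractionDoseSet

    t0 = time.time()
    dv, mm, structures = _load_phantom("evaluate", out)
    plans = _load_plans("evaluate", out)
    voxel_flat = np.loadtxt(_require("evaluate", out / "course_voxels.csv"),
                            dtype=np.int64)
    summary: dict = {"config": cfg.digest, "plans": {}}
    reports: dict = {}
    for label in ("org", "em"):
        values = np.atleast_2d(np.loadtxt(
            _require("evaluate", out / f"course_{label}.csv"), delimiter=","))
        course = FractionDoseSet(values=values, grid_shape=dv.shape,
                                 spacing=dv.spacing, origin=dv.origin,
                                 voxel_flat=voxel_flat)
        calc = DoseCalculator(dv, mm, plans[label].spot_plan.spots,
                              energy_column=plans[label].energy,
                              params=cfg.engine_params())
        planned = calc.dose_grid(plans[label].weights)
        delivered = {
            "CTV": ntd_accumulate(course, ALPHA_BETA_CTV),
            "ring": ntd_accumulate(course, ALPHA_BETA_RING),
        }
        report = variation_report(planned, delivered, structures)
        report.write(out / f"variation_{label}")
        summary["plans"][label] = json.loads(
            report.table.to_json(orient="records"))
        curves = {}
        for name, ntd in delivered.items():
            mask = structures[name]
            planned_ntd = ntd_uniform_course(planned.data[mask],
                                             ntd.n_fractions, ntd.alpha_beta)
            ones = np.ones(planned_ntd.size, dtype=bool)
            curves[f"{name} planned"] = compute_dvh(planned_ntd, ones,
                                                    structure=name)
            curves[f"{name} delivered"] = compute_dvh(ntd.values_in(mask), ones,
                                                      structure=name)
        for cname, curve in curves.items():
            curve.to_frame().to_csv(
                out / f"dvh_{label}_{cname.replace(' ', '_')}.csv", index=False)
        plot_dvh(curves, out / f"dvh_{label}.png", title=label.upper())
        reports[label] = report
    plot_variation(reports, out / "variation.png")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("evaluate: reports written (%.1f s)", time.time() - t0)
    return summary


def run_pipeline(cfg: ExperimentConfig, out: str | Path,
                 seed: int | None = None) -> dict:
    """Run every stage in order; returns the evaluation summary."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    stage_phantom(cfg, out)
    stage_plan(cfg, out)
    stage_optimize(cfg, out)
    stage_simulate(cfg, out, seed=seed)
    return stage_evaluate(cfg, out)
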