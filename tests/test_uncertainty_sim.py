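import numpy as np
import pandas as pd
import pytest

from detem._engine import DoseCalculator, EngineParams
from detem.det_planning import BeamArrangement, SpotPlan, plan_spots
from detem.fluence_opt import TreatmentPlan
from detem.uncertainty_sim import (ShiftSet, deliver_fraction, sample_shifts,
                                   simulate_course)


class TestSampleShifts:
    def test_cutoff_never_exceeded(self):
        ss = sample_shifts(100_000, seed=123)
        assert np.max(np.abs(ss.shifts)) <= 4.0

    def test_truncated_sd(self):
        # closed-form SD of a +/-2 sigma truncated normal with sigma = 2 mm
        # is 1.759 mm; the 6 mm 3D-norm rejection barely moves it
        ss = sample_shifts(100_000, seed=123)
        sd = ss.shifts.std(axis=0)
        assert np.all(sd >= 1.70) and np.all(sd <= 2.0)
        assert np.allclose(sd, 1.759, atol=0.05)
        assert np.allclose(ss.shifts.mean(axis=0), 0.0, atol=0.05)

    def test_3d_norm_bound(self):
        ss = sample_shifts(50_000, seed=7)
        assert np.max(np.linalg.norm(ss.shifts, axis=1)) <= 6.0
        unbounded = sample_shifts(50_000, seed=7, max_3d=None)
        assert np.max(np.linalg.norm(unbounded.shifts, axis=1)) <= np.sqrt(3) * 4.0

    def test_deterministic_under_seed(self):
        a = sample_shifts(30, seed=99)
        b = sample_shifts(30, seed=99)
        assert np.array_equal(a.shifts, b.shifts)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sample_shifts(10, sigma=0.0)
        with pytest.raises(ValueError):
            sample_shifts(10, cutoff=-1.0)

    def test_csv_round_trip_and_determinism(self, tmp_path):
        ss = sample_shifts(30, seed=7)
        p1 = ss.write(tmp_path / "a.csv")
        p2 = sample_shifts(30, seed=7).write(tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()
        back = ShiftSet.read(p1)
        assert np.array_equal(back.shifts, ss.shifts)
        assert back.seed == 7


@pytest.fixture(scope="module")
def small_treatment(small_phantom):
    dv, mm, st = small_phantom
    arrangement = BeamArrangement(angles=(0.0, 90.0, 180.0, 270.0), label="custom")
    plan = plan_spots(dv, mm, st["PTV"], arrangement)
    rng = np.random.default_rng(0)
    weights = rng.uniform(0.5, 1.5, size=len(plan))
    org = TreatmentPlan(spot_plan=plan, energy="E0", weights=weights)
    em = TreatmentPlan(spot_plan=plan, energy="E1", weights=weights)
    calc_org = DoseCalculator(dv, mm, plan.spots, "E0", EngineParams())
    calc_em = DoseCalculator(dv, mm, plan.spots, "E1", EngineParams())
    return dv, mm, st, org, em, calc_org, calc_em


class TestDeliverFraction:
    def test_zero_shift_equals_planned_over_n(self, small_treatment):
        dv, mm, st, org, _, calc, _ = small_treatment
        planned = calc.dose_grid(org.weights)
        fx = deliver_fraction(dv, mm, org, (0.0, 0.0, 0.0), n_fractions=30,
                              calculator=calc)
        assert np.allclose(fx.data, planned.data / 30.0, rtol=1e-12, atol=1e-15)

    def test_missing_weights_rejected(self, small_treatment):
        dv, mm, st, org, _, calc, _ = small_treatment
        bare = TreatmentPlan(spot_plan=org.spot_plan, energy="E0", weights=None)
        with pytest.raises(ValueError):
            deliver_fraction(dv, mm, bare, (0, 0, 0))

    def test_axial_shift_leaves_dose_unchanged(self, water_box):
        """A shift along the beam axis does not change any pencil beam's
        range, hence (in the patient frame) leaves the dose invariant."""
        dv, mm = water_box
        spots = pd.DataFrame({"beam": [0], "angle": [0.0], "u": [0.0],
                              "v": [0.0], "E0": [110]})
        plan = TreatmentPlan(SpotPlan(spots=spots), "E0", np.ones(1))
        calc = DoseCalculator(dv, mm, spots, "E0", EngineParams())
        d0 = deliver_fraction(dv, mm, plan, (0.0, 0.0, 0.0), calculator=calc)
        d1 = deliver_fraction(dv, mm, plan, (0.0, 4.0, 0.0), calculator=calc)
        assert np.allclose(d0.data, d1.data, rtol=1e-9, atol=1e-12)

    def test_lateral_shift_translates_dose_in_uniform_medium(self, water_box):
        dv, mm = water_box
        spots = pd.DataFrame({"beam": [0], "angle": [0.0], "u": [0.0],
                              "v": [0.0], "E0": [110]})
        plan = TreatmentPlan(SpotPlan(spots=spots), "E0", np.ones(1))
        calc = DoseCalculator(dv, mm, spots, "E0", EngineParams())
        planned = deliver_fraction(dv, mm, plan, (0.0, 0.0, 0.0), calculator=calc)
        shifted = deliver_fraction(dv, mm, plan, (2.0, 0.0, 0.0), calculator=calc)
        # patient moved +2 mm in x (one voxel): dose in the patient frame
        # moves by -2 mm (interior voxels; entry face is flat)
        assert np.allclose(shifted.data[:-1], planned.data[1:],
                           rtol=1e-6, atol=1e-9)

    def test_shift_into_cavity_deepens_peak(self, small_phantom_fine):
        """Moving a spot's path from water into the abutting air cavity
        extends its range by roughly the cavity chord."""
        dv, mm, st = small_phantom_fine
        # beam 270 travels +x; BEV u = -y.  u=14 -> y=-14 misses the 12 mm
        # cavity; a -4 mm y-shift moves the effective path to y=-10, whose
        # cavity chord is ~13 mm of air
        spots = pd.DataFrame({"beam": [0], "angle": [270.0], "u": [14.0],
                              "v": [1.0], "E0": [85]})
        plan = TreatmentPlan(SpotPlan(spots=spots), "E0", np.ones(1))
        calc = DoseCalculator(dv, mm, spots, "E0", EngineParams())
        iy = int(np.argmin(np.abs(dv.axis_coords(1) + 14.0)))
        iz = int(np.argmin(np.abs(dv.axis_coords(2) - 1.0)))
        flat = np.ravel_multi_index(
            (np.arange(dv.shape[0]), np.full(dv.shape[0], iy),
             np.full(dv.shape[0], iz)), dv.shape)
        d0 = calc.dose_flat(np.ones(1), voxel_flat=flat)
        d1 = calc.dose_flat(np.ones(1), shift=(0.0, -4.0, 0.0), voxel_flat=flat)
        x = dv.axis_coords(0)
        assert x[np.argmax(d1)] - x[np.argmax(d0)] >= 10.0


class TestSimulateCourse:
    def test_zero_shifts_reproduce_planned(self, small_treatment):
        dv, mm, st, org, em, calc_org, calc_em = small_treatment
        ss = ShiftSet(shifts=np.zeros((30, 3)))
        mask = st["CTV"] | st["ring"]
        c_org, c_em = simulate_course(dv, mm, org, em, ss, eval_mask=mask,
                                      calculators=(calc_org, calc_em))
        flat = np.flatnonzero(mask.ravel())
        for calc, plan, course in ((calc_org, org, c_org), (calc_em, em, c_em)):
            planned = calc.dose_flat(plan.weights, voxel_flat=flat)
            total = course.total()
            assert np.max(np.abs(total - planned)) <= 1e-6 * max(planned.max(), 1.0)

    def test_shared_shift_set_is_identical_object_data(self, small_treatment):
        dv, mm, st, org, em, calc_org, calc_em = small_treatment
        ss = sample_shifts(5, seed=3)
        before = ss.shifts.tobytes()
        mask = st["CTV"]
        simulate_course(dv, mm, org, em, ss, eval_mask=mask,
                        calculators=(calc_org, calc_em))
        assert ss.shifts.tobytes() == before

    def test_reproducible_under_seed(self, small_treatment):
        dv, mm, st, org, em, calc_org, calc_em = small_treatment
        mask = st["CTV"]
        outs = []
        for _ in range(2):
            ss = sample_shifts(5, seed=21)
            c_org, c_em = simulate_course(dv, mm, org, em, ss, eval_mask=mask,
                                          calculators=(calc_org, calc_em))
            outs.append((c_org.values.tobytes(), c_em.values.tobytes()))
        assert outs[0] == outs[1]

    def test_missing_weights_rejected(self, small_treatment):
        dv, mm, st, org, em, *_ = small_treatment
        bare = TreatmentPlan(spot_plan=org.spot_plan, energy="E0", weights=None)
        with pytest.raises(ValueError):
            simulate_course(dv, mm, bare, em, ShiftSet(shifts=np.zeros((2, 3))))
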