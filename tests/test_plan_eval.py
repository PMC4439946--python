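import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from detem.grids import DoseGrid
from detem.plan_eval import (DVHCurve, NTDGrid, compute_dvh, dvh_metric,
                             ntd_accumulate, ntd_uniform_course,
                             variation_report)
from detem.uncertainty_sim import FractionDoseSet

GEOM = dict(grid_shape=(4, 4, 4), spacing=(2.0, 2.0, 2.0),
            origin=(0.0, 0.0, 0.0))


def _fractions(values):
    return FractionDoseSet(values=np.asarray(values, dtype=float), **GEOM)


class TestNTD:
    def test_reference_fractionation_gives_physical_dose(self):
        """30 fractions of exactly 2 Gy accumulate to 60 Gy for any alpha/beta."""
        fr = _fractions(np.full((30, 5), 2.0))
        for ab in (0.5, 1.5, 10.0, 100.0):
            ntd = ntd_accumulate(fr, ab)
            assert np.all(ntd.values == 60.0)

    def test_hand_evaluated_single_fractions(self):
        fr = _fractions(np.full((1, 1), 4.0))
        assert ntd_accumulate(fr, 10.0).values[0] == pytest.approx(4 * 14 / 12, abs=1e-12)
        assert ntd_accumulate(fr, 1.5).values[0] == pytest.approx(4 * 5.5 / 3.5, abs=1e-12)

    def test_infinite_alpha_beta_limit_is_physical_dose(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.0, 4.0, size=(30, 20))
        ntd = ntd_accumulate(_fractions(vals), 1e6)
        assert np.allclose(ntd.values, vals.sum(axis=0), rtol=1e-5)

    def test_convex_increasing_in_fraction_dose(self):
        d = np.linspace(0.0, 6.0, 50)
        ntd = np.array([ntd_accumulate(_fractions([[x]]), 1.5).values[0] for x in d])
        assert np.all(np.diff(ntd) > 0)
        assert np.all(np.diff(ntd, 2) > -1e-12)

    def test_uniform_course_closed_form_matches_accumulation(self):
        totals = np.array([0.0, 30.0, 60.0, 75.0])
        n = 30
        fr = _fractions(np.tile(totals / n, (n, 1)))
        for ab in (1.5, 10.0):
            assert np.allclose(ntd_accumulate(fr, ab).values,
                               ntd_uniform_course(totals, n, ab), atol=1e-9)

    def test_invalid_alpha_beta(self):
        with pytest.raises(ValueError):
            ntd_accumulate(_fractions(np.ones((2, 2))), 0.0)


class TestDVH:
    def test_uniform_dose_step_function(self):
        vals = np.full((4, 4, 4), 60.0)
        curve = compute_dvh(vals, np.ones_like(vals, dtype=bool))
        assert dvh_metric(curve, 98) == pytest.approx(60.0, abs=0.1)
        assert dvh_metric(curve, 2) == pytest.approx(60.0, abs=0.1)
        assert curve.volume_pct[0] == 100.0
        assert curve.volume_pct[-1] == 0.0

    def test_two_level_distribution(self):
        vals = np.concatenate([np.full(50, 30.0), np.full(50, 60.0)])
        curve = compute_dvh(vals, np.ones(100, dtype=bool))
        # 50% of volume at >= 45 Gy; D50 ~ 60, D98 ~ 30
        i45 = np.searchsorted(curve.dose, 45.0)
        assert curve.volume_pct[i45] == pytest.approx(50.0)
        assert dvh_metric(curve, 50) == pytest.approx(60.0, abs=0.2)
        assert dvh_metric(curve, 98) == pytest.approx(30.0, abs=0.2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_dvh(np.ones((4, 4, 4)), np.zeros((4, 4, 4), dtype=bool))

    def test_percentile_bounds(self):
        vals = np.ones(10)
        curve = compute_dvh(vals, np.ones(10, dtype=bool))
        for bad in (0.0, -5.0, 101.0):
            with pytest.raises(ValueError):
                dvh_metric(curve, bad)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.sampled_from([2.0, 20.0, 50.0, 95.0, 98.0]))
    def test_metric_matches_sort_oracle(self, seed, pct):
        """Curve-interpolated Dx% agrees with the exact voxel-sorting oracle
        to within one histogram bin."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.0, 70.0, size=rng.integers(2000, 5000))
        curve = compute_dvh(vals, np.ones(vals.size, dtype=bool), bin_width=0.1)
        oracle = np.quantile(vals, 1.0 - pct / 100.0)
        assert dvh_metric(curve, pct) == pytest.approx(oracle, abs=0.5)

    def test_zero_shift_course_dvh_matches_planned(self, small_phantom):
        dv, mm, structures = small_phantom
        rng = np.random.default_rng(4)
        planned = rng.uniform(50.0, 62.0, size=dv.shape)
        fr = FractionDoseSet(values=np.tile(planned.ravel() / 30.0, (30, 1)),
                             grid_shape=dv.shape, spacing=dv.spacing,
                             origin=dv.origin)
        total = fr.total().reshape(dv.shape)
        mask = structures["CTV"]
        c1 = compute_dvh(planned, mask)
        c2 = compute_dvh(total, mask)
        for pct in (98, 50, 2):
            assert dvh_metric(c1, pct) == pytest.approx(dvh_metric(c2, pct),
                                                        abs=0.11)


class TestVariationReport:
    def _setup(self, delta=0.0):
        shape = (6, 6, 6)
        planned = DoseGrid(data=np.full(shape, 60.0), spacing=(2, 2, 2))
        structures = {
            "CTV": np.ones(shape, dtype=bool),
            "ring": np.ones(shape, dtype=bool),
        }
        delivered = {}
        for name, ab in (("CTV", 10.0), ("ring", 1.5)):
            vals = ntd_uniform_course(np.full(np.prod(shape), 60.0), 30, ab) + delta
            delivered[name] = NTDGrid(values=vals, alpha_beta=ab,
                                      grid_shape=shape, spacing=(2, 2, 2),
                                      origin=(0, 0, 0),
                                      voxel_flat=np.arange(np.prod(shape)))
        return planned, delivered, structures

    def test_delivered_equals_planned_gives_zero_variation(self):
        planned, delivered, structures = self._setup(0.0)
        rep = variation_report(planned, delivered, structures)
        assert np.allclose(rep.table.variation_pct, 0.0, atol=1e-9)

    def test_uniform_underdose_of_1p8_gy_is_minus_3pct(self):
        planned, delivered, structures = self._setup(-1.8)
        rep = variation_report(planned, delivered, structures)
        assert np.allclose(rep.table.variation_pct, -3.0, atol=0.01)

    def test_expected_metrics_present(self):
        planned, delivered, structures = self._setup(0.0)
        rep = variation_report(planned, delivered, structures)
        got = {(r.structure, r.metric) for r in rep.table.itertuples()}
        assert {("CTV", "D98"), ("CTV", "D95"), ("CTV", "D50"), ("CTV", "D2"),
                ("ring", "D2"), ("ring", "D20"), ("ring", "D50")} <= got

    def test_report_io(self, tmp_path):
        planned, delivered, structures = self._setup(-0.6)
        rep = variation_report(planned, delivered, structures)
        rep.write(tmp_path / "variation")
        assert (tmp_path / "variation.csv").exists()
        assert (tmp_path / "variation.json").exists()
        # one 0.1 Gy DVH bin corresponds to 0.167% of prescription
        assert rep.variation("CTV", 95) == pytest.approx(-1.0, abs=0.2)
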