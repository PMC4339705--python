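"""Dose warping, accumulation and DVH machinery."""

import numpy as np
import pytest

from doseacc.core_image import Volume, VectorField
from doseacc.dose_accumulation import (
    DoseGrid,
    accumulate,
    compute_dvh,
    dvh_difference,
    mean_dose,
    warp_dose,
)


def dose(arr, provenance="week"):
    return DoseGrid(np.asarray(arr, dtype=float), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0),
                    "Gy", provenance)


class TestWarpDose:
    def test_zero_field_is_identity(self, rng):
        d = dose(rng.uniform(0, 70, (8, 8, 8)))
        out = warp_dose(d, VectorField.zeros_like(d))
        np.testing.assert_array_equal(out.voxels, d.voxels)
        assert out.provenance == d.provenance

    def test_constant_dose_stays_constant(self, rng):
        d = dose(np.full((8, 8, 8), 2.0))
        disp = rng.uniform(-1.5, 1.5, size=(8, 8, 8, 3))
        mask = np.zeros((8, 8, 8, 1)); mask[1:-1, 1:-1, 1:-1] = 1.0
        out = warp_dose(d, VectorField(disp * mask, spacing=d.spacing, origin=d.origin))
        np.testing.assert_allclose(out.voxels, 2.0, atol=1e-12)

    def test_linear_gradient_shifts_exactly(self):
        geom = dose(np.zeros((12, 10, 8)))
        p = geom.grid_points()
        d = dose(1.0 + 0.5 * p[..., 0])
        disp = np.tile([5.0, 0.0, 0.0], d.shape + (1,))
        out = warp_dose(d, VectorField(disp, spacing=d.spacing, origin=d.origin))
        expected = 1.0 + 0.5 * (p[..., 0] + 5.0)
        np.testing.assert_allclose(out.voxels[:-3], expected[:-3], atol=1e-9)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            dose(np.full((4, 4, 4), -1.0))


class TestAccumulate:
    def test_six_constant_weeks(self):
        weeks = [dose(np.full((6, 6, 6), 2.0), f"week{w}") for w in range(1, 7)]
        total = accumulate(weeks)
        np.testing.assert_allclose(total.voxels, 12.0)
        assert total.provenance == "cumulated"

    def test_permutation_invariant(self, rng):
        weeks = [dose(rng.uniform(0, 3, (5, 5, 5))) for _ in range(4)]
        a = accumulate(weeks).voxels
        b = accumulate(weeks[::-1]).voxels
        np.testing.assert_allclose(a, b)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            accumulate([])

    def test_geometry_mismatch_rejected(self):
        a = dose(np.zeros((5, 5, 5)))
        b = DoseGrid(np.zeros((5, 5, 5)), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), "Gy", "week")
        with pytest.raises(ValueError):
            accumulate([a, b])


class TestDVH:
    def test_uniform_dose_step_curve(self):
        d = dose(np.full((6, 6, 6), 20.0))
        mask = np.ones((6, 6, 6))
        curve = compute_dvh(d, mask, bin_width_gy=1.0)
        assert curve.at(np.array([0.0]))[0] == 100.0
        assert curve.at(np.array([19.5]))[0] == 100.0
        assert curve.at(np.array([20.5]))[0] == 0.0
        assert curve.volume_pct[0] == 100.0 and curve.volume_pct[-1] == 0.0
        assert np.all(np.diff(curve.volume_pct) <= 1e-12)

    def test_two_valued_dose_has_half_plateau(self):
        arr = np.full((6, 6, 6), 10.0)
        arr[:3] = 30.0
        curve = compute_dvh(dose(arr), np.ones((6, 6, 6)), bin_width_gy=1.0)
        mid = curve.at(np.array([15.0, 25.0]))
        np.testing.assert_allclose(mid, 50.0)

    def test_mean_recovered_from_differential_histogram(self, rng):
        arr = rng.uniform(0, 60, (8, 8, 8))
        mask = np.ones((8, 8, 8))
        bw = 0.1
        curve = compute_dvh(dose(arr), mask, bin_width_gy=bw)
        diff = -np.diff(curve.volume_pct) / 100.0          # fraction per bin
        centers = 0.5 * (curve.edges[:-1] + curve.edges[1:])
        est_mean = np.sum(diff * centers)
        assert est_mean == pytest.approx(arr.mean(), abs=bw / 2)
        assert diff.sum() == pytest.approx(1.0, abs=1e-12)  # volume conserved

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_dvh(dose(np.ones((4, 4, 4))), np.zeros((4, 4, 4)))


class TestMeanDose:
    def test_uniform(self):
        assert mean_dose(dose(np.full((4, 4, 4), 26.0)), np.ones((4, 4, 4))) == 26.0

    def test_half_and_half(self):
        arr = np.zeros((4, 4, 4)); arr[:2] = 70.0
        assert mean_dose(dose(arr), np.ones((4, 4, 4))) == pytest.approx(35.0)

    def test_matches_brute_force_on_random_mask(self, rng):
        arr = rng.uniform(0, 70, (6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.5
        expected = arr[mask].mean()
        assert mean_dose(dose(arr), mask.astype(float)) == pytest.approx(expected, rel=1e-12)


class TestDvhDifference:
    def test_identical_curves_give_zero(self):
        d = dose(np.full((6, 6, 6), 30.0))
        c = compute_dvh(d, np.ones((6, 6, 6)))
        out = dvh_difference(c, c)
        np.testing.assert_allclose(out["volume_pct_diff"], 0.0, atol=1e-12)

    def test_fraction_scaling_reproduces_total_course_plan(self):
        # a uniform 2 Gy fraction, scaled by the 35 delivered fractions,
        # matches a uniform 70 Gy plan exactly
        frac = compute_dvh(dose(np.full((6, 6, 6), 2.0)), np.ones((6, 6, 6)))
        plan = compute_dvh(dose(np.full((6, 6, 6), 70.0)), np.ones((6, 6, 6)))
        out = dvh_difference(frac, plan, scale_to_total=35.0)
        np.testing.assert_allclose(out["volume_pct_diff"], 0.0, atol=1e-9)

    def test_ten_percent_volume_shift_plateau(self):
        base = np.full((10, 10, 10), 50.0)
        shifted = base.copy()
        shifted[:1] = 10.0  # 10% of the volume drops out of the high-dose region
        c_plan = compute_dvh(dose(base), np.ones((10, 10, 10)))
        c_week = compute_dvh(dose(shifted), np.ones((10, 10, 10)))
        out = dvh_difference(c_week, c_plan)
        sel = (out["dose_gy"] > 12) & (out["dose_gy"] < 48)
        np.testing.assert_allclose(out.loc[sel, "volume_pct_diff"], -10.0, atol=1e-9)
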