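"""Landmark scoring, accuracy/precision aggregation and method comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from doseacc.core_image import VectorField
from doseacc.dose_accumulation import DoseGrid
from doseacc.evaluation import (
    LandmarkSet,
    accuracy_precision,
    compare_methods,
    cumulated_dose_at_landmarks,
    cumulated_dose_error,
    landmark_errors,
    load_landmark_catalog,
    propagate_landmarks,
)


def lm_set(positions, n=None):
    positions = np.asarray(positions, dtype=float)
    n = n or len(positions)
    return LandmarkSet(
        np.arange(1, n + 1),
        [f"lm{i}" for i in range(n)],
        ["bone" if i < n // 2 else "soft" for i in range(n)],
        positions,
    )


class TestCatalog:
    def test_fourteen_entries_balanced_tissues(self):
        cat = load_landmark_catalog()
        assert len(cat) == 14
        assert (cat["tissue"] == "bone").sum() == 7
        assert (cat["tissue"] == "soft").sum() == 7
        assert cat["index"].is_unique

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet([1, 1], ["a", "b"], ["bone", "soft"], np.zeros((2, 3)))


class TestPropagation:
    def test_zero_field_keeps_positions(self):
        lms = lm_set([[10.0, 10.0, 10.0], [20.0, 12.0, 8.0]])
        fld = VectorField(np.zeros((20, 20, 20, 3)), (2.0, 2.0, 2.0))
        out = propagate_landmarks(lms, fld)
        np.testing.assert_allclose(out.positions, lms.positions)

    def test_constant_field_shifts_all(self):
        lms = lm_set([[10.0, 10.0, 10.0], [20.0, 12.0, 8.0]])
        fld = VectorField(np.tile([5.0, 0.0, 0.0], (20, 20, 20, 1)), (2.0, 2.0, 2.0))
        out = propagate_landmarks(lms, fld)
        np.testing.assert_allclose(out.positions - lms.positions, [[5.0, 0.0, 0.0]] * 2)


class TestLandmarkErrors:
    def test_identical_sets_zero(self):
        lms = lm_set(np.random.default_rng(0).normal(size=(5, 3)))
        assert landmark_errors(lms, lms).eq(0).all()

    def test_three_four_five_triangle(self):
        a = lm_set([[0.0, 0.0, 0.0]])
        b = lm_set([[3.0, 4.0, 0.0]])
        assert landmark_errors(a, b).iloc[0] == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        pa, pb = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        got = landmark_errors(lm_set(pa), lm_set(pb)).to_numpy()
        expected = np.sqrt(((pa - pb) ** 2).sum(axis=1))
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_index_mismatch_rejected(self):
        a = lm_set(np.zeros((2, 3)))
        b = LandmarkSet([3, 4], ["x", "y"], ["bone", "soft"], np.zeros((2, 3)))
        with pytest.raises(ValueError):
            landmark_errors(a, b)


class TestAccuracyPrecision:
    def test_two_landmark_hand_case(self):
        acc, prec = accuracy_precision({1: [1.0, 3.0], 2: [2.0, 2.0]})
        assert acc == pytest.approx(2.0)
        assert prec == pytest.approx(np.mean([np.std([1, 3], ddof=1), 0.0]))
        assert prec == pytest.approx(0.7071, abs=1e-4)

    def test_constant_errors(self):
        acc, prec = accuracy_precision({1: [2.5, 2.5], 2: [2.5, 2.5]})
        assert acc == 2.5 and prec == 0.0

    def test_single_group_sd(self):
        acc, prec = accuracy_precision({1: [0.0, 2.0, 4.0]})
        assert acc == pytest.approx(2.0)
        assert prec == pytest.approx(2.0)

    def test_all_singletons_gives_nan_precision(self):
        acc, prec = accuracy_precision({1: [1.0], 2: [3.0]})
        assert acc == pytest.approx(2.0)
        assert np.isnan(prec)

    def test_scaling_property(self, rng):
        groups = {i: rng.uniform(0, 5, 4) for i in range(5)}
        acc, prec = accuracy_precision(groups)
        acc3, prec3 = accuracy_precision({k: 3 * v for k, v in groups.items()})
        assert acc3 == pytest.approx(3 * acc)
        assert prec3 == pytest.approx(3 * prec)

    def test_group_mean_first_option(self):
        acc, _ = accuracy_precision({1: [0.0, 0.0, 0.0, 4.0], 2: [2.0]}, accuracy_over="groups")
        assert acc == pytest.approx((1.0 + 2.0) / 2)


class TestCumulatedDose:
    def grid(self, arr):
        return DoseGrid(np.asarray(arr, float), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), "Gy", "week")

    def test_constant_weekly_doses_sum(self):
        doses = [self.grid(np.full((10, 10, 10), 2.0)) for _ in range(6)]
        pos = [lm_set([[8.0, 8.0, 8.0], [10.0, 6.0, 6.0]]) for _ in range(6)]
        out = cumulated_dose_at_landmarks(doses, pos)
        np.testing.assert_allclose(out.to_numpy(), 12.0)

    def test_additive_over_weeks(self, rng):
        doses = [self.grid(rng.uniform(0, 3, (10, 10, 10))) for _ in range(4)]
        pos = [lm_set(rng.uniform(4, 14, (3, 3))) for _ in range(4)]
        total = cumulated_dose_at_landmarks(doses, pos)
        running = sum(
            cumulated_dose_at_landmarks([d], [p]) for d, p in zip(doses, pos)
        )
        np.testing.assert_allclose(total.to_numpy(), running.to_numpy(), atol=1e-12)

    def test_systematic_offset_on_linear_dose(self):
        # 1 Gy/mm gradient along x; a 2 mm propagation offset along the
        # gradient accumulates 2 Gy per week, 12 Gy over six weeks
        geom = self.grid(np.zeros((16, 10, 10)))
        p = geom.grid_points()
        d = self.grid(p[..., 0] * 1.0)
        truth = [lm_set([[10.0, 10.0, 10.0]]) for _ in range(6)]
        offset = [lm_set([[12.0, 10.0, 10.0]]) for _ in range(6)]
        doses = [d] * 6
        ref = cumulated_dose_at_landmarks(doses, truth)
        est = cumulated_dose_at_landmarks(doses, offset)
        assert (est - ref).iloc[0] == pytest.approx(12.0, abs=1e-9)

    def test_error_aggregation_hand_case(self):
        ref = pd.Series([10.0, 20.0], index=[1, 2])
        est = pd.Series([11.0, 18.0], index=[1, 2])
        res = cumulated_dose_error(ref, est)
        np.testing.assert_allclose(res.errors.to_numpy(), [1.0, 2.0])
        assert res.accuracy == pytest.approx(1.5)
        assert res.precision == pytest.approx(np.std([1.0, 2.0], ddof=1))

    def test_identical_estimates_zero_error(self):
        ref = pd.Series([5.0, 6.0, 7.0], index=[1, 2, 3])
        res = cumulated_dose_error(ref, ref.copy())
        assert res.accuracy == 0.0 and res.errors.eq(0).all()


def error_table(errors_by_method, n_cells=None):
    rows = []
    for method, errs in errors_by_method.items():
        for i, e in enumerate(errs):
            rows.append(
                {"method": method, "patient": i % 2, "week": (i // 2) % 6 + 1,
                 "landmark": i % 14 + 1, "error_mm": e}
            )
    return pd.DataFrame(rows)


class TestCompareMethods:
    def test_identical_methods_not_ordered(self, rng):
        errs = rng.uniform(0, 5, 84)
        table = error_table({"A": errs, "B": errs.copy()})
        res = compare_methods(table)
        assert res.p_adjusted.loc["A", "B"] == pytest.approx(1.0)
        assert not res.better_pairs

    def test_uniformly_worse_method_detected(self, rng):
        errs = rng.uniform(0, 5, 84)
        table = error_table({"A": errs, "B": errs + 1.0})
        res = compare_methods(table)
        # exact sign-test oracle: 84 of 84 negative differences
        oracle_p = stats.binomtest(84, 84, 0.5, alternative="greater").pvalue
        assert res.p_one_sided.loc["A", "B"] == pytest.approx(oracle_p)
        assert oracle_p == pytest.approx(0.5**84)
        assert res.p_adjusted.loc["A", "B"] < 0.01
        assert ("A", "B") in {(a, b) for a, b, _ in res.better_pairs}

    def test_antisymmetric_ordering(self, rng):
        errs = rng.uniform(0, 5, 84)
        table = error_table({"A": errs, "B": errs + 0.5})
        res = compare_methods(table)
        winners = {(a, b) for a, b, _ in res.better_pairs}
        assert ("A", "B") in winners and ("B", "A") not in winners
        assert res.p_adjusted.loc["B", "A"] > 0.5

    def test_unmatched_design_rejected(self, rng):
        table = error_table({"A": rng.uniform(0, 5, 84), "B": rng.uniform(0, 5, 70)})
        with pytest.raises(ValueError):
            compare_methods(table)

    def test_summary_mentions_ordering(self, rng):
        errs = rng.uniform(0, 5, 84)
        res = compare_methods(error_table({"A": errs, "B": errs + 1.0}))
        assert "A < B" in res.summary()
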