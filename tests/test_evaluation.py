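"""Evaluation system: DVH counting, Diff_result orientation, rescaling,
acceptance rule."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoplan import (
    PrescriptionItem,
    compute_dvh,
    diff_result,
    evaluate_plan,
    rescale_to_coverage,
    spider_from_csv,
    spider_to_csv,
)
from autoplan.evaluate import acceptable_from_diffs, dvh_to_csv
from autoplan.optimize import PlanResult


def _plan(dose):
    return PlanResult(
        weights=np.ones(1), dose=dose, sensitivity=[], objective_value=0.0,
        converged=True, kkt_residual=0.0,
    )


class TestDVH:
    def test_uniform_dose_is_step_function(self):
        dose = np.full((8, 8), 50.0)
        mask = np.ones((8, 8), bool)
        dvh = compute_dvh(dose, mask, 0.1)
        assert dvh.at(0.0) == 100.0
        assert dvh.at(50.0) == 100.0
        assert dvh.at(50.2) == 0.0

    def test_matches_brute_force_count_at_every_edge(self):
        rng = np.random.default_rng(5)
        dose = rng.uniform(0, 70, (16, 16))
        mask = rng.random((16, 16)) < 0.6
        dvh = compute_dvh(dose, mask, 0.5)
        d = dose[mask]
        for edge, vol in zip(dvh.edges_gy, dvh.volume_percent):
            assert vol == pytest.approx(100.0 * np.mean(d >= edge))

    def test_monotone_nonincreasing_and_normalized(self):
        rng = np.random.default_rng(6)
        dose = rng.uniform(0, 70, (16, 16))
        dvh = compute_dvh(dose, np.ones((16, 16), bool), 0.1)
        assert dvh.volume_percent[0] == 100.0
        assert (np.diff(dvh.volume_percent) <= 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(np.zeros((4, 4)), np.zeros((4, 4), bool), 0.1)


class TestDiffResult:
    def test_coverage_exactly_at_goal_is_one(self, prostate_case):
        """95% achieved against a 95% requirement scores exactly 1."""
        mask = prostate_case.structure("ptv").mask
        dose = np.zeros(prostate_case.grid_shape)
        d = np.argwhere(mask)
        n = len(d)
        k = int(np.ceil(0.95 * n))
        for iy, ix in d[:k]:
            dose[iy, ix] = 70.0
        item = PrescriptionItem.make("cov", "ptv", "V_D_at_least", 67.5, 95.0)
        r = diff_result(item, dose, prostate_case)
        assert r.achieved == pytest.approx(100.0 * k / n)
        assert r.diff_result == pytest.approx(95.0 / (100.0 * k / n))

    def test_upper_bound_ratio(self, prostate_case):
        dose = np.full(prostate_case.grid_shape, 40.0)
        item = PrescriptionItem.make("dmax", "rectum", "D_max_at_most", 50.0, 50.0)
        r = diff_result(item, dose, prostate_case)
        assert r.diff_result == pytest.approx(0.8)
        assert r.met

    def test_volume_limit_exceeded(self, prostate_case):
        mask = prostate_case.structure("rectum").mask
        dose = np.zeros(prostate_case.grid_shape)
        idx = np.argwhere(mask)
        k = int(round(0.30 * len(idx)))
        for iy, ix in idx[:k]:
            dose[iy, ix] = 55.0
        item = PrescriptionItem.make("v50", "rectum", "V_D_at_most", 50.0, 25.0)
        r = diff_result(item, dose, prostate_case)
        assert r.diff_result == pytest.approx((100.0 * k / len(idx)) / 25.0)
        assert not r.met

    def test_zero_coverage_capped_with_flag(self, prostate_case):
        dose = np.zeros(prostate_case.grid_shape)
        item = PrescriptionItem.make("cov", "ptv", "V_D_at_least", 67.5, 95.0)
        r = diff_result(item, dose, prostate_case)
        assert r.capped
        assert r.diff_result == 100.0


class TestRescale:
    def test_plan_already_at_coverage_unchanged(self, prostate_case):
        target = prostate_case.structure("ptv")
        dose = np.zeros(prostate_case.grid_shape)
        idx = np.argwhere(target.mask)
        k = int(np.ceil(0.95 * len(idx)))
        for i, (iy, ix) in enumerate(idx):
            dose[iy, ix] = 67.5 if i < k else 30.0
        _, s = rescale_to_coverage(_plan(dose), target, 95.0)
        assert s == pytest.approx(1.0)

    def test_scale_invariance(self, prostate_case):
        rng = np.random.default_rng(7)
        target = prostate_case.structure("ptv")
        dose = rng.uniform(30, 80, prostate_case.grid_shape)
        p1, _ = rescale_to_coverage(_plan(dose), target, 95.0)
        p2, _ = rescale_to_coverage(_plan(2.0 * dose), target, 95.0)
        np.testing.assert_allclose(p1.dose, p2.dose, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_hits_coverage_within_half_voxel_and_idempotent(self, seed, prostate_case):
        rng = np.random.default_rng(seed)
        target = prostate_case.structure("ptv")
        dose = rng.uniform(20, 90, prostate_case.grid_shape)
        rescaled, s = rescale_to_coverage(_plan(dose), target, 95.0)
        d = rescaled.dose[target.mask]
        coverage = 100.0 * np.mean(d >= target.prescribed_dose)
        voxel_pct = 100.0 / target.mask.sum()
        assert 95.0 - 1e-9 <= coverage <= 95.0 + voxel_pct
        again, s2 = rescale_to_coverage(rescaled, target, 95.0)
        assert s2 == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(again.dose, rescaled.dose, rtol=1e-12)

    def test_all_zero_dose_rejected(self, prostate_case):
        with pytest.raises(ValueError, match="rescale"):
            rescale_to_coverage(
                _plan(np.zeros(prostate_case.grid_shape)),
                prostate_case.structure("ptv"),
            )


class TestEvaluatePlan:
    def _dose(self, case):
        dose = np.zeros(case.grid_shape)
        dose[case.structure("ptv").mask] = 70.0
        dose[case.structure("rectum").mask] = 20.0
        return dose

    def test_loose_limits_acceptable(self, prostate_case):
        items = [
            PrescriptionItem.make("cov", "ptv", "V_D_at_least", 67.5, 95.0),
            PrescriptionItem.make("rmax", "rectum", "D_max_at_most", 67.5, 75.0),
        ]
        report, _ = evaluate_plan(_plan(self._dose(prostate_case)), items, prostate_case)
        assert report.acceptable

    def test_one_failing_item_rejects_plan(self, prostate_case):
        items = [
            PrescriptionItem.make("cov", "ptv", "V_D_at_least", 67.5, 95.0),
            PrescriptionItem.make("rmax", "rectum", "D_max_at_most", 10.0, 10.0),
        ]
        report, _ = evaluate_plan(_plan(self._dose(prostate_case)), items, prostate_case)
        assert not report.acceptable
        assert report.max_diff > 1.0

    def test_spider_csv_round_trip(self, prostate_case, tmp_path):
        items = [
            PrescriptionItem.make("cov", "ptv", "V_D_at_least", 67.5, 95.0),
            PrescriptionItem.make("rmax", "rectum", "D_max_at_most", 67.5, 75.0),
        ]
        report, _ = evaluate_plan(_plan(self._dose(prostate_case)), items, prostate_case)
        path = tmp_path / "spider.csv"
        spider_to_csv(report, path)
        assert spider_from_csv(path) == pytest.approx(report.diff_map())

    def test_dvh_csv_has_column_per_structure(self, prostate_case, tmp_path):
        path = tmp_path / "dvh.csv"
        dvh_to_csv(self._dose(prostate_case), prostate_case, path, 0.5)
        header = path.read_text().splitlines()[0].split(",")
        assert header[0] == "dose_Gy"
        assert set(header[1:]) == {s.name for s in prostate_case.structures}


@settings(max_examples=300, deadline=None)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=3.0, allow_nan=False),
        min_size=1, max_size=12,
    )
)
def test_acceptance_rule_equivalent_to_max_diff(diffs):
    """acceptable <=> max Diff_result <= 1 (+ tolerance), exactly."""
    assert acceptable_from_diffs(diffs) == (max(diffs) <= 1.0 + 1e-6)
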