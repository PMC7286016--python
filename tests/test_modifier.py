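"""Rule engine: step gating, rule arithmetic, oscillation detection, caps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoplan import (
    CostFunction,
    ModifierState,
    PrescriptionItem,
    Template,
    detect_oscillation,
    ensure_body_cost_functions,
    make_hn_case,
    make_initial_template,
    make_prostate_case,
    run_autoplan,
    step1_adjust_targets,
    step2_adjust_body,
    step3_adjust_oars,
)
from autoplan.config import DEFAULT_CONFIG
from autoplan.evaluate import EvaluationReport, ItemResult
from autoplan.modifier import body_cost_function_ids
from autoplan.optimize import SensitivityRecord


def _report(diff_by_item, items_by_id):
    results = [
        ItemResult(item=items_by_id[i], achieved=0.0, diff_result=d)
        for i, d in diff_by_item.items()
    ]
    ok = all(r.diff_result <= 1.0 + 1e-6 for r in results)
    return EvaluationReport(items=results, acceptable=ok, rescale_factor=1.0)


def _sens(cf_id, impact, iso=1.0, eff=None, lam=1.0):
    return SensitivityRecord(
        cf_id=cf_id, isoconstraint=iso,
        isoeffect=iso if eff is None else eff,
        multiplier=lam if impact > 0 else 0.0, relative_impact=impact,
    )


class TestStep1:
    def test_single_target_case_advances_untouched(self, prostate_case):
        t = make_initial_template(prostate_case)
        state = ModifierState()
        state.note_template(t)
        items = {i.id: i for i in t.prescription_items}
        report = _report({i: 2.0 for i in items}, items)
        out, advanced = step1_adjust_targets(state, t, report, [], prostate_case)
        assert advanced
        assert out == t
        assert state.step == 2

    def test_high_impact_gradient_cf_margin_grown_one_step(self, hn_case):
        t = make_initial_template(hn_case)
        state = ModifierState()
        state.note_template(t)
        items = {i.id: i for i in t.prescription_items}
        report = _report(
            {i: (1.5 if i == "ptv_boost_coverage" else 0.5) for i in items}, items
        )
        sens = [_sens("grad_ptv_elective", impact=0.9)]
        before = t.cost_function("grad_ptv_elective").shrink_margin
        out, advanced = step1_adjust_targets(state, t, report, sens, hn_case)
        assert not advanced
        after = out.cost_function("grad_ptv_elective").shrink_margin
        assert after == pytest.approx(before + DEFAULT_CONFIG.margin_step_mm)
        # only the named cost function was touched
        for cf in out.cost_functions:
            if cf.id != "grad_ptv_elective":
                assert cf == t.cost_function(cf.id)

    def test_met_target_items_advance(self, hn_case):
        t = make_initial_template(hn_case)
        state = ModifierState()
        state.note_template(t)
        items = {i.id: i for i in t.prescription_items}
        report = _report({i: 0.5 for i in items}, items)
        _, advanced = step1_adjust_targets(state, t, report, [], hn_case)
        assert advanced


class TestStep2:
    def test_body_cost_functions_installed_once(self, hn_case):
        t = make_initial_template(hn_case)
        t2 = ensure_body_cost_functions(t, hn_case)
        ids = {cf.id for cf in t2.cost_functions}
        assert set(body_cost_function_ids()) <= ids
        assert ensure_body_cost_functions(t2, hn_case) == t2
        rx = hn_case.primary_target.prescribed_dose
        for level in DEFAULT_CONFIG.body_isodose_levels:
            cf = t2.cost_function(f"tissue_{int(round(100 * level))}")
            assert cf.reference_dose == pytest.approx(level * rx)
            assert cf.structure == "unspecified_tissue"

    def test_above_band_cf_loosened_one_step(self, hn_case):
        t = ensure_body_cost_functions(make_initial_template(hn_case), hn_case)
        state = ModifierState()
        state.note_template(t)
        items = {i.id: i for i in t.prescription_items}
        report = _report({i: 2.0 for i in items}, items)
        sens = [
            _sens("tissue_90", 0.6, iso=t.cost_function("tissue_90").isoconstraint),
            _sens("tissue_80", 0.2, iso=t.cost_function("tissue_80").isoconstraint),
            _sens("tissue_70", 0.2, iso=t.cost_function("tissue_70").isoconstraint),
        ]
        out, advanced = step2_adjust_body(state, t, report, sens, hn_case)
        assert not advanced
        assert out.cost_function("tissue_90").isoconstraint == pytest.approx(
            t.cost_function("tissue_90").isoconstraint * DEFAULT_CONFIG.loosen_step
        )
        assert out.cost_function("tissue_80").isoconstraint == pytest.approx(
            t.cost_function("tissue_80").isoconstraint
        )

    def test_all_in_band_advances_unchanged(self, hn_case):
        t = ensure_body_cost_functions(make_initial_template(hn_case), hn_case)
        state = ModifierState()
        state.step = 2
        state.note_template(t)
        items = {i.id: i for i in t.prescription_items}
        report = _report({i: 2.0 for i in items}, items)
        sens = [_sens(i, 0.2) for i in ("tissue_90", "tissue_80", "tissue_70")]
        out, advanced = step2_adjust_body(state, t, report, sens, hn_case)
        assert advanced
        assert out == t
        assert state.step == 3


class TestStep3:
    def _setup(self, hn_case):
        t = ensure_body_cost_functions(make_initial_template(hn_case), hn_case)
        state = ModifierState()
        state.step = 3
        state.note_template(t)
        items = {i.id: i for i in t.prescription_items}
        return t, state, items

    def test_acceptable_at_entry_terminates_without_modification(self, hn_case):
        t, state, items = self._setup(hn_case)
        report = _report({i: 0.5 for i in items}, items)
        out, terminated = step3_adjust_oars(state, t, report, [], hn_case)
        assert terminated
        assert out == t

    def test_failing_item_tightens_active_cf_by_inverse_diff(self, hn_case):
        """Diff_result 1.25 on an active constraint multiplies its
        isoconstraint by 0.8."""
        t, state, items = self._setup(hn_case)
        cf = t.cost_function("auto_parotid_l_mean")
        diffs = {i: 0.5 for i in items}
        diffs["parotid_l_mean"] = 1.25
        report = _report(diffs, items)
        sens = [_sens(cf.id, 0.5, iso=cf.isoconstraint)]  # active: isoeffect == iso
        out, _ = step3_adjust_oars(state, t, report, sens, hn_case)
        assert out.cost_function(cf.id).isoconstraint == pytest.approx(
            cf.isoconstraint * 0.8
        )

    def test_slack_cf_snapped_to_isoeffect_before_tightening(self, hn_case):
        t, state, items = self._setup(hn_case)
        cf = t.cost_function("auto_cord_max")  # starts at 1.5x the 45 Gy limit
        diffs = {i: 0.5 for i in items}
        diffs["cord_max"] = 1.1
        report = _report(diffs, items)
        sens = [_sens(cf.id, 0.5, iso=cf.isoconstraint, eff=49.5)]
        out, _ = step3_adjust_oars(state, t, report, sens, hn_case)
        assert out.cost_function(cf.id).isoconstraint == pytest.approx(49.5 / 1.1)

    def test_oscillating_item_gets_fixed_weight(self, hn_case):
        t, state, items = self._setup(hn_case)
        state.diff_history["parotid_l_mean"] = [1.1, 0.9, 1.1, 0.9, 1.1]
        diffs = {i: 0.5 for i in items}
        diffs["parotid_l_mean"] = 1.1
        report = _report(diffs, items)
        sens = [_sens("auto_parotid_l_mean", 0.5, lam=2.0)]
        out, _ = step3_adjust_oars(state, t, report, sens, hn_case)
        cf = out.cost_function("auto_parotid_l_mean")
        assert cf.fixed_weight == pytest.approx(
            DEFAULT_CONFIG.oscillation_weight_factor * 2.0
        )
        assert state.oscillation_flags["parotid_l_mean"] == 1

    def test_cap_terminates_with_flag(self, hn_case):
        t, state, items = self._setup(hn_case)
        state.trials_in_step = t.caps[2]
        report = _report({i: 2.0 for i in items}, items)
        _, terminated = step3_adjust_oars(state, t, report, [], hn_case)
        assert terminated
        assert state.warnings


class TestOscillation:
    def test_monotone_series_not_oscillating(self):
        assert not detect_oscillation([1.5, 1.3, 1.1, 0.9, 0.8])

    def test_alternating_series_oscillates(self):
        assert detect_oscillation([1.1, 0.9, 1.1, 0.9])

    def test_short_series_never_oscillates(self):
        assert not detect_oscillation([1.1, 0.9, 1.1])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.5, 1.5, allow_nan=False), min_size=4, max_size=20))
    def test_matches_brute_force_sign_count(self, series):
        signs = [np.sign(d - 1.0) for d in series]
        best = run = 0
        for a, b in zip(signs[:-1], signs[1:]):
            run = run + 1 if a * b < 0 else 0
            best = max(best, run)
        assert detect_oscillation(series) == (best >= 3)


class TestLoopContracts:
    def test_full_run_respects_bounds_and_caps(self, tmp_path):
        case = make_prostate_case(seed=2, overlap_fraction=0.2)
        template = make_initial_template(case)
        log = run_autoplan(case, template, tmp_path / "run", seed=2)
        assert log.n_trials <= sum(template.caps)
        steps = [r.step for r in log.records]
        assert steps == sorted(steps)  # step index never decreases
        initial = {}
        for rec in log.records:
            for cf in rec.template.cost_functions:
                initial.setdefault(cf.id, cf.isoconstraint)
        floor = DEFAULT_CONFIG.isoconstraint_floor_factor
        ceil = DEFAULT_CONFIG.isoconstraint_ceiling_factor
        for rec in log.records:
            for cf in rec.template.cost_functions:
                init = initial[cf.id]
                assert cf.isoconstraint >= floor * init - 1e-9
                assert cf.isoconstraint <= ceil * init + 1e-9
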