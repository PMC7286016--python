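"""Rule-based template modifier: the virtual planner.

The modifier mimics an experienced planner's divide-and-conquer routine in
three steps, each driven by the previous trial's evaluation report and the
optimizer's multiplier sensitivities:

1. **Targets** (multi-target cases only): when a quadratic-overdose function
   that controls the gradient between dose levels shows a high relative
   impact on the primary-target objective, relax it by growing its shrink
   margin.  Advance once the target coverage and uniformity items are met.
2. **Unspecified tissue**: install a global maximum-dose cap plus quadratic
   overdose functions controlling the 90/80/70% isodose surfaces in
   unspecified normal tissue, then tune their RMS isoconstraints (and
   margins) until each shows a *moderate* relative impact — strong enough to
   shape the dose falloff, weak enough to leave room for the OAR constraints
   that come next.
3. **OARs**: impose everything.  Each failing OAR item tightens its driving
   constraint proportionally to its Diff_result; if target coverage suffers
   while some OAR constraints hold with slack, the slack constraint with the
   highest impact is loosened; items that keep oscillating around their goal
   get their constraint promoted to a fixed-weight objective term
   (artificially high priority).  Terminate on an acceptable plan or at the
   trial cap, returning the best trial seen.

Per-step trial caps default to 15, 15 and 30, bounding a run at 60 fluence
optimizations; all per-trial changes are multiplicative with bounded factors
and every isoconstraint is clamped to a window around its initial value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cases import Case
from .config import DEFAULT_CONFIG, AutoplanConfig
from .evaluate import EvaluationReport
from .optimize import PlanResult, SensitivityRecord, effective_mask
from .templates import (
    UNSPECIFIED_TISSUE,
    CostFunction,
    Template,
    find_driving_cf,
)

log = logging.getLogger("autoplan")


@dataclass
class ModifierState:
    """Mutable bookkeeping across trials; history is append-only."""

    config: AutoplanConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    step: int = 1
    trials_in_step: int = 0
    history: list[dict] = field(default_factory=list)
    initial_isoconstraints: dict[str, float] = field(default_factory=dict)
    oscillation_flags: dict[str, int] = field(default_factory=dict)
    diff_history: dict[str, list[float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def note_template(self, template: Template) -> None:
        for cf in template.cost_functions:
            self.initial_isoconstraints.setdefault(cf.id, cf.isoconstraint)

    def record_trial(
        self, template: Template, report: EvaluationReport, result: PlanResult
    ) -> None:
        self.history.append(
            {
                "step": self.step,
                "template": template.model_dump(mode="json"),
                "max_diff": report.max_diff,
                "acceptable": report.acceptable,
                "diffs": report.diff_map(),
                "sensitivity": [r.to_dict() for r in result.sensitivity],
            }
        )
        if self.step == 3:
            for r in report.items:
                self.diff_history.setdefault(r.item.id, []).append(r.diff_result)

    def advance(self, warning: str | None = None) -> None:
        if warning:
            log.warning(warning)
            self.warnings.append(warning)
        self.step += 1
        self.trials_in_step = 0


def _clamp_isoconstraint(state: ModifierState, cf: CostFunction, value: float) -> float:
    init = state.initial_isoconstraints.get(cf.id, cf.isoconstraint)
    lo = state.config.isoconstraint_floor_factor * init
    hi = state.config.isoconstraint_ceiling_factor * init
    return float(min(max(value, lo), hi))


def _impact(sensitivity: list[SensitivityRecord], cf_id: str) -> float:
    for r in sensitivity:
        if r.cf_id == cf_id:
            return r.relative_impact
    return 0.0


def _isoeffect(sensitivity: list[SensitivityRecord], cf_id: str) -> float | None:
    for r in sensitivity:
        if r.cf_id == cf_id:
            return r.isoeffect
    return None


def _tighten(
    state: ModifierState,
    sensitivity: list[SensitivityRecord],
    cf: CostFunction,
    factor: float,
) -> None:
    """Tighten an isoconstraint: snap a slack bound down to the achieved
    isoeffect first (tightening a bound the plan already beats is a no-op),
    then apply the bounded multiplicative step."""
    base = cf.isoconstraint
    eff = _isoeffect(sensitivity, cf.id)
    if eff is not None and eff < base:
        base = eff
    cf.isoconstraint = _clamp_isoconstraint(state, cf, base * factor)


def _target_items_met(report: EvaluationReport, case: Case) -> bool:
    target_names = {t.name for t in case.targets}
    return all(r.met for r in report.items if r.item.structure in target_names)


# ---------------------------------------------------------------------------
# step 1: targets
# ---------------------------------------------------------------------------

def step1_adjust_targets(
    state: ModifierState,
    template: Template,
    report: EvaluationReport,
    sensitivity: list[SensitivityRecord],
    case: Case,
) -> tuple[Template, bool]:
    """Returns (template, advanced).  Single-target cases advance untouched."""
    cfg = state.config
    if len(case.targets) < 2:
        state.advance()
        return template, True
    if _target_items_met(report, case):
        state.advance()
        return template, True
    if state.trials_in_step >= template.caps[0]:
        state.advance("step 1 cap reached without meeting all target items")
        return template, True

    target_names = {t.name for t in case.targets}
    t = template.model_copy(deep=True)
    modified = []
    for cf in t.cost_functions:
        if (
            cf.kind == "quadratic_overdose"
            and cf.structure in target_names
            and cf.role == "constraint"
            and _impact(sensitivity, cf.id) > cfg.high_impact
        ):
            new_margin = cf.shrink_margin + cfg.margin_step_mm
            if effective_mask(
                cf.model_copy(update={"shrink_margin": new_margin}), case
            ).any():
                cf.shrink_margin = new_margin
                modified.append(cf.id)
    if not modified:
        state.advance(
            "step 1: target items unmet but no high-impact gradient constraint to relax"
        )
        return template, True
    log.info("step 1: grew shrink margins of %s", modified)
    return t, False


# ---------------------------------------------------------------------------
# step 2: unspecified normal tissue
# ---------------------------------------------------------------------------

def body_cost_function_ids(config: AutoplanConfig = DEFAULT_CONFIG) -> list[str]:
    return ["body_max"] + [
        f"tissue_{int(round(100 * f))}" for f in config.body_isodose_levels
    ]


def ensure_body_cost_functions(
    template: Template, case: Case, config: AutoplanConfig = DEFAULT_CONFIG
) -> Template:
    """Install the global max-dose cap and the isodose-shell overdose
    functions on unspecified tissue, if not already present."""
    t = template.model_copy(deep=True)
    existing = {cf.id for cf in t.cost_functions}
    rx = case.primary_target.prescribed_dose
    if "body_max" not in existing:
        cap = config.body_max_dose_factor * rx
        t.cost_functions.append(
            CostFunction(
                id="body_max",
                structure=case.body.name,
                kind="max_dose",
                reference_dose=cap,
                isoconstraint=cap,
            )
        )
    for i, level in enumerate(config.body_isodose_levels):
        cf_id = f"tissue_{int(round(100 * level))}"
        if cf_id in existing:
            continue
        ref = level * rx
        t.cost_functions.append(
            CostFunction(
                id=cf_id,
                structure=UNSPECIFIED_TISSUE,
                kind="quadratic_overdose",
                reference_dose=ref,
                isoconstraint=0.04 * ref,
                shrink_margin=(i + 1) * config.margin_step_mm,
            )
        )
    return t


def step2_adjust_body(
    state: ModifierState,
    template: Template,
    report: EvaluationReport,
    sensitivity: list[SensitivityRecord],
    case: Case,
) -> tuple[Template, bool]:
    """Tune the tissue overdose functions into the moderate-impact band."""
    cfg = state.config
    lo, hi = cfg.moderate_band
    shell_ids = [i for i in body_cost_function_ids(cfg) if i != "body_max"]
    impacts = {i: _impact(sensitivity, i) for i in shell_ids if _has_cf(template, i)}
    in_band = all(lo <= v <= hi for v in impacts.values())
    if in_band:
        state.advance()
        return template, True
    if state.trials_in_step >= template.caps[1]:
        state.advance("step 2 cap reached with tissue constraints out of band")
        return template, True

    t = template.model_copy(deep=True)
    for cf in t.cost_functions:
        v = impacts.get(cf.id)
        if v is None:
            continue
        if v > hi:
            cf.isoconstraint = _clamp_isoconstraint(state, cf, cf.isoconstraint * cfg.loosen_step)
            log.info("step 2: loosened %s to %.3f (impact %.2f)", cf.id, cf.isoconstraint, v)
        elif v < lo:
            _tighten(state, sensitivity, cf, cfg.tighten_floor)
            log.info("step 2: tightened %s to %.3f (impact %.2f)", cf.id, cf.isoconstraint, v)
    if t.model_dump() == template.model_dump():
        # stalemate: every prescribed adjustment was clamped to a no-op, so
        # another trial would repeat this one exactly — move on
        state.advance()
        return template, True
    return t, False


def _has_cf(template: Template, cf_id: str) -> bool:
    return any(cf.id == cf_id for cf in template.cost_functions)


# ---------------------------------------------------------------------------
# step 3: OARs
# ---------------------------------------------------------------------------

def detect_oscillation(diff_series: list[float], min_alternations: int = 3) -> bool:
    """True when (Diff_result - 1) alternated sign in at least
    ``min_alternations`` consecutive trial pairs."""
    if len(diff_series) < min_alternations + 1:
        return False
    signs = np.sign(np.asarray(diff_series) - 1.0)
    run = 0
    best = 0
    for a, b in zip(signs[:-1], signs[1:]):
        if a * b < 0:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best >= min_alternations


def step3_adjust_oars(
    state: ModifierState,
    template: Template,
    report: EvaluationReport,
    sensitivity: list[SensitivityRecord],
    case: Case,
) -> tuple[Template, bool]:
    """Returns (template, terminated).  Termination on acceptance is decided
    by the caller; here it means the step-3 trial cap was exhausted."""
    cfg = state.config
    if report.acceptable:
        return template, True
    if state.trials_in_step >= template.caps[2]:
        state.advance("step 3 cap reached without an acceptable plan")
        return template, True

    oar_names = {s.name for s in case.oars}
    target_names = {t.name for t in case.targets}
    t = template.model_copy(deep=True)

    # (a) tighten the driving constraint of every failing item; the primary
    # coverage item is driven by the objective itself and is skipped
    for r in report.items:
        if r.met:
            continue
        cf = find_driving_cf(t, r.item)
        if cf is None or cf.role == "objective" or cf.fixed_weight is not None:
            continue
        # at least a 1% step: a barely-failing item (diff 1.001) would
        # otherwise tighten by a factor indistinguishable from 1
        factor = max(cfg.tighten_floor, min(1.0 / r.diff_result, 0.99))
        _tighten(state, sensitivity, cf, factor)
        log.info(
            "step 3: tightened %s by %.3f for item %s (diff %.3f)",
            cf.id, factor, r.item.id, r.diff_result,
        )

    # (b) coverage rescue: loosen the highest-impact slack OAR constraint
    # (a zero-impact constraint is inactive — loosening it cannot help)
    coverage_failing = any(
        not r.met
        for r in report.items
        if r.item.structure in target_names and r.item.direction == "lower_bound"
    )
    if coverage_failing:
        slack_cfs = []
        for r in report.items:
            if r.item.structure not in oar_names or not r.met:
                continue
            cf = find_driving_cf(t, r.item)
            if (
                cf is not None
                and cf.role == "constraint"
                and cf.fixed_weight is None
                and _impact(sensitivity, cf.id) > 0.0
            ):
                slack_cfs.append(cf)
        if slack_cfs:
            slack_cfs.sort(key=lambda cf: (-_impact(sensitivity, cf.id), cf.id))
            cf = slack_cfs[0]
            cf.isoconstraint = _clamp_isoconstraint(
                state, cf, cf.isoconstraint * cfg.loosen_step
            )
            log.info("step 3: loosened %s for target coverage", cf.id)

    # (c) oscillating OAR items get a fixed-weight priority override; the
    # weight is floored so the penalty never degenerates when the active
    # multipliers are numerically tiny
    active = [r.multiplier for r in sensitivity if r.multiplier > 1e-6]
    mean_lambda = max(float(np.mean(active)) if active else 1.0, 1.0)
    for item_id, series in state.diff_history.items():
        if not detect_oscillation(series):
            continue
        r = report.result(item_id)
        if r.item.structure not in oar_names:
            continue
        cf = find_driving_cf(t, r.item)
        if cf is None or cf.role == "objective" or cf.fixed_weight is not None:
            continue
        cf.fixed_weight = cfg.oscillation_weight_factor * mean_lambda
        state.oscillation_flags[item_id] = state.oscillation_flags.get(item_id, 0) + 1
        log.info(
            "step 3: item %s oscillates; fixed weight %.3f on %s",
            item_id, cf.fixed_weight, cf.id,
        )
    return t, False


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def propose_next_template(
    state: ModifierState,
    template: Template,
    report: EvaluationReport,
    result: PlanResult,
    case: Case,
) -> tuple[Template, bool]:
    """One modifier decision after a trial.

    Returns (template for the next trial, terminated).  ``terminated`` is
    only True when step 3 gives up (its cap); acceptance termination is the
    driver's call.  Step advances consume no trial.
    """
    sens = result.sensitivity
    if state.step == 1:
        new_t, advanced = step1_adjust_targets(state, template, report, sens, case)
        if advanced:
            # entering step 2: install the tissue constraints, then run a trial
            new_t = ensure_body_cost_functions(new_t, case, state.config)
            state.note_template(new_t)
        return new_t, False
    if state.step == 2:
        new_t, _advanced = step2_adjust_body(state, template, report, sens, case)
        return new_t, False
    new_t, terminated = step3_adjust_oars(state, template, report, sens, case)
    return new_t, terminated
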