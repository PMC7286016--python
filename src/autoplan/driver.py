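"""Trial orchestration: initialize from template, optimize, evaluate, modify,
repeat — until the plan is acceptable or the trial caps run out.

Every trial appends one JSON line to ``trials.jsonl`` (flushed immediately,
so a partial log is always parseable), stores the trial's template, and the
run ends with the final DVH and spider-chart CSVs.  The numeric content of a
run is fully determined by (case, template, seed, config); wall-clock fields
are the only nondeterministic entries in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cases import Case
from .config import DEFAULT_CONFIG, AutoplanConfig
from .dose import BeamletMatrix, build_beamlet_matrix
from .evaluate import EvaluationReport, dvh_to_csv, evaluate_plan, spider_to_csv
from .modifier import ModifierState, ensure_body_cost_functions, propose_next_template
from .optimize import PlanResult, active_cost_functions, solve_fmo
from .templates import (
    Template,
    augment_constraint_set,
    load_template,
    save_template,
    template_to_json,
    validate_template,
)

log = logging.getLogger("autoplan")

LOG_SCHEMA_VERSION = "1"


@dataclass
class TrialRecord:
    trial: int
    step: int
    template: Template
    objective_value: float
    converged: bool
    kkt_residual: float
    feasibility_gy: float
    complementarity: float
    sensitivity: list[dict]
    diff_results: dict[str, float]
    achieved: dict[str, float]
    acceptable: bool
    rescale_factor: float
    max_diff: float
    wall_time_s: float
    solver_trace: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["template"] = self.template.model_dump(mode="json")
        d["type"] = "trial"
        return d


@dataclass
class TrialLog:
    case_hash: str
    case_path: str
    seed: int
    records: list[TrialRecord] = field(default_factory=list)
    verdict: str = "error"  # acceptable | best_effort | error
    best_trial: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.records)

    def record(self, trial: int) -> TrialRecord:
        for r in self.records:
            if r.trial == trial:
                return r
        raise IndexError(f"no trial {trial} in log (have 1..{self.n_trials})")


def run_autoplan(
    case: Case | str | Path,
    template: Template | str | Path,
    out_dir: str | Path,
    seed: int = 0,
    config: AutoplanConfig = DEFAULT_CONFIG,
    matrix: BeamletMatrix | None = None,
) -> TrialLog:
    """Run the full auto-planning loop for one case.

    ``case`` / ``template`` may be objects or file paths.  Writes
    ``trials.jsonl``, per-trial templates, ``dvh_final.csv`` and
    ``spider_final.csv`` into ``out_dir``; returns the trial log.  The loop
    never raises on planning failure — the verdict is ``acceptable``,
    ``best_effort`` (caps exhausted) or ``error`` (a module error aborted the
    loop; the partial log stays intact).
    """
    case_path = ""
    if not isinstance(case, Case):
        case_path = str(case)
        case = Case.load(case)
    if not isinstance(template, Template):
        template = load_template(template)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_template(template, case)
    template = augment_constraint_set(template, case, config)

    if matrix is None:
        matrix = build_beamlet_matrix(case, config=config)
    items = template.prescription_items

    state = ModifierState(config=config)
    state.note_template(template)
    if len(case.targets) < 2:
        # single dose level: the target-gradient step has nothing to do
        state.step = 2
        template = ensure_body_cost_functions(template, case, config)
        state.note_template(template)

    trial_log = TrialLog(case_hash=case.case_hash(), case_path=case_path, seed=seed)
    log_path = out / "trials.jsonl"
    max_total = sum(template.caps)

    with open(log_path, "w") as fh:
        header = {
            "type": "header",
            "schema_version": LOG_SCHEMA_VERSION,
            "case_hash": trial_log.case_hash,
            "case_path": case_path,
            "seed": seed,
            "config": config.to_dict(),
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        fh.flush()

        final_plan: PlanResult | None = None
        final_report: EvaluationReport | None = None
        trial = 0
        try:
            while trial < max_total:
                trial += 1
                state.trials_in_step += 1
                t0 = time.perf_counter()
                current = template.model_copy(
                    update={"stage_state": state.step, "trial_index": trial}
                )
                cfs = active_cost_functions(current, case, state.step)
                trace: list[dict] = []
                result = solve_fmo(
                    case, matrix, current, config, cost_functions=cfs, trace=trace
                )
                report, plan = evaluate_plan(result, items, case, config)
                wall = time.perf_counter() - t0

                record = TrialRecord(
                    trial=trial,
                    step=state.step,
                    template=current,
                    objective_value=result.objective_value,
                    converged=result.converged,
                    kkt_residual=result.kkt_residual,
                    feasibility_gy=result.feasibility_gy,
                    complementarity=result.complementarity,
                    sensitivity=[r.to_dict() for r in result.sensitivity],
                    diff_results=report.diff_map(),
                    achieved={r.item.id: r.achieved for r in report.items},
                    acceptable=report.acceptable,
                    rescale_factor=report.rescale_factor,
                    max_diff=report.max_diff,
                    wall_time_s=wall,
                    solver_trace=trace,
                )
                trial_log.records.append(record)
                fh.write(json.dumps(record.to_json_dict(), sort_keys=True) + "\n")
                fh.flush()
                save_template(current, out / f"template_trial_{trial}.json")
                state.record_trial(current, report, result)
                log.info(
                    "trial %d (step %d): max_diff=%.3f acceptable=%s converged=%s",
                    trial, state.step, report.max_diff, report.acceptable, result.converged,
                )

                if report.acceptable:
                    trial_log.verdict = "acceptable"
                    final_plan, final_report = plan, report
                    break
                prev_step = state.step
                template, terminated = propose_next_template(
                    state, current, report, result, case
                )
                if terminated:
                    trial_log.verdict = "best_effort"
                    break
                if (
                    state.step == prev_step
                    and state.step == 3
                    and template_to_json(template) == template_to_json(
                        current.model_copy(update={"stage_state": state.step, "trial_index": trial})
                    )
                ):
                    # identical template and step: the deterministic loop is
                    # stuck repeating itself — stop rather than burn the cap
                    state.warnings.append("step 3 deadlock: template unchanged, stopping early")
                    trial_log.verdict = "best_effort"
                    break
            else:
                trial_log.verdict = "best_effort"
        except Exception:  # noqa: BLE001 - abort gracefully, keep the partial log
            log.exception("auto-planning loop aborted at trial %d", trial)
            trial_log.verdict = "error"

        trial_log.warnings = list(state.warnings)
        if trial_log.records:
            best = min(trial_log.records, key=lambda r: (r.max_diff, r.trial))
            trial_log.best_trial = best.trial
        footer = {
            "type": "footer",
            "verdict": trial_log.verdict,
            "best_trial": trial_log.best_trial,
            "n_trials": trial_log.n_trials,
            "warnings": trial_log.warnings,
        }
        fh.write(json.dumps(footer, sort_keys=True) + "\n")
        fh.flush()

    if final_plan is None and trial_log.records:
        # reproduce the best trial's plan for the final exports
        best_record = trial_log.record(trial_log.best_trial)
        result, final_plan = _replay_record(best_record, case, matrix, config)
        final_report, _ = evaluate_plan(result, items, case, config)
    if final_plan is not None and final_report is not None:
        dvh_to_csv(final_plan.dose, case, out / "dvh_final.csv", config.dvh_bin_gy)
        spider_to_csv(final_report, out / "spider_final.csv")
        _dump_plan(final_plan, out / "plan_final.json")
    return trial_log


def _dump_plan(plan: PlanResult, path: Path) -> None:
    payload = {
        "weights": [float(w) for w in plan.weights],
        "objective_value": plan.objective_value,
        "converged": plan.converged,
        "kkt_residual": plan.kkt_residual,
        "dose_stats": {
            "max_gy": float(plan.dose.max()),
            "mean_gy": float(plan.dose.mean()),
        },
    }
    path.write_text(json.dumps(payload, sort_keys=True))


def _replay_record(
    record: TrialRecord, case: Case, matrix: BeamletMatrix, config: AutoplanConfig
) -> tuple[PlanResult, PlanResult]:
    """Re-solve one trial; returns (raw result, rescaled plan)."""
    cfs = active_cost_functions(record.template, case, record.step)
    result = solve_fmo(case, matrix, record.template, config, cost_functions=cfs)
    _report, plan = evaluate_plan(
        result, record.template.prescription_items, case, config
    )
    return result, plan


def read_trial_log(log_path: str | Path) -> tuple[dict, list[TrialRecord], dict | None]:
    """Parse a trials.jsonl file: (header, records, footer-or-None).

    Records written before a crash are always recoverable."""
    header: dict | None = None
    footer: dict | None = None
    records: list[TrialRecord] = []
    with open(log_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            kind = obj.get("type")
            if kind == "header":
                header = obj
            elif kind == "footer":
                footer = obj
            elif kind == "trial":
                obj.pop("type")
                obj["template"] = Template.model_validate(obj["template"])
                records.append(TrialRecord(**obj))
    if header is None:
        raise ValueError(f"{log_path}: no header record")
    return header, records, footer


def replay_trial(
    log_path: str | Path,
    trial_index: int,
    case: Case | str | Path | None = None,
    matrix: BeamletMatrix | None = None,
) -> PlanResult:
    """Re-run the fluence optimization of one logged trial and verify that it
    reproduces the stored Diff_result values to within 1e-6.

    ``case`` defaults to the path recorded in the log header; a case whose
    hash differs from the log's is refused.
    """
    header, records, _ = read_trial_log(log_path)
    matching = [r for r in records if r.trial == trial_index]
    if not matching:
        raise IndexError(
            f"trial {trial_index} not in log (trials 1..{len(records)})"
        )
    record = matching[0]

    if case is None:
        if not header.get("case_path"):
            raise ValueError("log does not record a case path; pass the case explicitly")
        case = header["case_path"]
    if not isinstance(case, Case):
        case = Case.load(case)
    if case.case_hash() != header["case_hash"]:
        raise ValueError(
            f"case hash mismatch: log has {header['case_hash']}, "
            f"supplied case is {case.case_hash()}"
        )
    config = AutoplanConfig(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in header["config"].items()
    })
    if matrix is None:
        matrix = build_beamlet_matrix(case, config=config)
    result, plan = _replay_record(record, case, matrix, config)
    report, _ = evaluate_plan(result, record.template.prescription_items, case, config)
    for item_id, stored in record.diff_results.items():
        redone = report.diff_map()[item_id]
        if abs(redone - stored) > 1e-6:
            raise ValueError(
                f"replay mismatch on item {item_id!r}: stored {stored!r}, got {redone!r}"
            )
    return result
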