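"""Plan templates: the complete optimization specification for one trial.

A template is the messenger between the rule engine and the optimizer: it
carries the cost-function set (one objective plus constraints, each with an
isoconstraint and a shrink margin), the prescription items the plan is judged
against, and bookkeeping for the three-step modifier.  Templates are versioned
JSON — plain text and diffable, so trial-to-trial template diffs are part of
the run log.

The initial-template editor operations live here too: structure-name
reconciliation and constraint-set augmentation (every prescription item must
have a cost function capable of driving it before the loop starts).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from .cases import Case
from .config import DEFAULT_CONFIG, AutoplanConfig

log = logging.getLogger("autoplan")

TEMPLATE_SCHEMA_VERSION = "1"

#: pseudo-structure resolved as body minus all targets
UNSPECIFIED_TISSUE = "unspecified_tissue"

CFKind = Literal["quadratic_underdose", "quadratic_overdose", "max_dose", "serial_eud"]
Metric = Literal["V_D_at_least", "V_D_at_most", "D_max_at_most", "D_mean_at_most"]

_METRIC_DIRECTION = {
    "V_D_at_least": "lower_bound",
    "V_D_at_most": "upper_bound",
    "D_max_at_most": "upper_bound",
    "D_mean_at_most": "upper_bound",
}


class CostFunction(BaseModel):
    """One TPS-style cost function.

    ``isoconstraint`` is the user-set bound: an RMS excess in Gy for the
    quadratic kinds, a dose in Gy for ``max_dose``, an EUD in Gy for
    ``serial_eud``.  ``shrink_margin`` erodes the structure away from the
    adjacent higher-priority target before the function is evaluated.
    A set ``fixed_weight`` moves the function out of the constraint set and
    into the objective as a weighted penalty (manual-priority override).
    """

    id: str
    structure: str
    kind: CFKind
    reference_dose: float = Field(gt=0.0)
    isoconstraint: float = Field(ge=0.0)
    shrink_margin: float = Field(default=0.0, ge=0.0)
    role: Literal["objective", "constraint"] = "constraint"
    fixed_weight: Optional[float] = Field(default=None, gt=0.0)
    eud_k: Optional[float] = None


class PrescriptionItem(BaseModel):
    """One dosimetric goal on a target or OAR.

    ``threshold`` is a %-volume for the V_D metrics and a dose in Gy for the
    D_max / D_mean metrics.
    """

    id: str
    structure: str
    metric: Metric
    dose_gy: float = Field(gt=0.0)
    threshold: float = Field(gt=0.0)
    direction: Literal["lower_bound", "upper_bound"]

    @model_validator(mode="after")
    def _direction_matches_metric(self) -> "PrescriptionItem":
        expected = _METRIC_DIRECTION[self.metric]
        if self.direction != expected:
            raise ValueError(
                f"item {self.id!r}: metric {self.metric} requires direction {expected}"
            )
        return self

    @classmethod
    def make(cls, id: str, structure: str, metric: Metric, dose_gy: float, threshold: float):
        return cls(
            id=id,
            structure=structure,
            metric=metric,
            dose_gy=dose_gy,
            threshold=threshold,
            direction=_METRIC_DIRECTION[metric],
        )


class Template(BaseModel):
    version: str = TEMPLATE_SCHEMA_VERSION
    case_ref: str = ""
    cost_functions: list[CostFunction]
    prescription_items: list[PrescriptionItem]
    stage_state: int = Field(default=1, ge=1, le=3)
    trial_index: int = 0
    caps: tuple[int, int, int] = (15, 15, 30)

    @field_validator("caps")
    @classmethod
    def _caps_positive(cls, v):
        if any(c <= 0 for c in v):
            raise ValueError("per-step trial caps must be positive")
        return v

    @model_validator(mode="after")
    def _one_objective(self) -> "Template":
        n_obj = sum(1 for cf in self.cost_functions if cf.role == "objective")
        if n_obj != 1:
            raise ValueError(f"template must have exactly one objective cost function, got {n_obj}")
        ids = [cf.id for cf in self.cost_functions]
        if len(ids) != len(set(ids)):
            raise ValueError("cost function ids must be unique")
        return self

    @property
    def objective(self) -> CostFunction:
        return next(cf for cf in self.cost_functions if cf.role == "objective")

    def cost_function(self, cf_id: str) -> CostFunction:
        for cf in self.cost_functions:
            if cf.id == cf_id:
                return cf
        raise KeyError(f"no cost function {cf_id!r}")

    def referenced_structures(self) -> set[str]:
        return {cf.structure for cf in self.cost_functions} | {
            it.structure for it in self.prescription_items
        }


def resolve_mask(case: Case, name: str):
    """Structure mask by name; the pseudo-structure ``unspecified_tissue``
    resolves to body minus all targets."""
    if name == UNSPECIFIED_TISSUE:
        return case.unspecified_tissue()
    return case.structure(name).mask


def structure_resolves(case: Case, name: str) -> bool:
    return name == UNSPECIFIED_TISSUE or case.has_structure(name)


def validate_template(template: Template, case: Case) -> None:
    """Raise if any referenced structure does not resolve against the case."""
    missing = sorted(
        n for n in template.referenced_structures() if not structure_resolves(case, n)
    )
    if missing:
        raise ValueError(f"template references structures absent from the case: {missing}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def save_template(template: Template, path: str | Path) -> None:
    Path(path).write_text(template_to_json(template))


def template_to_json(template: Template) -> str:
    return json.dumps(template.model_dump(mode="json"), indent=1, sort_keys=True)


def load_template(path: str | Path) -> Template:
    raw = json.loads(Path(path).read_text())
    if str(raw.get("version", TEMPLATE_SCHEMA_VERSION)) != TEMPLATE_SCHEMA_VERSION:
        raise ValueError(f"unsupported template schema version {raw.get('version')!r}")
    return Template.model_validate(raw)


# ---------------------------------------------------------------------------
# initial-template editor operations
# ---------------------------------------------------------------------------

def reconcile_structures(
    template: Template, case: Case, name_map: dict[str, str]
) -> Template:
    """Rename structure references via ``name_map`` and verify everything
    resolves against the case.  Unresolved names raise, listing them."""
    for old, new in name_map.items():
        if not structure_resolves(case, new):
            raise ValueError(f"name_map target {new!r} does not exist in the case")

    def rename(name: str) -> str:
        return name_map.get(name, name)

    t = template.model_copy(deep=True)
    for cf in t.cost_functions:
        cf.structure = rename(cf.structure)
    for item in t.prescription_items:
        item.structure = rename(item.structure)
    unresolved = sorted(
        n for n in t.referenced_structures() if not structure_resolves(case, n)
    )
    if unresolved:
        raise ValueError(f"unresolved structure names after reconciliation: {unresolved}")
    return t


#: metric → cost-function kinds able to drive it
_DRIVER_KINDS = {
    "D_max_at_most": ("max_dose",),
    "V_D_at_most": ("quadratic_overdose", "max_dose"),
    "D_mean_at_most": ("quadratic_overdose", "serial_eud"),
    "V_D_at_least": ("quadratic_underdose",),
}


def find_driving_cf(template: Template, item: PrescriptionItem) -> Optional[CostFunction]:
    """The cost function responsible for an item: an augmentation-created one
    by id convention first, else the first kind-compatible one on the item's
    structure (the objective drives coverage items on its own structure)."""
    auto_id = f"auto_{item.id}"
    for cf in template.cost_functions:
        if cf.id == auto_id:
            return cf
    if item.metric == "V_D_at_least" and template.objective.structure == item.structure:
        return template.objective
    for cf in template.cost_functions:
        if cf.structure == item.structure and cf.kind in _DRIVER_KINDS[item.metric]:
            return cf
    return None


def augment_constraint_set(
    template: Template, case: Case, config: AutoplanConfig = DEFAULT_CONFIG
) -> Template:
    """Ensure every prescription item has a cost function able to drive it.

    Added functions start deliberately loose (1.5x the limit for max-dose
    items, a generous RMS for quadratic overdose / underdose drivers) so the
    modifier tightens from a feasible side.  Idempotent.
    """
    validate_template(template, case)
    t = template.model_copy(deep=True)
    for item in t.prescription_items:
        if find_driving_cf(t, item) is not None:
            continue
        cf_id = f"auto_{item.id}"
        if item.metric == "D_max_at_most":
            cf = CostFunction(
                id=cf_id,
                structure=item.structure,
                kind="max_dose",
                reference_dose=item.threshold,
                isoconstraint=1.5 * item.threshold,
            )
        elif item.metric in ("V_D_at_most", "D_mean_at_most"):
            ref = item.dose_gy
            cf = CostFunction(
                id=cf_id,
                structure=item.structure,
                kind="quadratic_overdose",
                reference_dose=ref,
                isoconstraint=0.3 * ref,
            )
        else:  # V_D_at_least on a non-objective structure
            # reference a few % above the goal dose: voxels sitting just under
            # the goal would otherwise defeat the V_D count at zero RMS cost
            cf = CostFunction(
                id=cf_id,
                structure=item.structure,
                kind="quadratic_underdose",
                reference_dose=1.05 * item.dose_gy,
                isoconstraint=0.02 * item.dose_gy,
            )
        log.info("augment: added %s (%s on %s) for item %s", cf.id, cf.kind, cf.structure, item.id)
        t.cost_functions.append(cf)
    return t


# ---------------------------------------------------------------------------
# site-default initial templates and prescriptions
# ---------------------------------------------------------------------------

def default_prescription(case: Case) -> list[PrescriptionItem]:
    """Clinically-styled prescription items for the synthetic sites."""
    items: list[PrescriptionItem] = []
    for t in case.targets:
        items.append(
            PrescriptionItem.make(
                f"{t.name}_coverage", t.name, "V_D_at_least", t.prescribed_dose, 95.0
            )
        )
    primary = case.primary_target
    items.append(
        PrescriptionItem.make(
            f"{primary.name}_max", primary.name, "D_max_at_most",
            primary.prescribed_dose, 1.10 * primary.prescribed_dose,
        )
    )
    if case.site == "prostate":
        items += [
            PrescriptionItem.make("rectum_v60", "rectum", "V_D_at_most", 60.0, 35.0),
            PrescriptionItem.make("rectum_v50", "rectum", "V_D_at_most", 50.0, 50.0),
            PrescriptionItem.make("bladder_v50", "bladder", "V_D_at_most", 50.0, 30.0),
            PrescriptionItem.make("bladder_v40", "bladder", "V_D_at_most", 40.0, 45.0),
        ]
    elif case.site == "hn_sib":
        items += [
            PrescriptionItem.make("cord_max", "cord", "D_max_at_most", 45.0, 45.0),
            PrescriptionItem.make("parotid_l_mean", "parotid_l", "D_mean_at_most", 26.0, 26.0),
            PrescriptionItem.make("parotid_r_mean", "parotid_r", "D_mean_at_most", 26.0, 26.0),
        ]
    else:
        for oar in case.oars:
            items.append(
                PrescriptionItem.make(
                    f"{oar.name}_max", oar.name, "D_max_at_most",
                    primary.prescribed_dose, 0.8 * primary.prescribed_dose,
                )
            )
    return items


def make_initial_template(
    case: Case,
    items: Optional[list[PrescriptionItem]] = None,
    config: AutoplanConfig = DEFAULT_CONFIG,
) -> Template:
    """Build the starting template for a case: a quadratic-underdose objective
    on the primary target, coverage and gradient-control functions for the
    secondary targets, then augmentation so every prescription item has a
    driver.  Body (unspecified-tissue) functions are installed by the modifier
    when its second step begins."""
    if items is None:
        items = default_prescription(case)
    primary = case.primary_target
    cfs: list[CostFunction] = [
        CostFunction(
            id=f"obj_{primary.name}",
            structure=primary.name,
            kind="quadratic_underdose",
            reference_dose=primary.prescribed_dose,
            isoconstraint=0.0,
            role="objective",
        )
    ]
    for t in case.targets[1:]:
        # coverage driver: reference ~5% above the level so the V_D goal is
        # met with margin, loose RMS start
        cfs.append(
            CostFunction(
                id=f"cov_{t.name}",
                structure=t.name,
                kind="quadratic_underdose",
                reference_dose=1.05 * t.prescribed_dose,
                isoconstraint=0.02 * t.prescribed_dose,
            )
        )
        cfs.append(
            CostFunction(
                id=f"grad_{t.name}",
                structure=t.name,
                kind="quadratic_overdose",
                reference_dose=1.05 * t.prescribed_dose,
                isoconstraint=0.05 * t.prescribed_dose,
                shrink_margin=config.margin_step_mm,
            )
        )
    template = Template(
        case_ref=case.case_hash(),
        cost_functions=cfs,
        prescription_items=items,
    )
    return augment_constraint_set(template, case, config)
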