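"""Constrained fluence-map optimization with multiplier sensitivities.

The plan optimization problem is

    minimize    f(phi)                 (objective cost function)
    subject to  g_i(phi) <= c_i        (constraint cost functions)
                phi >= 0               (beamlet weights)

where dose is linear in the weights, D(phi) = A phi.  At a KKT point the
stationarity condition  grad f = -sum_i lambda_i grad g_i  holds, so the
multipliers lambda_i measure how strongly each constraint limits the
objective: tightening an active constraint by dc degrades the optimum by
about lambda_i * dc.  The solver reports, per constraint, the isoconstraint
(the set bound c_i), the isoeffect (the achieved value g_i), the multiplier,
and the relative impact lambda_i / sum_j lambda_j — the sensitivity data the
rule-based modifier feeds on.

The solver is an augmented-Lagrangian method: each constraint is expressed as
a smooth normalized function u(phi) <= b (quadratic kinds are kept in squared
form, max-dose becomes one linear bound per voxel, serial EUD is kept in
power-mean form), the inner bound-constrained subproblem is solved with
L-BFGS-B, and the multiplier estimates are the standard AL updates
max(0, lambda + rho (u - b)).  Multipliers are converted back to the
dose-space parameterization (dF/dc_i, units of f per Gy) before
normalization so that the relative impacts of different constraint kinds are
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.optimize import minimize

from .cases import Case
from .config import DEFAULT_CONFIG, AutoplanConfig
from .dose import BeamletMatrix
from .templates import CostFunction, Template, resolve_mask, validate_template

log = logging.getLogger("autoplan")


# ---------------------------------------------------------------------------
# shrink margins and cost-function evaluation
# ---------------------------------------------------------------------------

def apply_shrink_margin(
    structure_mask: np.ndarray,
    margin_mm: float,
    source_mask: np.ndarray,
    voxel_size_mm: tuple[float, float],
) -> np.ndarray:
    """Remove from ``structure_mask`` every voxel within ``margin_mm`` of the
    source mask (the adjacent higher-priority target).

    A zero margin returns the mask unchanged; a positive margin also removes
    the overlap with the source itself (distance zero).  May return an empty
    mask; the caller decides whether that is an error.
    """
    if margin_mm < 0:
        raise ValueError("shrink margin must be nonnegative")
    if margin_mm == 0.0 or not source_mask.any():
        return structure_mask.copy()
    dist = ndimage.distance_transform_edt(~source_mask, sampling=voxel_size_mm)
    return structure_mask & (dist > margin_mm)


def shrink_source_mask(case: Case, cf: CostFunction) -> np.ndarray:
    """Source the shrink margin erodes away from: all targets with a strictly
    higher prescription than the cost function's own structure (all targets,
    for OAR / body functions)."""
    own_dose = 0.0
    if case.has_structure(cf.structure):
        s = case.structure(cf.structure)
        if s.kind == "target":
            own_dose = s.prescribed_dose
    src = np.zeros(case.grid_shape, dtype=bool)
    for t in case.targets:
        if t.prescribed_dose > own_dose:
            src |= t.mask
    return src


def effective_mask(cf: CostFunction, case: Case) -> np.ndarray:
    """The voxel set a cost function is evaluated on: its structure eroded by
    the shrink margin away from higher-priority targets."""
    mask = resolve_mask(case, cf.structure)
    return apply_shrink_margin(
        mask, cf.shrink_margin, shrink_source_mask(case, cf), case.voxel_size_mm
    )


def evaluate_cost(
    cf: CostFunction,
    dose: np.ndarray,
    case: Case,
    config: AutoplanConfig = DEFAULT_CONFIG,
) -> float:
    """Isoeffect of a cost function on a dose grid (Gy).

    quadratic_overdose  -> RMS of max(0, d - reference) over the mask
    quadratic_underdose -> RMS of max(0, reference - d)
    max_dose            -> max masked dose
    serial_eud          -> (mean d^k)^(1/k), k = cf.eud_k or config default
    """
    mask = effective_mask(cf, case)
    if not mask.any():
        raise ValueError(
            f"cost function {cf.id!r}: structure {cf.structure!r} is empty "
            f"after a {cf.shrink_margin} mm shrink margin"
        )
    d = dose[mask]
    if cf.kind == "quadratic_overdose":
        return float(np.sqrt(np.mean(np.maximum(0.0, d - cf.reference_dose) ** 2)))
    if cf.kind == "quadratic_underdose":
        return float(np.sqrt(np.mean(np.maximum(0.0, cf.reference_dose - d) ** 2)))
    if cf.kind == "max_dose":
        return float(d.max())
    k = cf.eud_k if cf.eud_k is not None else config.serial_eud_k
    return float(np.mean(np.maximum(d, 0.0) ** k) ** (1.0 / k))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class SensitivityRecord:
    cf_id: str
    isoconstraint: float
    isoeffect: float
    multiplier: float
    relative_impact: float

    def to_dict(self) -> dict:
        return {
            "cf_id": self.cf_id,
            "isoconstraint": self.isoconstraint,
            "isoeffect": self.isoeffect,
            "multiplier": self.multiplier,
            "relative_impact": self.relative_impact,
        }


@dataclass
class PlanResult:
    weights: np.ndarray
    dose: np.ndarray
    sensitivity: list[SensitivityRecord]
    objective_value: float
    converged: bool
    kkt_residual: float
    feasibility_gy: float = 0.0
    complementarity: float = 0.0
    n_outer: int = 0
    violations: dict[str, float] = field(default_factory=dict)

    def record(self, cf_id: str) -> SensitivityRecord:
        for r in self.sensitivity:
            if r.cf_id == cf_id:
                return r
        raise KeyError(f"no sensitivity record for {cf_id!r}")


def extract_sensitivity(result: PlanResult) -> list[SensitivityRecord]:
    """Records sorted by relative impact, largest first."""
    return sorted(result.sensitivity, key=lambda r: (-r.relative_impact, r.cf_id))


# ---------------------------------------------------------------------------
# smooth constraint blocks
# ---------------------------------------------------------------------------

class _Block:
    """One cost function as a smooth normalized constraint u(phi) <= b."""

    def __init__(self, cf: CostFunction, case: Case, A: sparse.csr_matrix, config: AutoplanConfig):
        self.cf = cf
        mask = effective_mask(cf, case)
        if not mask.any():
            raise ValueError(
                f"cost function {cf.id!r}: empty effective mask on {cf.structure!r}"
            )
        self.rows = np.flatnonzero(mask.ravel())
        self.A = A[self.rows, :].tocsr()
        self.n = self.rows.size
        self.config = config
        c = cf.isoconstraint
        ref = cf.reference_dose
        if cf.kind in ("quadratic_overdose", "quadratic_underdose"):
            self.scale = max(c, 0.1)
            self.bound = (c / self.scale) ** 2
        elif cf.kind == "max_dose":
            self.scale = max(c, 1.0)
            self.bound = np.full(self.n, c / self.scale)
        else:  # serial_eud
            self.k = cf.eud_k if cf.eud_k is not None else config.serial_eud_k
            self.scale = max(c, 1.0)
            self.bound = (c / self.scale) ** self.k

    @property
    def is_vector(self) -> bool:
        return self.cf.kind == "max_dose"

    def dose(self, phi: np.ndarray) -> np.ndarray:
        return self.A @ phi

    def u_and_grad_coeff(self, d: np.ndarray):
        """u(phi) and du/dd per masked voxel (grad_phi u = A^T coeff)."""
        cf, s = self.cf, self.scale
        if cf.kind == "quadratic_overdose":
            ex = np.maximum(0.0, d - cf.reference_dose)
            return np.mean(ex**2) / s**2, (2.0 / (self.n * s**2)) * ex
        if cf.kind == "quadratic_underdose":
            ex = np.maximum(0.0, cf.reference_dose - d)
            return np.mean(ex**2) / s**2, (-2.0 / (self.n * s**2)) * ex
        if cf.kind == "max_dose":
            return d / s, np.full(self.n, 1.0 / s)
        dd = np.maximum(d, 0.0) / s
        return np.mean(dd**self.k), (self.k / (self.n * s)) * dd ** (self.k - 1.0)

    def isoeffect(self, d: np.ndarray) -> float:
        cf = self.cf
        if cf.kind == "quadratic_overdose":
            return float(np.sqrt(np.mean(np.maximum(0.0, d - cf.reference_dose) ** 2)))
        if cf.kind == "quadratic_underdose":
            return float(np.sqrt(np.mean(np.maximum(0.0, cf.reference_dose - d) ** 2)))
        if cf.kind == "max_dose":
            return float(d.max())
        return float(np.mean(np.maximum(d, 0.0) ** self.k) ** (1.0 / self.k))

    def violation_gy(self, d: np.ndarray) -> float:
        return max(0.0, self.isoeffect(d) - self.cf.isoconstraint)

    def multiplier_to_dose_space(self, lam) -> float:
        """Convert the AL multiplier(s) of the normalized form to dF/dc in
        units of f per Gy, so kinds are comparable."""
        cf, s = self.cf, self.scale
        if cf.kind in ("quadratic_overdose", "quadratic_underdose"):
            return float(lam) * 2.0 * cf.isoconstraint / s**2
        if cf.kind == "max_dose":
            return float(np.sum(lam)) / s
        c = max(cf.isoconstraint, 1e-12)
        return float(lam) * self.k * (c / s) ** (self.k - 1.0) / s


class _Objective:
    """The objective cost function plus any fixed-weight penalty functions,
    as a smooth normalized scalar f(phi)."""

    def __init__(
        self,
        objective_cf: CostFunction,
        penalty_cfs: list[CostFunction],
        case: Case,
        A: sparse.csr_matrix,
        config: AutoplanConfig,
    ):
        self.main = _Block(objective_cf, case, A, config)
        self.penalties = [(_Block(cf, case, A, config), cf.fixed_weight) for cf in penalty_cfs]

    def value_and_grad(self, phi: np.ndarray):
        d = self.main.dose(phi)
        u, coeff = self.main.u_and_grad_coeff(d)
        val = u
        grad = self.main.A.T @ coeff
        for blk, w in self.penalties:
            db = blk.dose(phi)
            ub, cb = blk.u_and_grad_coeff(db)
            if blk.is_vector:
                # vector penalty: mean squared excess over the per-voxel bound
                ex = np.maximum(0.0, ub - blk.bound)
                val += w * float(np.mean(ex**2))
                grad += blk.A.T @ ((2.0 * w / blk.n) * ex * cb)
            else:
                # pure weighted penalty: the isoconstraint no longer gates it
                val += w * ub
                grad += w * (blk.A.T @ cb)
        return val, grad


# ---------------------------------------------------------------------------
# augmented-Lagrangian solver
# ---------------------------------------------------------------------------

def initial_weights(case: Case, matrix: BeamletMatrix) -> np.ndarray:
    """Deterministic start: uniform weights scaled so the mean primary-target
    dose equals the prescription."""
    phi = np.ones(matrix.n_beamlets)
    primary = case.primary_target
    rows = np.flatnonzero(primary.mask.ravel())
    mean_dose = float((matrix.matrix[rows, :] @ phi).mean())
    if mean_dose <= 0:
        return phi
    return phi * (primary.prescribed_dose / mean_dose)


def active_cost_functions(template: Template, case: Case, step: int) -> list[CostFunction]:
    """Cost functions imposed at a given modifier step: targets only in step 1,
    plus unspecified-tissue / body functions in step 2, everything in step 3."""
    out = []
    for cf in template.cost_functions:
        fam = _family(cf, case)
        if fam == "target" or (fam == "body" and step >= 2) or (fam == "oar" and step >= 3):
            out.append(cf)
    return out


def _family(cf: CostFunction, case: Case) -> str:
    if cf.structure == "unspecified_tissue" or (
        case.has_structure(cf.structure) and case.structure(cf.structure).kind == "body"
    ):
        return "body"
    if case.has_structure(cf.structure) and case.structure(cf.structure).kind == "target":
        return "target"
    return "oar"


def solve_fmo(
    case: Case,
    matrix: BeamletMatrix,
    template: Template,
    config: AutoplanConfig = DEFAULT_CONFIG,
    cost_functions: list[CostFunction] | None = None,
    trace: list | None = None,
) -> PlanResult:
    """Solve the constrained fluence-map optimization for a template.

    ``cost_functions`` restricts the imposed set (the driver passes the subset
    active at the current modifier step); by default every cost function in
    the template is imposed.  Never raises on non-convergence: the best
    iterate found is returned with ``converged=False`` and a per-constraint
    violation report.
    """
    validate_template(template, case)
    cfs = list(template.cost_functions) if cost_functions is None else list(cost_functions)
    try:
        objective_cf = next(cf for cf in cfs if cf.role == "objective")
    except StopIteration:
        raise ValueError("no objective cost function among the imposed set") from None
    penalty_cfs = [cf for cf in cfs if cf.role == "constraint" and cf.fixed_weight is not None]
    constraint_cfs = [cf for cf in cfs if cf.role == "constraint" and cf.fixed_weight is None]

    A = matrix.matrix
    fobj = _Objective(objective_cf, penalty_cfs, case, A, config)
    blocks = [_Block(cf, case, A, config) for cf in constraint_cfs]
    lams = [np.zeros(b.n) if b.is_vector else 0.0 for b in blocks]
    rho = config.initial_penalty

    phi = initial_weights(case, matrix)
    bounds = [(0.0, None)] * matrix.n_beamlets

    def aug_lagrangian(x):
        val, grad = fobj.value_and_grad(x)
        for b, lam in zip(blocks, lams):
            d = b.dose(x)
            u, coeff = b.u_and_grad_coeff(d)
            m = np.maximum(0.0, lam + rho * (u - b.bound))
            if b.is_vector:
                val += float(np.sum(m**2 - np.asarray(lam) ** 2)) / (2.0 * rho)
                grad += b.A.T @ (m * coeff)
            else:
                val += (m**2 - lam**2) / (2.0 * rho)
                if m > 0:
                    grad += m * (b.A.T @ coeff)
        return val, grad

    def kkt(x, lam_list):
        """(stationarity residual, max violation Gy, complementarity)."""
        fval, grad = fobj.value_and_grad(x)
        gradL = grad.copy()
        viol = 0.0
        compl_res = 0.0
        for b, lam in zip(blocks, lam_list):
            d = b.dose(x)
            u, coeff = b.u_and_grad_coeff(d)
            if b.is_vector:
                gradL += b.A.T @ (np.asarray(lam) * coeff)
                comp = np.abs(np.asarray(lam) * (u - b.bound)) / (1.0 + np.asarray(lam))
                compl_res = max(compl_res, float(comp.max()) if comp.size else 0.0)
            else:
                if lam > 0:
                    gradL += lam * (b.A.T @ coeff)
                compl_res = max(compl_res, abs(lam * (u - b.bound)) / (1.0 + lam))
            viol = max(viol, b.violation_gy(d))
        proj = gradL.copy()
        at_bound = (x <= 1e-10) & (proj > 0)
        proj[at_bound] = 0.0
        denom = 1.0 + float(np.linalg.norm(grad))
        return float(np.linalg.norm(proj)) / denom, viol, compl_res

    best = None  # (is_feasible, key, phi, lams)
    prev_viol = np.inf
    n_outer = 0
    for outer in range(config.max_outer_iterations):
        n_outer = outer + 1
        res = minimize(
            aug_lagrangian,
            phi,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_inner_iterations, "ftol": 1e-14, "gtol": 1e-10},
        )
        phi = np.maximum(res.x, 0.0)

        # multiplier update
        new_lams = []
        max_viol = 0.0
        for b, lam in zip(blocks, lams):
            d = b.dose(phi)
            u, _ = b.u_and_grad_coeff(d)
            new_lams.append(np.maximum(0.0, lam + rho * (u - b.bound)))
            max_viol = max(max_viol, b.violation_gy(d))
        lams = new_lams

        stat, viol, compl_res = kkt(phi, lams)
        fval, _ = fobj.value_and_grad(phi)
        if trace is not None:
            trace.append({"outer": outer, "f": float(fval), "max_violation_gy": viol,
                          "stationarity": stat, "rho": rho})

        feasible = viol <= config.feasibility_tol_gy
        key = (0 if feasible else 1, fval if feasible else viol)
        if best is None or key < best[0]:
            best = (key, phi.copy(), [np.array(l, copy=True) for l in lams])

        if feasible and stat <= config.stationarity_tol:
            break
        if max_viol > 0.25 * prev_viol:
            rho = min(rho * config.penalty_growth, config.penalty_cap)
        prev_viol = max(max_viol, 1e-300)
    else:
        log.warning("FMO iteration budget exhausted; returning best iterate")

    _, phi, lams = best
    stat, viol, compl_res = kkt(phi, lams)
    converged = viol <= config.feasibility_tol_gy and stat <= config.stationarity_tol

    dose = np.asarray(A @ phi).reshape(case.grid_shape)
    records = []
    mults = [b.multiplier_to_dose_space(l) for b, l in zip(blocks, lams)]
    total = sum(mults)
    violations = {}
    for b, m in zip(blocks, mults):
        d = b.dose(phi)
        iso = b.isoeffect(d)
        records.append(
            SensitivityRecord(
                cf_id=b.cf.id,
                isoconstraint=b.cf.isoconstraint,
                isoeffect=iso,
                multiplier=m,
                relative_impact=m / total if total > 0 else 0.0,
            )
        )
        v = b.violation_gy(d)
        if v > config.feasibility_tol_gy:
            violations[b.cf.id] = v
    records.sort(key=lambda r: (-r.relative_impact, r.cf_id))

    return PlanResult(
        weights=phi,
        dose=dose,
        sensitivity=records,
        objective_value=fobj.main.isoeffect(fobj.main.dose(phi)),
        converged=converged,
        kkt_residual=stat,
        feasibility_gy=viol,
        complementarity=compl_res,
        n_outer=n_outer,
        violations=violations,
    )
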