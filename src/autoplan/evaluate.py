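"""Plan evaluation: DVHs, per-item Diff_result indices, and acceptance.

Every dosimetric goal is a prescription item; how well a plan meets it is
condensed into one nonnegative index, Diff_result.  The orientation is
uniform: an item is met exactly when its Diff_result is <= 1, so a spider
chart of all items is acceptable exactly when every spoke lies inside the
unit circle.  Upper-bound items use achieved/limit; lower-bound (coverage)
items use required/achieved, which keeps the met <=> inside-the-unit-circle
reading consistent across item types.

Before evaluation a plan is rescaled so the prescribed dose covers a fixed
fraction (default 95%) of the primary target volume — coverage is normalized
away and the remaining items decide acceptability, mirroring how plans are
normalized for clinical comparison.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cases import Case, Structure
from .config import DEFAULT_CONFIG, AutoplanConfig
from .optimize import PlanResult
from .templates import PrescriptionItem

log = logging.getLogger("autoplan")


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVH:
    """Cumulative dose-volume histogram: volume_percent[i] is the percentage
    of the structure receiving at least edges_gy[i]."""

    edges_gy: np.ndarray
    volume_percent: np.ndarray

    def at(self, dose_gy: float) -> float:
        """V(d): % volume receiving >= dose_gy (exact voxel counting at any
        query dose, not an interpolation)."""
        idx = np.searchsorted(self.edges_gy, dose_gy, side="right") - 1
        idx = max(int(idx), 0)
        return float(self.volume_percent[idx])


def compute_dvh(dose: np.ndarray, mask: np.ndarray, bin_width_gy: float = 0.1) -> DVH:
    """Exact-counting cumulative DVH on a voxel mask."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    if not mask.any():
        raise ValueError("cannot compute a DVH on an empty structure mask")
    d = dose[mask]
    top = float(d.max()) + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    percent = 100.0 * np.mean(d[None, :] >= edges[:, None], axis=1)
    return DVH(edges_gy=edges, volume_percent=percent)


# ---------------------------------------------------------------------------
# Diff_result
# ---------------------------------------------------------------------------

def achieved_value(item: PrescriptionItem, dose: np.ndarray, case: Case) -> float:
    """The plan's value for an item: a %-volume for V_D metrics, Gy for
    D_max / D_mean metrics."""
    mask = case.structure(item.structure).mask
    if not mask.any():
        raise ValueError(f"item {item.id!r}: structure {item.structure!r} is empty")
    d = dose[mask]
    if item.metric in ("V_D_at_least", "V_D_at_most"):
        return float(100.0 * np.mean(d >= item.dose_gy))
    if item.metric == "D_max_at_most":
        return float(d.max())
    return float(d.mean())


@dataclass
class ItemResult:
    item: PrescriptionItem
    achieved: float
    diff_result: float
    capped: bool = False

    @property
    def met(self) -> bool:
        return self.diff_result <= 1.0 + 1e-6


def diff_result(
    item: PrescriptionItem,
    dose: np.ndarray,
    case: Case,
    config: AutoplanConfig = DEFAULT_CONFIG,
) -> ItemResult:
    """Diff_result index for one item; met <=> value <= 1.

    A coverage item with zero achieved volume has an infinite index; it is
    reported capped at ``config.diff_cap`` with a flag.
    """
    achieved = achieved_value(item, dose, case)
    capped = False
    if item.direction == "upper_bound":
        value = achieved / item.threshold
    else:
        if achieved <= 0.0:
            value, capped = config.diff_cap, True
        else:
            value = item.threshold / achieved
            if value > config.diff_cap:
                value, capped = config.diff_cap, True
    return ItemResult(item=item, achieved=achieved, diff_result=value, capped=capped)


# ---------------------------------------------------------------------------
# coverage rescaling
# ---------------------------------------------------------------------------

def rescale_to_coverage(
    result: PlanResult,
    target: Structure,
    coverage_percent: float = 95.0,
) -> tuple[PlanResult, float]:
    """Scale dose and weights by the unique factor making the prescribed dose
    cover exactly ``coverage_percent`` of the target (to within one voxel of
    volume resolution, via the exact dose quantile).

    Returns the rescaled plan and the factor; idempotent.
    """
    if target.prescribed_dose is None:
        raise ValueError(f"structure {target.name!r} has no prescribed dose to rescale to")
    d = result.dose[target.mask]
    if d.size == 0 or float(d.max()) <= 0.0:
        raise ValueError("cannot rescale an all-zero dose distribution")
    n = d.size
    k = int(math.ceil(coverage_percent / 100.0 * n))
    k = min(max(k, 1), n)
    dq = float(np.sort(d)[::-1][k - 1])
    if dq <= 0.0:
        raise ValueError("cannot rescale: the coverage quantile dose is zero")
    s = target.prescribed_dose / dq
    scaled = dataclasses.replace(
        result, weights=result.weights * s, dose=result.dose * s
    )
    return scaled, s


# ---------------------------------------------------------------------------
# the report
# ---------------------------------------------------------------------------

def acceptable_from_diffs(diffs, tolerance: float = 1e-6) -> bool:
    """The acceptance rule: every spoke inside the unit circle."""
    return all(d <= 1.0 + tolerance for d in diffs)


@dataclass
class EvaluationReport:
    items: list[ItemResult]
    acceptable: bool
    rescale_factor: float

    @property
    def max_diff(self) -> float:
        return max(r.diff_result for r in self.items)

    def result(self, item_id: str) -> ItemResult:
        for r in self.items:
            if r.item.id == item_id:
                return r
        raise KeyError(f"no item {item_id!r} in report")

    def diff_map(self) -> dict[str, float]:
        return {r.item.id: r.diff_result for r in self.items}


def evaluate_plan(
    result: PlanResult,
    items: list[PrescriptionItem],
    case: Case,
    config: AutoplanConfig = DEFAULT_CONFIG,
    rescale: bool = True,
) -> tuple[EvaluationReport, PlanResult]:
    """Rescale to the coverage level and score every prescription item.

    The plan is acceptable exactly when every Diff_result is <= 1 (plus a
    float-noise tolerance).  Returns the report and the rescaled plan.
    """
    if not items:
        raise ValueError("cannot evaluate a plan against an empty prescription")
    plan = result
    factor = 1.0
    if rescale:
        plan, factor = rescale_to_coverage(
            result, case.primary_target, config.coverage_percent
        )
    results = [diff_result(it, plan.dose, case, config) for it in items]
    acceptable = acceptable_from_diffs(
        (r.diff_result for r in results), config.diff_tolerance
    )
    return EvaluationReport(items=results, acceptable=acceptable, rescale_factor=factor), plan


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def dvh_to_csv(
    dose: np.ndarray,
    case: Case,
    path: str | Path,
    bin_width_gy: float = 0.1,
) -> None:
    """CSV export: dose_Gy column then one %-volume column per structure."""
    dvhs = {s.name: compute_dvh(dose, s.mask, bin_width_gy) for s in case.structures if s.mask.any()}
    top = max(dvh.edges_gy[-1] for dvh in dvhs.values())
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dose_Gy"] + list(dvhs))
        for e in edges:
            writer.writerow(
                [f"{e:.4f}"] + [f"{dvhs[name].at(e):.6f}" for name in dvhs]
            )


def spider_to_csv(report: EvaluationReport, path: str | Path) -> None:
    """Spider-chart data: one row per prescription item."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["item_id", "diff_result"])
        for r in report.items:
            writer.writerow([r.item.id, f"{r.diff_result:.10g}"])


def spider_from_csv(path: str | Path) -> dict[str, float]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return {row["item_id"]: float(row["diff_result"]) for row in reader}


def plot_spider(report: EvaluationReport, path: str | Path) -> None:
    """Optional radar-plot image of the Diff_result spokes and unit circle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [r.item.id for r in report.items]
    values = [min(r.diff_result, 2.0) for r in report.items]
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.plot(np.append(angles, angles[0]), values + [values[0]], "o-")
    ax.plot(np.linspace(0, 2 * np.pi, 200), np.ones(200), "--", color="gray")
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_title("acceptable" if report.acceptable else "not acceptable")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
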