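"""Central configuration for the auto-planning loop.

Every tunable that the rule engine, the optimizer, or the evaluator consults
lives here so a whole run is determined by (case, template, seed, config).
Values can be overridden from a JSON file (see :meth:`AutoplanConfig.from_json`)
or from CLI flags.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger("autoplan")


@dataclass
class AutoplanConfig:
    # --- pencil-beam dose engine ---
    mu_per_cm: float = 0.05          # exponential attenuation coefficient, 1/cm
    sigma_mm: float = 3.0            # Gaussian penumbra width, mm
    beamlet_margin_mm: float = 10.0  # field extent beyond the target projection

    # --- constrained fluence-map optimizer ---
    feasibility_tol_gy: float = 1e-3     # max constraint violation, Gy
    stationarity_tol: float = 1e-4       # relative projected-gradient norm
    complementarity_tol: float = 1e-3    # normalized lambda*(g-c) residual
    max_outer_iterations: int = 60       # augmented-Lagrangian outer loop
    max_inner_iterations: int = 500      # L-BFGS-B iterations per outer step
    initial_penalty: float = 10.0
    penalty_growth: float = 4.0
    penalty_cap: float = 1e9
    serial_eud_k: float = 12.0           # EUD exponent for serial-OAR analogues

    # --- evaluation system ---
    coverage_percent: float = 95.0       # plans rescaled so V_Rx(primary PTV) hits this
    dvh_bin_gy: float = 0.1
    diff_tolerance: float = 1e-6         # acceptance slack on Diff_result <= 1
    diff_cap: float = 100.0              # sentinel cap when a coverage item reads 0%

    # --- rule-based template modifier ---
    step_caps: tuple[int, int, int] = (15, 15, 30)
    high_impact: float = 0.4                     # relative impact above this = "high"
    moderate_band: tuple[float, float] = (0.05, 0.4)
    tighten_floor: float = 0.8                   # per-trial multiplicative tighten bound
    loosen_step: float = 1.15                    # per-trial multiplicative loosen factor
    margin_step_mm: float = 4.0                  # shrink-margin increment (one voxel)
    isoconstraint_floor_factor: float = 0.05     # bound: iso >= factor * initial
    isoconstraint_ceiling_factor: float = 4.0    # bound: iso <= factor * initial
    oscillation_weight_factor: float = 10.0      # fixed_weight = factor * mean active lambda
    body_isodose_levels: tuple[float, float, float] = (0.9, 0.8, 0.7)
    body_max_dose_factor: float = 1.07           # global max dose cap / max prescription

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "AutoplanConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("step_caps", "moderate_band", "body_isodose_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


DEFAULT_CONFIG = AutoplanConfig()
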