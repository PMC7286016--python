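# Methods

## Scope and shape of the system

`autoplan` closes the loop that in clinical practice runs between a planner
and a treatment planning system: *template in → constrained fluence-map
optimization (FMO) → DVH / sensitivity export → template edit → next trial*.
All four stages are in-process here.  The optimizer stands in for a
commercial TPS's Stage-I engine; MLC segmentation, segment-weight
optimization and Monte Carlo dose (a clinical Stage II) are out of scope, as
are DICOM-RT I/O and real patient anatomy.

## Synthetic phantoms

Cases are 2-D axial slices, 64×64 voxels of 4 mm (configurable), with
structures rasterized from analytic ellipses — exactly reproducible from a
seed, which jitters centers and radii by a few millimetres.  Two sites are
generated:

* **Prostate-like**: one PTV (67.5 Gy), a posterior OAR slid along the
  posterior axis until a requested fraction of its volume overlaps the PTV
  (the difficulty knob; the realized fraction is within ~0.01 of the request
  at this grid resolution and never decreases when the request grows), and a
  displaced anterior OAR.
* **Head-and-neck-like SIB**: two or three nested targets at strictly
  decreasing dose levels (66/54 Gy, or 70/60/54 Gy), a small serial-OAR
  analogue (cord stand-in) posterior to the targets with a guaranteed air
  gap, and two lateral parallel-OAR analogues (parotid stand-ins).

Default prescriptions are clinically styled for the phantom geometry
(coverage V_Rx ≥ 95% per target, primary D_max ≤ 110%, cord D_max ≤ 45 Gy,
parotid D_mean ≤ 26 Gy, moderate rectum/bladder volume limits) and were
chosen once so that the goals are *feasible but not trivial* on these
phantoms; they are fixtures of this package, not claims about any clinical
protocol.  What the phantoms do **not** emulate: CT densities and
heterogeneity, 3-D scatter, realistic organ shapes, setup uncertainty.
Passing tests therefore demonstrate the behaviour of the *planning loop*, not
dosimetric realism.

## Dose engine

A beamlet deposition matrix `A` (voxels × beamlets, sparse CSR) is built by
ray-marching each coplanar beam through the body mask: dose per unit weight
decays as `exp(−μ·depth)` with geometric (water-equivalent) depth sampled at
1 mm steps, and the 4 mm top-hat beamlet profile is convolved with a Gaussian
penumbra (an erf-difference in closed form).  Defaults μ = 0.05 cm⁻¹ and
σ = 3 mm give a qualitatively megavoltage-like curve.  Beamlets span the
union-of-targets projection plus a 10 mm margin (fields conformed to the
target); beamlets depositing nothing inside the body are dropped with a
warning.  Dose outside the body is zero.  Seven equispaced beams approximate
an arc delivery with static fields.

## Constrained optimization and sensitivities

Cost functions follow TPS conventions: quadratic overdose / underdose
(isoconstraint = permitted RMS excess in Gy over the structure), maximum
dose, and serial EUD `(mean d^k)^(1/k)` with k = 12 by default.  A *shrink
margin* erodes a function's structure away from all higher-prescription
targets (Euclidean distance transform, voxels strictly within the margin
removed) before evaluation.

The solver is an augmented-Lagrangian method with L-BFGS-B inner iterations
on the nonnegative weights:

* quadratic kinds are kept in smooth squared form `mean(excess²)/s² ≤ (c/s)²`;
* a max-dose function becomes one linear bound per voxel with a multiplier
  each (their sum, divided by the limit, is the function's multiplier);
* serial EUD is kept in power-mean form, normalized to avoid overflow;
* a cost function with `fixed_weight` set leaves the constraint set and is
  added to the objective as a pure weighted penalty.

Multiplier estimates are the standard updates `λ ← max(0, λ + ρ(u − b))`,
with ρ growing by 4× (from 10, capped at 1e9) whenever infeasibility fails
to shrink by 4×.  Before normalization into relative impacts, multipliers
are converted to a common dose-space parameterization dF/dc (per-Gy), so
impacts of different constraint kinds are comparable.  Convergence demands
max constraint violation ≤ 1e−3 Gy and a projected-gradient stationarity
residual ≤ 1e−4 (relative to 1 + ‖∇f‖); the normalized complementarity
residual `|λ(u−b)|/(1+λ)` is reported alongside.  On exhaustion of the
iteration budget the best iterate (feasible with least objective, else least
infeasible) is returned with `converged=False` and a per-constraint
violation report — never an exception.  The solver is deterministic:
uniform initial weights scaled so the mean primary-target dose equals the
prescription, no stochastic restarts.

A note on degeneracy: on these forgiving phantoms the underdose objective is
often *fully* satisfied at the solution, in which case every multiplier is
legitimately zero and relative impacts carry no information.  The rule
engine therefore leans on isoeffects and Diff_results as much as on impacts;
the multiplier pathway is exercised by construction in the test suite with
phantoms whose every beam path crosses an OAR.

## Evaluation

DVHs are exact voxel counts (no interpolation), default bin 0.1 Gy.  Before
scoring, the plan is rescaled so the prescription covers exactly 95% of the
primary target, using the exact sorted-dose quantile (single multiplicative
factor; idempotent; accurate to one voxel of volume).  Each prescription
item yields a `Diff_result`: achieved/limit for upper-bound items and
required/achieved for lower-bound (coverage) items, so *met ⇔ ≤ 1* holds
uniformly and a spider chart's unit circle is the acceptance boundary.  (The
two conventions in circulation — target ratio oriented so "met" means ≥ 1,
versus the unit-circle rule — conflict; the unit-circle semantics win here.)
A coverage item reading 0% has an infinite index; it is capped at 100 and
flagged.  Acceptance tolerance on the ≤ 1 comparison is 1e−6.

## Template modifier

The rule engine runs in three steps with per-step trial caps 15 / 15 / 30
(hard total 60).  All isoconstraint edits are multiplicative, bounded per
trial (tighten ≥ ×0.8, loosen ×1.15), and clamped to
[0.05, 4.0] × the initial value.  When a bound is slack, it is first snapped
down to the achieved isoeffect before the step is applied (a multiplicative
step on a slack bound would be a no-op).  Tie-breaks are deterministic
(highest relative impact, then lexicographic id).

1. **Targets** (multi-target cases only; single-target cases skip without
   consuming a trial).  While target coverage / uniformity items fail, any
   overdose function on a target whose relative impact exceeds 0.4 has its
   shrink margin grown by one voxel (4 mm).  If no such function exists the
   step advances with a warning rather than idling.
2. **Unspecified tissue.**  On entry, a global body max-dose cap
   (1.07 × prescription) and three overdose functions at 0.9/0.8/0.7 × the
   prescription on body-minus-targets (shrink margins 4/8/12 mm, initial RMS
   0.04 × their reference) are installed.  Each trial, shells with relative
   impact above the moderate band [0.05, 0.4] are loosened one step, shells
   below it tightened one step; the step advances when all shells are
   in-band, when an adjustment round changes nothing (stalemate — a repeat
   trial would be identical), or at the cap.
3. **OARs.**  All constraints now active.  Per trial: (a) every failing item
   tightens its driving constraint by `max(0.8, min(1/Diff, 0.99))` — the
   0.99 cap guarantees a ≥ 1% step for barely-failing items; the primary
   coverage item is driven by the objective and exempt; (b) if target
   coverage fails while some OAR items are met, the met-OAR constraint with
   the highest (positive) relative impact is loosened one step; (c) an OAR
   item whose `Diff − 1` changed sign in ≥ 3 consecutive trial pairs gets
   its constraint promoted to a fixed-weight objective penalty (weight
   10 × the mean active multiplier, floored at 10 so the penalty is never
   vacuous).  The loop ends on acceptance, at the cap, or when the engine
   reaches a fixed point (identical next template) — the best trial
   (minimum over trials of the maximum Diff_result) is then reported.

Coverage-driving underdose functions reference 1.05 × the goal dose: with
the reference at the goal itself, many voxels settle *just* below it at
essentially zero RMS cost and defeat the V_D count.

## Driver, logging, determinism

Each trial appends one JSON line (template, objective, convergence and KKT
diagnostics, per-constraint sensitivity, per-item Diff_results, the
per-iteration solver trace, wall time) to `trials.jsonl`, flushed
immediately, so a partial log is always parseable.  `(case, template, seed,
config)` fully determines the numeric content of a run; wall-time fields are
the only nondeterministic entries.  `replay_trial` re-solves any logged
trial against the case (hash-checked) and verifies the stored Diff_results
to 1e−6.

## Problem sizes and runtime

The shipped configuration — 64×64 grid, 7 beams, ~120 beamlets — solves one
FMO in well under a second and a full SIB case in a few seconds; the
five-case batch in `scripts/acceptance.py` completes in a few minutes on one
CPU.  On this batch every case reaches an acceptable plan within 10–21
step-3 trials (23–32 trials in total), and the easy prostate configuration
(zero overlap) is acceptable at the first trial.

## Known limitations

* 2-D phantoms and a water-equivalent pencil beam: absolute dose values are
  illustrative only.
* The moderate-impact band of step 2 is often unattainable as stated
  (relative impacts concentrate on a single active constraint), so the
  stalemate exit does much of the work; the band bounds are config values.
* Oscillation handling covers OAR items only; an oscillating target item
  would have to be resolved by the coverage-rescue rule.
* The serial-EUD kind is available but the default prescriptions drive
  serial OARs through max-dose constraints; EUD paths are covered by unit
  tests rather than the end-to-end fixtures.
* Feasibility of the default prescriptions is a property of these phantoms;
  a user-supplied infeasible prescription ends in a best-effort verdict with
  the best trial returned, not an error.
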