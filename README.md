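# autoplan

Rule-based auto-planning for intensity-modulated radiotherapy, self-contained
at desk scale.  The package emulates the workflow in which a treatment
planning system's constrained fluence-map optimizer (FMO) is driven to a
clinically acceptable plan not by a human planner but by a rule engine that
reads the plan evaluation and the optimizer's own sensitivity data, edits the
plan *template* (the full optimization specification), and launches the next
trial — repeating until every prescription item is met.

It is aimed at medical-physics researchers who want to study protocol-based
automatic iterative optimization — step-size rules, constraint scheduling,
oscillation handling — without a commercial TPS in the loop: the optimizer,
the phantoms and the evaluation system are all included and fully
reproducible.

## The model

Dose is linear in the nonnegative beamlet weights, `D(φ) = A φ`, with `A` a
pencil-beam deposition matrix (exponential depth attenuation, Gaussian
penumbra) on a 2-D voxel phantom.  One planning trial solves the constrained
problem

```
minimize    f(φ)                  (target underdose objective)
subject to  g_i(φ) ≤ c_i          (quadratic overdose / max-dose / serial-EUD
            φ ≥ 0                  constraint cost functions at their
                                   isoconstraints c_i)
```

At the optimum, `∇f = −Σ_i λ_i ∇g_i`: the Lagrange multipliers λ_i measure
how strongly each constraint limits target coverage.  The solver (an
augmented-Lagrangian method) reports, per constraint, the isoconstraint c_i,
the achieved isoeffect g_i, the multiplier λ_i, and the *relative impact*
λ_i / Σ_j λ_j.

Each plan is rescaled so the prescription dose covers 95% of the primary
target, then scored: every dosimetric goal (prescription item) becomes a
`Diff_result` index oriented so that *met ⇔ Diff_result ≤ 1*; a plan is
acceptable exactly when all items are met (all spider-chart spokes inside
the unit circle).

The template modifier then applies a three-step divide-and-conquer rule set —
(1) inter-target dose gradients via shrink margins, (2) conformity via
overdose constraints on the 90/80/70% isodose shells in unspecified normal
tissue tuned to moderate impact, (3) adaptive OAR constraint tightening with
coverage rescue and a fixed-weight priority override for oscillating goals —
with per-step trial caps of 15, 15 and 30.

## Worked example

A head-and-neck-like phantom with a simultaneous-integrated boost (66 Gy
boost nested in a 54 Gy elective volume, a cord analogue at D_max ≤ 45 Gy and
two parotid analogues at D_mean ≤ 26 Gy):

```
$ autoplan make-case --site hn --seed 1 --out case.json
wrote hn case (6 structures) to case.json
$ autoplan init-template --case case.json --out template.json
wrote template (7 cost functions, 6 items) to template.json
$ autoplan run --case case.json --template template.json --out run/ --seed 1
acceptable after 24 trials (best trial 24)
$ autoplan evaluate --case case.json --template run/template_trial_24.json
ptv_boost_coverage       achieved   96.610  diff  0.983  met
ptv_elective_coverage    achieved   96.804  diff  0.981  met
ptv_boost_max            achieved   70.430  diff  0.970  met
cord_max                 achieved   41.150  diff  0.914  met
parotid_l_mean           achieved   25.932  diff  0.997  met
parotid_r_mean           achieved   25.989  diff  1.000  met
acceptable
```

Reading: after 24 automatic trials every Diff_result is ≤ 1 — e.g. 96.6% of
the boost receives 66 Gy against the 95% requirement (diff = 95/96.6 = 0.983),
and the parotid mean doses sit just inside their 26 Gy limits (diff ≈ 1.0,
the rule engine stops tightening once a goal is met).  `run/` holds the
per-trial templates, `trials.jsonl` (isoconstraints, isoeffects, multipliers,
relative impacts and Diff_results for every trial), and the final DVH and
spider-chart CSVs.  `autoplan replay --log run/trials.jsonl --trial K`
re-solves any logged trial and verifies it reproduces the log.

The same works for the prostate-like site (`--site prostate`), where the
difficulty knob is the PTV–OAR overlap fraction: with no overlap the loop
finishes in a single trial.

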