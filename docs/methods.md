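# Methods

## The clinical decision problem

A patient with atrial fibrillation (AF) who receives a coronary stent for
an acute coronary syndrome (ACS) faces three competing 30-day risks:
cardioembolic stroke (mitigated by oral anticoagulation, OAC), coronary
events — above all early stent thrombosis — (mitigated by potent dual
antiplatelet therapy, DAPT), and bleeding (aggravated by combining the
two). The candidate regimens are triple therapy (TAT: OAC + aspirin +
P2Y12 inhibitor), dual therapy (DAT: OAC + one P2Y12 inhibitor, by
guideline a clopidogrel-based one), and modern DAPT (aspirin + ticagrelor
or prasugrel, deferring OAC for the first month).

The package quantifies this trade-off as numbers needed to treat for
benefit (NNTB) per endpoint across the CHA2DS2-VASc spectrum, plus an
indirect bleeding hazard-ratio network, and validates the arithmetic with
a Monte Carlo cohort simulator.

## Stroke arm

For a CHA2DS2-VASc score *s* with annual stroke/systemic-embolism rate
*a(s)* per 100 patient-years (non-anticoagulated AF patients):

```
monthly untreated risk  u(s) = a(s) / 12 × m        (per 100 patients)
risk on OAC                  = u(s) × (1 − 0.64)
risk on aspirin+clopidogrel  = u(s) × 0.36 × 1.72
stroke NNTB(s)               = floor( 100 / |ARR| )
```

* `a(2) = 3.7`, `a(3) = 5.9` are the two directly supported rates; the
  remaining scores in `StrokeRiskTable.extended()` come from the Danish
  nationwide AF cohort (Olesen et al., BMJ 2011), whose score-2/3 values
  (3.71/5.92) match the core table and whose score-4 value (9.27/100)
  reproduces the third reported monthly risk of 0.8/100. These extension
  entries are clearly marked in `data/defaults.yaml`; conclusions at
  scores ≥ 4 inherit their (registry-based, not trial-based) provenance.
* `m = 3.9` is the early post-ACS excess in stroke hazard. Whether it is
  uniform across scores is uncertain; it is a config parameter, applied
  uniformly by default.
* 0.64 is the relative risk reduction of full anticoagulation versus no
  antithrombotic therapy; 1.72 the risk ratio of aspirin+clopidogrel
  DAPT versus full OAC. The 72% excess is interpreted *relative to OAC*,
  not to no therapy — the only reading that reproduces NNTB 320 (score 2)
  and 201 (score 3).
* Annual→monthly conversion is plain division by 12, not compound
  `1−(1−p)^(1/12)`; "one month" and "30 days" are the same horizon. Both
  are conventions of the source arithmetic, kept deliberately.

## Coronary arm and calibration

The 30-day coronary event risk under the clopidogrel-DAPT reference,
*r(s)* per 100 patients, is not directly published. It is recovered by
inverting published 30-day NNTBs of switching clopidogrel for a modern
P2Y12 inhibitor with first-month relative risk reduction RRR (0.12 for
ticagrelor, 0.22 for prasugrel):

```
NNTB = 1 / (r × RRR)   ⇒   r(s) = 100 / (NNTB(s) × RRR)   per 100
```

The bundled table is calibrated from the ticagrelor anchors NNTB(1)=179,
NNTB(3)=140, NNTB(9)=105, with piecewise-linear interpolation in score
between anchors. Design notes:

* The score-3 anchor matters: interpolating straight from score 1 to 9
  puts r(3) ≈ 5.48 and the ticagrelor NNTB at ≈ 152, inconsistent with
  the published score-3 values (140 and 77). With the three-anchor
  table, r(3) = 5.95 and both score-3 NNTBs fall within ±5 of the
  published figures (140 exactly; prasugrel 76 vs 77).
* The prasugrel-implied rates (from NNTB 97 and 57) agree with the
  ticagrelor-implied ones within 1% at both end scores — an independent
  cross-check, asserted at 2% tolerance in the tests. Under floor
  rounding the single ticagrelor-calibrated table reproduces all four
  published anchor NNTBs (179, 105, 97, 57).
* Complex PCI (≥ 3 high-risk procedural features) multiplies the 30-day
  coronary probability by 3.4 — the early stent-thrombosis hazard ratio
  applied as a risk ratio, which is exactly what yields the published
  "70% further reduction" in coronary NNTBs (1 − 1/3.4 = 70.6%).
* All effect composition is multiplicative on the probability scale,
  i.e. HR ≈ RR in the small-probability regime (monthly risks of order
  1/100). This is the model's central approximation.

## NNTB conventions

`nntb = floor(100 / |ARR|)` — the only rounding consistent with both
reference values (320.83 → 320, 201.20 → 201). Unrounded values are kept
on every result. Equal risks return an explicit infinite sentinel. To
keep the floor robust against float round-off (an exactly recoverable
integer NNTB such as 105 can compute as 104.999…99), the unrounded value
is rounded at the 9th decimal before flooring.

**Equipoise** is the smallest score at which the stroke NNTB of adding
OAC drops to or below the coronary NNTB of modern DAPT, decided on
unrounded values (ties count as crossed; the source states crossing
scores without a tie rule). Under the bundled tables the crossing is at
score 4 for ticagrelor (matching the published figure) and score 6 for
prasugrel (published: 5). The prasugrel discrepancy traces to the
unpublished interior coronary rates: with registry stroke rates the
score-5 stroke NNTB is 77.8 versus a prasugrel coronary NNTB of 68.7 —
close, and sensitive to interpolation details we cannot recover. The
tests therefore assert the crossing region (4 ± 1 and 5 ± 1), not strict
equality. Under complex PCI no crossing exists: DAPT is favored at every
score.

## Bleeding network

Direct early-bleeding comparisons, one per study, form a tree:

| from | to | HR | source |
|---|---|---|---|
| TAT-warfarin | DAPT-clopidogrel | 2.2 | Danish nationwide registry (adjusted) |
| DAT-dabigatran-110 | TAT-warfarin | 0.52 | RE-DUAL PCI |
| DAT-dabigatran-150 | TAT-warfarin | 0.72 | RE-DUAL PCI |
| DAT-rivaroxaban-15 | TAT-warfarin | 0.59 | PIONEER AF-PCI |
| DAT-apixaban-5-bid | TAT-warfarin | 0.39 | AUGUSTUS |
| DAPT-ticagrelor | DAPT-clopidogrel | 1.05 | PLATO |
| DAPT-prasugrel | DAPT-clopidogrel | 1.31 | TRITON-TIMI 38 |

Indirect HRs are Bucher-style products of point estimates along the
connecting path, computed in log space (reverse edges contribute −log hr,
so reversing a path gives the exact reciprocal). Because the graph is a
tree, every indirect HR is path-unique; on cyclic user-supplied graphs,
shortest paths disagreeing by more than 1% trigger a consistency
warning. Reported values round half-up to 2 decimals; unrounded values
are always exposed. No uncertainty propagation is attempted — the
analysis composes point estimates only (the edge schema accepts a
standard-error column as a documented stub). The edoxaban-based DAT is a
node with a qualitative flag only: its trial supports a directional
claim (more early bleeding than DAPT) but no composable estimate.

This composition reproduces the six published indirect estimates:
dabigatran-150 DAT vs ticagrelor-/prasugrel-DAPT 1.51/1.21,
rivaroxaban-15 DAT vs ticagrelor-DAPT 1.24, apixaban DAT vs
clopidogrel-/ticagrelor-/prasugrel-DAPT 0.86/0.82/0.65.

## Sample size

For the motivating design (stent-thrombosis rate 0.7%/year in controls,
+55% relative increase, two-sided α = 0.05, power 0.90, 1-year horizon)
two standard answers are computed, framing the published "at least
10,500 per arm" as a lower bound both satisfy:

* unpooled two-proportion normal approximation:
  `n = (z_{α/2}+z_β)² [p₁(1−p₁)+p₂(1−p₂)] / (p₂−p₁)²` → 12,536/arm
  (Fleiss continuity correction available behind a flag, off by default);
* Schoenfeld events-required: `d = 4(z_{α/2}+z_β)²/(ln HR)²` ≈ 219
  events, converted via the expected event yield per patient → 12,260/arm.

The two agree within 2.3% here (rare-event regime); the tests assert
10% agreement and monotonicity in effect size, base rate and power.

## Monte Carlo cohort simulator

The simulator is the stochastic oracle for the analytic pipeline: for a
two-arm scenario (score, regimens, PCI complexity) it draws per-arm
30-day event counts as binomial variates with the risk engine's
probabilities — exactly the distribution of independent per-patient
Bernoulli draws, without materialising patient arrays at n = 10⁶–10⁷.
One `numpy` `default_rng(seed)` per simulation; no global state; the
seed and n are embedded in every result. Empirical NNTBs carry a
delta-method standard error, `SE(100/ARR) = 100·SE(ARR)/ARR²`.

What the simulator does *not* emulate — and hence what passing recovery
tests do not show about real cohorts: within-month event timing,
competing risks (a fatal bleed precluding a stroke), correlation between
endpoints, covariates beyond score and complexity, and any deviation of
true risks from the multiplicative model. Endpoints are drawn
independently by design, matching the additive treatment of endpoint
families in the analytic model.

Test problem sizes: recovery tests run at n = 10⁶ per arm (3-binomial-SE
criterion, fixed seeds), the empirical-NNTB bracket at n = 10⁷, the
convergence check averages five seed replicates at n = 10⁴ vs 10⁶; the
full suite completes in a few seconds.

## Degenerate inputs and numerical choices

* Probabilities are capped at 100/100 with a logged warning, never
  silently.
* Missing table scores raise, never extrapolate.
* Broken effect chains and broken graph paths raise errors naming both
  regimens involved.
* Scenario validation is fail-fast and exhaustive (all missing keys
  reported at once); no partial outputs are written.
* Rounding happens only at the reporting layer; computation carries full
  precision.
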