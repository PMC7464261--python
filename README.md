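# afacs — antithrombotic trade-offs in AF patients early after an ACS

`afacs` is a decision-analytic toolkit for the first 30 days after an
acute coronary syndrome (ACS) in patients with atrial fibrillation (AF) —
the window in which triple therapy (TAT: anticoagulant + aspirin + P2Y12
inhibitor), anticoagulant-based dual therapy (DAT) and modern dual
antiplatelet therapy (DAPT: aspirin + ticagrelor or prasugrel) trade
cardioembolic protection against coronary protection and bleeding. It is
aimed at clinical researchers and biostatisticians who want the
risk-benefit arithmetic behind regimen choice to be explicit,
reproducible and stress-testable.

The core quantities:

* **Stroke NNTB.** For CHA2DS2-VASc score *s* with annual stroke rate
  *a(s)* per 100 patient-years, the monthly post-ACS untreated risk is
  `u = a/12 × 3.9`; the 30-day number needed to treat with OAC on top of
  aspirin+clopidogrel DAPT is `floor(100 / (u·0.36·1.72 − u·0.36))`
  (0.64 = RRR of full anticoagulation; 1.72 = DAPT-vs-OAC risk ratio).
* **Coronary NNTB.** The 30-day coronary risk under clopidogrel DAPT,
  *r(s)*, is calibrated by inverting published NNTBs
  (`r = 100/(NNTB·RRR)`, RRR 0.12 ticagrelor / 0.22 prasugrel) and
  scaled ×3.4 for complex PCI (≥ 3 high-risk procedural features).
* **Equipoise.** The smallest score where the stroke NNTB falls to or
  below the coronary NNTB — below it, withholding OAC for one month in
  favor of modern DAPT prevents the cheaper event.
* **Bleeding network.** Indirect hazard ratios between regimens never
  compared head-to-head, as Bucher-style products of per-study direct
  HRs along a comparison tree anchored at warfarin-TAT vs
  clopidogrel-DAPT (HR 2.2).
* **Sample size** for a rare-event superiority trial (two-proportion and
  Schoenfeld events-required formulas), and a seeded **Monte Carlo
  cohort simulator** that recovers every analytic risk empirically.

## Worked example

```
$ afacs figure4
 score  stroke_nntb  coronary_nntb_ticagrelor  coronary_nntb_prasugrel  ...
     2          320                       157                       85
     3          201                       140                       76
     4          128                       132                       72
     5           77                       126                       68
     ...
equipoise: {'ticagrelor': 4, 'prasugrel': 6, 'ticagrelor_complex': None, 'prasugrel_complex': None}
```

At score 2, treating 320 patients for a month with OAC on top of DAPT
prevents one stroke, while 157 patients on clopidogrel instead of
ticagrelor suffer one extra coronary event — the coronary event is the
cheaper one to prevent, favoring modern DAPT. The curves cross at score
4 (ticagrelor): from there upward, anticoagulation's stroke benefit is
at least as cheap. Under complex PCI the coronary columns drop ~3.4-fold
and no crossing exists. The score-3 walkthrough behind the motivating
case:

```
$ afacs vignette
   stroke NNTB, OAC added vs aspirin+clopidogrel DAPT    201
coronary NNTB, ticagrelor-DAPT vs clopidogrel regimen    140
 coronary NNTB, prasugrel-DAPT vs clopidogrel regimen     76
   bleeding HR, rivaroxaban-15 DAT vs ticagrelor-DAPT   1.24
```

— a clopidogrel-based DAT averts one stroke per 201 patient-months but
costs one coronary event per 140 (vs ticagrelor) or 76 (vs prasugrel)
patient-months, with 24% more bleeding than ticagrelor-DAPT. The same
library calls are available in Python:

```python
from afacs import stroke_nntb_oac_vs_dapt, default_graph, round_half_up

stroke_nntb_oac_vs_dapt(3).nntb                                  # 201
g = default_graph()
round_half_up(g.indirect_hr("DAT-dabigatran-150", "DAPT-ticagrelor"))  # 1.51
```

Other subcommands: `afacs figure5` (full indirect bleeding-HR matrix,
`--edges` to supply your own comparison list), `afacs samplesize`
(default design → 12,536/arm two-proportion, 12,260/arm event-driven),
`afacs simulate` (seeded cohort simulation with empirical NNTBs). All
model inputs live in a plain YAML scenario (`--config`); the bundled
defaults are in `src/afacs/data/`. See `docs/methods.md` for the model,
its assumptions and its limitations.

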