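# Methods

This note documents the model implemented in `ieev_cea`: its structure,
assumptions, parameter conventions, numerical choices, and what the
synthetic inputs do and do not establish.

## Decision tree

The intervention arm classifies every patient with the monitor
(sensitivity *Se*, specificity *Sp*) against the true IEEV prevalence π and
treats on every alarm, with success probability *e*. Leaf probabilities are
the plain products (π·Se·e, π·Se·(1−e), π·(1−Se), (1−π)·(1−Sp), (1−π)·Sp).
Three behavioural assumptions close the tree:

* a **successful treatment** moves the patient onto the without-IEEV outcome
  profile — justified by events being detectable within 3 minutes against a
  median event duration of ~21 minutes, leaving time to intervene;
* an **unsuccessful treatment** leaves the full with-IEEV profile (no harm,
  no benefit), and **missed events** are indistinguishable from untreated
  events;
* **false positives** incur the treatment cost but no outcome change —
  treatments are low-risk ventilator/sedation adjustments, and side effects
  are out of scope.

Treatment happens once, on the first ICU day. Consequently the analytics
arm's with-IEEV mixture weight is π − π·Se·e, and every short-term
incremental outcome has a closed form, e.g. ΔLOS = −π·Se·e·(LOS_w − LOS_wo).
These closed forms are used as test oracles against brute-force leaf
enumeration.

## Markov cohort model

Four states: ICU → ward → discharged → dead, no ICU readmission (none
occurred in the source cohort). Cycle lengths:

1. **ICU cycle** — the arm's expected ICU stay (days/365). Everyone accrues
   ICU utility (0.297) for the full observed length; ICU non-survivors move
   to dead at cycle end.
2. **Ward cycle** — the post-ICU hospital stay (17.3 d). Ward occupants
   accrue ward utility (0.60); discharge probability is the mixture hospital
   survival divided by the mixture ICU survival.
3. **Annual cycles** — survivors face the life-table hazard times the
   post-discharge hazard ratio (2.01): per-cycle death probability
   1 − exp(−hr·h(a)). Utilities by years since discharge: 0.67 (year 1),
   0.70 (years 2–10), 0.68 (after 10).

The **half-cycle correction** is applied to the annual cycles (life-years
and QALYs use the mean of start- and end-of-cycle alive fractions, with a
mid-cycle discount exponent). The two in-hospital cycles deliberately use
full-length accrual with end-of-cycle transitions: their lengths are
directly observed cohort medians, so there is no within-cycle timing
uncertainty to correct, and this choice makes the model's short-stay cells
exactly equal the decision-tree mixture averages. One visible consequence:
in the limit of an enormous hazard ratio the post-discharge cohort still
accrues half a year of life (they die mid-cycle on average).

In-hospital QALY accrual applies to all occupants, including those who die
at cycle end, because the stay inputs are cohort medians, not
survivor-specific stays. Discounting (3.5 %/yr for costs and health,
separately configurable) starts at admission; the in-hospital period
contributes only ~0.1 years of discount time.

## Life table

The general-population baseline is a **synthetic Gompertz stand-in**:
h(a) = α·e^{b·a} with slope b = 0.085/yr, terminal age 110 (q = 1), and α
solved by Brent's method so that period life expectancy at birth equals
81.0 years — a typical Southern-European value. Any (age, q) CSV can be
substituted. Age at admission defaults to 62, a representative
mixed-ICU mean; the original cohort's mean age is unpublished, so lifetime
absolute results (LY/QALY levels per arm) are *calibration-dependent*: the
package treats them as plausibility bands (base-case ΔQ ∈ [0.15, 0.27],
ΔLY ∈ [0.22, 0.40]) rather than reproduction targets. With the defaults the
model lands at ΔQ ≈ 0.213 and ΔLY ≈ 0.308.

## Costing conventions

The source analysis under-specifies two accounting rules; both were fixed
by requiring the worst-case incremental cost to reconstruct exactly:

* **licence apportionment**: price × expected ventilated days / 365
  (worst case: 20000·15.6/365 = €854.79);
* **treatment costing**: once per alarm, true *and* false positives
  (worst case: 155·0.259 = €40.15; together €894.94 ≈ the published €895).

Other conventions: ventilated ICU days at the full daily cost, weaned days
reduced by 10 %; ward costs only for ICU survivors (extra survivors under
the analytics arm *do* incur extra ward costs, ~€62 per base-case patient
against the ICU savings); the discharged state is cost-free; in-hospital
costs are not half-cycle corrected. Under these conventions the base-case
incremental cost computes to −€229 and the break-even price to €6,932,
inside the documented tolerance bands of the published −€246/−€264 and
€7,307 (the publication itself prints two different base-case figures).

Because ΔC is affine in the licence price with slope MV/365, the break-even
price is computed in closed form and self-checked by re-evaluation
(|ΔC| < €0.01 at the root). Headroom N + λ·Q is exact arithmetic on the
price-zero evaluation; per-bed conversion multiplies by 365/device-days
(default 17 days of device use per patient).

## One-way sensitivity

The tornado varies every parameter with a low/high range (including the
discount rates and the 0–0.5 effectiveness range), one at a time. When a
bound would cross a cross-field invariant (e.g. without-IEEV hospital
survival 0.77 vs ICU survival 0.75) the value is clipped to the boundary
and a warning logged, keeping the analysis strictly one-way. With these
ranges the widest incremental-cost bars are the licence price, the two
ICU-stay lengths, effectiveness, the ICU day cost and prevalence; the
stay-length bars are as wide as the cost/prevalence bars, so the analysis
reports the full ordering rather than a fixed top four.

## Probabilistic sensitivity analysis

Fitting from (base, low, high): beta and gamma by method of moments with
mean = base and sd = (high − low)/3.92 (range read as a central 95 %
interval); the hazard ratio as a normal truncated below 0; rows marked
beta-PERT use (low, base, high) as (min, mode, max) with shape constant 4 —
their sampled mean (min + 4·mode + max)/6 therefore differs from the base
value (prior: 0.353 vs 0.38). The licence price, treatment effectiveness
and discount rates are never sampled; effectiveness is instead fixed per
run at 10/30/50 %.

Draws are independent across parameters. Cross-field invariants are
enforced by resampling the offending pair; for the without-IEEV survival
pair this affects ~15 % of draws (the two fitted distributions overlap),
which is an unavoidable consequence of independent sampling from the
published marginals — counts are logged, and the resulting truncation does
not touch the cost side of the model. Draw *j* seeds its own generator from
(seed, j), so a 1,000-draw run is a prefix of the 10,000-draw run with the
same seed. The test suite and the acceptance script use 1,000 draws per
effectiveness level (a few seconds on one CPU; Monte-Carlo error on the
CEAC probability at that size is ≈ 0.7 percentage points, far from the 90 %
decision boundary); the CLI default is 10,000.

## Synthetic cohort generator

`generate_cohort` emulates the *structure* of the source hospital data
(110 ventilated patients, 38 % IEEV prevalence): a Bernoulli event flag;
per group, gamma-distributed ICU stay with median at the model input and a
coefficient-of-variation knob (default 0.35 — the source publishes only
centres and ranges, so dispersion is a generator choice, not a data claim);
ventilated days clipped to the stay, with the gamma scale calibrated so the
*post-clipping* median equals the requested centre; Bernoulli ICU survival
and conditional hospital survival. It does not emulate IEEV timing within
the stay, repeated events, or any correlation between stay length and
survival — so parameter-recovery tests establish that the estimation
pipeline is unbiased for this structure, not that the model fits any
particular hospital.

`estimate_parameters` returns proportions with exact Clopper–Pearson 95 %
intervals and group medians with seeded percentile-bootstrap intervals
(500 resamples by default). Recovery tests at n = 5,000 require ≥ 90 %
coverage of the generating values over 100 replicates.

## Known limitations

* Alert fatigue, treatment side effects, ICU readmission and repeated
  events per stay are excluded by design.
* Absolute lifetime cells depend on the life-table stand-in and admission
  age; only incremental bands are asserted.
* PSA draws are independent across parameters; any real correlation between
  stay, ventilation time and survival is not represented.
* The per-bed headroom conversion uses exactly 17 device-days; the
  published per-bed figures imply ≈ 17.3, a ~1.6 % gap the package does not
  attempt to resolve.
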