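# ieev-cea

Early cost-effectiveness analysis of real-time analytics that detect
**ineffective effort events (IEEVs)** in mechanically ventilated ICU
patients.

An IEEV is a burst of patient–ventilator asynchrony (> 30 ineffective
inspiratory efforts within 3 minutes) associated with higher hospital
mortality, longer ICU stay and longer time on ventilation. Real-time
analytics of ventilator waveforms could alert clinicians to intervene
(adjust ventilator settings, sedation or bronchodilation) while the event is
still running. This package implements the decision-analytic model used to
ask, *before* such analytics exist in practice: what would they be worth —
in deaths averted, QALYs gained and euros saved — and what is the maximum
defensible licence price?

It is written for health-economics researchers and developers of ICU
analytics who want a reproducible, testable version of the analysis rather
than a spreadsheet.

## Model

Two strategies are compared for a cohort entering the ICU on assisted
ventilation:

* **current care** — IEEVs go undetected and untreated; a fraction π
  (prevalence, base case 0.38) carries the worse *with-IEEV* outcome profile;
* **analytics** — a monitor with sensitivity *Se* and specificity *Sp*
  raises an alarm; every alarm triggers a treatment that succeeds with
  probability *e*, moving the patient onto the *without-IEEV* profile.

The decision tree gives the intervention arm's leaf probabilities
(π·Se·e successes, π·Se·(1−e) failed treatments, π·(1−Se) missed events,
(1−π)·(1−Sp) false alarms, (1−π)·Sp true negatives). Short-term outcomes
are mixture averages of the two profiles (ICU LOS, ventilated days, ICU and
hospital survival).

Long-term outcomes come from a four-state Markov cohort model
**ICU → ward → discharged → dead**: one cycle at the expected ICU stay, one
at the post-ICU ward stay, then annual cycles in which survivors face the
general-population hazard from a life table scaled by a post-discharge
hazard ratio (2.01), with a half-cycle correction, utility weights by
location and years since discharge, and 3.5 %/yr discounting of costs and
health.

Costing: full ICU day price while ventilated, 10 % cheaper when weaned;
ward days for ICU survivors; the annual per-bed licence apportioned to a
patient by expected ventilated days (price·MV/365); treatment charged once
per alarm. Outputs are incremental cost ΔC, QALYs ΔQ, the ICER or a
dominance verdict, net monetary benefit λ·ΔQ − ΔC, the break-even licence
price, and the headroom **N + λ·Q** (N = savings at price zero).

Because the national life table and cohort mean age behind the original
analysis are not published, the package ships a synthetic Gompertz life
table calibrated to life expectancy 81.0 (slope 0.085/yr) and defaults to
admission age 62; lifetime absolute results are therefore close to, but not
exact reproductions of, the published table. A synthetic patient-level
cohort generator with matching structure supports end-to-end
data → parameters → model runs.

## Worked example

```python
from ieev_cea import CostEffectivenessModel

model = CostEffectivenessModel.from_defaults()
print(model.fit().summary())
print(f"break-even licence price: {model.break_even_price():,.0f} EUR/bed/yr")
```

prints

```
Cost-effectiveness results — scenario: base
====================================================================
                        Current care  With analytics  Incremental
Total cost (EUR)              19,799          19,570         -229
ICU length of stay (d)         24.28           23.68        -0.60
Days on ventilation            17.28           16.68        -0.60
Hospital mortality              0.43            0.40        -0.03
Life years (disc.)              6.86            7.17         0.31
QALYs (disc.)                   4.70            4.92         0.21
--------------------------------------------------------------------
ICER: analytics arm is dominant
break-even licence price: 6,932 EUR/bed/yr
```

Read: at the base case (30 % treatment effectiveness, €1,918/bed/yr
licence) the analytics shorten the average ICU stay by 0.6 days, cut
hospital mortality by 3 percentage points, add 0.21 discounted QALYs and
save €229 per patient — the strategy *dominates* current care. Savings
persist until the licence price exceeds ≈ €6.9k per bed-year.

Scenario presets (`model.fit("worst")`, `"best"`, `"high_icu_cost"`),
tornado diagrams, price sweeps, headroom and the probabilistic sensitivity
analysis (`model.run_psa`, `ieev_cea.psa.ceac`) hang off the same objects,
and the `ieev-cea` command line mirrors them (`run`, `tornado`, `sweep`,
`breakeven`, `headroom`, `psa`, `simulate-cohort`, `estimate`).

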