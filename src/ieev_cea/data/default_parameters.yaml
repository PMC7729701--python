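# Base-case inputs of the ineffective-effort-event cost-effectiveness model.
# Probability-like rows are written as fractions (units: fraction); write
# "units: percent" to supply them as percentages instead.
# Each row: base / low / high (deterministic range) / family (PSA distribution;
# "fixed" rows are not sampled).
units: fraction

# diagnostic performance of the prototype ineffective-effort monitor
sens: {base: 0.88, low: 0.79, high: 0.94, family: beta}
spec: {base: 0.99, low: 0.80, high: 1.00, family: beta_pert}

# epidemiology and treatment
prior: {base: 0.38, low: 0.10, high: 0.50, family: beta_pert}
eff: {base: 0.30, low: 0.00, high: 0.50, family: fixed}

# survival by ineffective-effort-event status
surv_icu_ieev: {base: 0.63, low: 0.48, high: 0.77, family: beta}
surv_icu_no: {base: 0.75, low: 0.63, high: 0.84, family: beta}
surv_hosp_ieev: {base: 0.41, low: 0.27, high: 0.57, family: beta}
surv_hosp_no: {base: 0.67, low: 0.55, high: 0.77, family: beta}

# post-discharge mortality hazard ratio vs the general population
hr_post_icu: {base: 2.01, low: 1.64, high: 2.46, family: normal}

# utilities
u_icu: {base: 0.297, low: 0.24, high: 0.36, family: beta}
u_ward: {base: 0.60, low: 0.53, high: 0.67, family: beta}
u_y1: {base: 0.67, low: 0.62, high: 0.71, family: beta}
u_y2_10: {base: 0.70, low: 0.65, high: 0.75, family: beta}
u_gt10: {base: 0.68, low: 0.62, high: 0.74, family: beta}

# resource use (days)
los_icu_ieev: {base: 28, low: 23, high: 34, family: gamma}
los_icu_no: {base: 22, low: 18, high: 27, family: gamma}
mv_ieev: {base: 21, low: 17, high: 27, family: gamma}
mv_no: {base: 15, low: 12, high: 17, family: gamma}
los_ward: {base: 17.3, low: 14, high: 21, family: gamma}

# unit costs (2019 EUR)
price_analytics: {base: 1918, low: 100, high: 20000, family: fixed}
cost_treat: {base: 100, low: 57, high: 155, family: gamma}
cost_icu_day: {base: 686, low: 392, high: 1060, family: gamma}
cost_ward_day: {base: 298, low: 170, high: 460, family: gamma}
wean_reduction: {base: 0.10, low: 0.00, high: 0.35, family: beta_pert}

# annual discount rates (fixed in the PSA, varied in the tornado)
disc_costs: {base: 0.035, low: 0.03, high: 0.05, family: fixed}
disc_health: {base: 0.035, low: 0.01, high: 0.05, family: fixed}
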