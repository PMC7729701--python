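"""Markov cohort model: traces, half-cycle correction, discounting."""

import numpy as np
import pytest

from ieev_cea.cohort import post_discharge_trace, run_cohort
from ieev_cea.decision_tree import arm_outcome_mix
from ieev_cea.life_table import LifeTable, build_life_table


def flat_table(q, terminal=60, start=0):
    arr = np.full(terminal - start + 1, q, dtype=float)
    arr[-1] = 1.0
    return LifeTable(start_age=start, q=arr)


class TestPostDischargeTrace:
    def test_identity_case_recovers_life_expectancy(self, life_table):
        """hr=1, utilities 1, no discounting: total LY must equal the
        general-population remaining life expectancy at that age."""
        frag = post_discharge_trace(
            age_at_discharge=62.0, hr=1.0, lt=life_table, disc_health=0.0,
            utilities=(1.0, 1.0, 1.0), t0=0.0,
        )
        assert frag["ly_disc"].sum() == pytest.approx(
            life_table.life_expectancy(62.0), abs=1e-9
        )
        assert frag["qaly_disc"].sum() == pytest.approx(frag["ly_disc"].sum())

    def test_huge_hazard_ratio_kills_cohort_immediately(self, life_table):
        frag = post_discharge_trace(
            age_at_discharge=62.0, hr=1e6, lt=life_table, disc_health=0.0,
            utilities=(1.0, 1.0, 1.0), t0=0.0,
        )
        assert frag["ly_disc"].sum() == pytest.approx(0.5, abs=1e-6)
        # half-cycle: the cohort lives on average half the first year

    def test_flat_hazard_agrees_with_brute_force_summation(self):
        """Independent oracle: per-year summation of the exp(-hr*h*k)
        survival schedule with half-cycle correction, at a flat q."""
        q, hr = 0.05, 2.01
        lt = flat_table(q, terminal=60)
        frag = post_discharge_trace(
            age_at_discharge=0.0, hr=hr, lt=lt, disc_health=0.0,
            utilities=(1.0, 1.0, 1.0), t0=0.0,
        )
        total, alive = 0.0, 1.0
        for age in range(61):  # includes the closing terminal-age year
            if alive <= 1e-8:
                break
            h = -np.log(1 - lt.q_at(age)) if lt.q_at(age) < 1 else np.inf
            nxt = alive * np.exp(-hr * h)
            total += 0.5 * (alive + nxt)
            alive = nxt
        assert frag["ly_disc"].sum() == pytest.approx(total, abs=1e-9)

    def test_utility_bins_by_years_since_discharge(self):
        lt = flat_table(0.0, terminal=40)  # nobody dies before terminal age
        frag = post_discharge_trace(
            age_at_discharge=0.0, hr=1.0, lt=lt, disc_health=0.0,
            utilities=(0.5, 0.7, 0.9), t0=0.0,
        )
        u = (frag["qaly_disc"] / frag["ly_disc"]).to_numpy()
        assert u[0] == pytest.approx(0.5)
        assert np.allclose(u[1:10], 0.7)
        assert np.allclose(u[10:-1], 0.9)

    def test_discounting_uses_mid_cycle_factor(self):
        lt = flat_table(0.0, terminal=10)
        frag = post_discharge_trace(
            age_at_discharge=0.0, hr=1.0, lt=lt, disc_health=0.035,
            utilities=(1.0, 1.0, 1.0), t0=2.0,
        )
        expected = 1.035 ** -(2.0 + 0.5)
        assert frag["ly_disc"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_age_beyond_table_raises(self, life_table):
        with pytest.raises(ValueError, match="range"):
            post_discharge_trace(130.0, 1.0, life_table, 0.0, (1, 1, 1), 0.0)

    def test_nonpositive_hazard_ratio_raises(self, life_table):
        with pytest.raises(ValueError, match="hazard ratio"):
            post_discharge_trace(62.0, 0.0, life_table, 0.0, (1, 1, 1), 0.0)


class TestRunCohort:
    @pytest.mark.parametrize("arm", ["current_care", "analytics"])
    def test_trace_invariants(self, base_params, life_table, arm):
        out = run_cohort(arm_outcome_mix(base_params, arm), base_params, life_table)
        frame = out.trace.frame
        occ = frame[["icu", "ward", "discharged", "dead"]].sum(axis=1)
        assert np.allclose(occ, 1.0, atol=1e-10)
        assert (np.diff(frame["dead"]) >= -1e-12).all()
        assert (frame["ly_disc"] >= 0).all()
        assert out.qalys < out.life_years  # utilities < 1

    def test_zero_utilities_zero_qalys(self, base_params, life_table):
        p = base_params.replace(
            u_icu=0.0, u_ward=0.0, u_y1=0.0, u_y2_10=0.0, u_gt10=0.0
        )
        mix = arm_outcome_mix(p, "current_care")
        out = run_cohort(mix, p, life_table)
        ref = run_cohort(arm_outcome_mix(base_params, "current_care"),
                         base_params, life_table)
        assert out.qalys == 0.0
        assert out.life_years == pytest.approx(ref.life_years)

    def test_no_excess_mortality_recovers_general_population(self, base_params, life_table):
        """All survive the hospital and hr=1: LY = remaining expectancy at
        discharge age plus the in-hospital time."""
        p = base_params.replace(
            surv_icu_ieev=1.0, surv_icu_no=1.0,
            surv_hosp_ieev=1.0, surv_hosp_no=1.0,
            hr_post_icu=1.0, disc_health=0.0,
        )
        mix = arm_outcome_mix(p, "current_care")
        out = run_cohort(mix, p, life_table, age_at_admission=62.0)
        in_hospital = (24.28 + 17.3) / 365.0
        expected = in_hospital + life_table.life_expectancy(62.0 + in_hospital)
        assert out.life_years == pytest.approx(expected, abs=1e-9)

    def test_discounted_below_undiscounted(self, base_params, life_table):
        mix = arm_outcome_mix(base_params, "current_care")
        disc = run_cohort(mix, base_params, life_table)
        p0 = base_params.replace(disc_health=0.0, disc_costs=0.0)
        undisc = run_cohort(arm_outcome_mix(p0, "current_care"), p0, life_table)
        assert disc.life_years < undisc.life_years
        assert disc.qalys < undisc.qalys

    def test_zero_rate_reproduces_plain_sums(self, base_params, life_table):
        """Oracle: at discount 0 the trace increments are plain occupancy
        sums (cycle lengths times mean alive fractions)."""
        p0 = base_params.replace(disc_health=0.0)
        out = run_cohort(arm_outcome_mix(p0, "current_care"), p0, life_table)
        frame = out.trace.frame
        head = frame.iloc[:2]
        manual_head = (
            head["length"] * head[["icu", "ward"]].sum(axis=1)
        ).sum()
        tail = frame.iloc[2:]
        alive = tail["discharged"].to_numpy()
        alive_next = np.append(alive[1:], 0.0)
        # last cycle's end-of-cycle alive fraction is below the truncation
        # threshold, not exactly zero; bound the discrepancy instead
        manual_tail = (0.5 * (alive + alive_next)).sum()
        assert out.life_years == pytest.approx(
            manual_head + manual_tail, abs=1e-4
        )

    def test_incremental_qalys_monotone_in_effectiveness(self, base_params, life_table):
        from ieev_cea.economics import evaluate

        gains = []
        for eff in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            p = base_params.replace(eff=eff)
            gains.append(evaluate(p, life_table).delta_qalys)
        assert gains[0] == pytest.approx(0.0, abs=1e-12)
        assert all(a < b for a, b in zip(gains, gains[1:]))

    def test_base_case_gains_within_plausibility_bands(self, model):
        res = model.fit()
        assert 0.15 <= res.ce.delta_qalys <= 0.27
        assert 0.22 <= res.ce.delta_life_years <= 0.40
        assert res.ce.delta_qalys < res.ce.delta_life_years

    def test_degenerate_ward_survival_raises(self, base_params, life_table):
        bad = base_params.replace(surv_icu_ieev=0.05, surv_icu_no=0.05,
                                  surv_hosp_ieev=0.05, surv_hosp_no=0.05)
        # make hospital survival exceed ICU survival after mixing is
        # impossible through validation, so drive s_ward > 1 via rounding-free
        # construction: ICU survival lower than hospital survival is rejected
        # at the ParameterSet level already
        mix = arm_outcome_mix(bad, "current_care")
        out = run_cohort(mix, bad, life_table)  # still valid: s_ward = 1
        assert out.life_years > 0


def test_build_life_table_used_by_model_defaults(model):
    assert model.life_table.terminal_age == 110
    assert model.life_table.life_expectancy(0) == pytest.approx(81.0, abs=0.05)
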