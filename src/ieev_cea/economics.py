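"""Costing, incremental results, headroom and break-even price.

Costing conventions
-------------------
* ICU days on mechanical ventilation are charged at the full daily ICU cost;
  weaned ICU days at the daily cost reduced by ``wean_reduction``.
* Ward costs accrue only for ICU survivors (the expected ward stay of the
  arm's mixture), discounted back over the ICU stay at the cost rate.
* The analytics licence (EUR per bed per year) is apportioned to a patient
  by the expected days on mechanical ventilation: ``price * mv_days / 365``.
* Treatment is charged once per alarm — true and false positives alike.
* The discharged state is cost-free: no post-discharge healthcare costs are
  modelled, so lifetime costs equal in-hospital costs plus the intervention.

Headroom is the maximum per-patient price compatible with a willingness to
pay ``lambda``: ``N + lambda * Q``, where ``N`` is the saving at analytics
price zero and ``Q`` the QALY gain.  Because incremental cost is affine in
the licence price, the break-even price has the closed form
``N / (mv_days / 365)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

from .cohort import DAYS_PER_YEAR, DEFAULT_AGE_AT_ADMISSION, run_cohort
from .decision_tree import (
    ARM_LABELS,
    ArmLabel,
    BranchMix,
    OutcomeProfile,
    arm_outcome_mix,
    expected_short_term,
    profiles_from_params,
)
from .life_table import LifeTable
from .parameters import ParameterSet

__all__ = [
    "CostBreakdown",
    "ArmResult",
    "CEResult",
    "HeadroomResult",
    "DEFAULT_DEVICE_DAYS",
    "in_hospital_costs",
    "analytics_cost_per_patient",
    "treatment_cost_per_patient",
    "evaluate",
    "headroom",
    "break_even_price",
    "net_monetary_benefit",
]

# average days a patient occupies the monitored bed, for per-patient ->
# per-bed-per-year conversion of headroom
DEFAULT_DEVICE_DAYS = 17.0

DominanceLabel = Literal["dominant", "dominated", "icer"]


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted per-patient cost components of one arm (EUR)."""

    icu_cost: float
    ward_cost: float
    analytics_cost: float
    treatment_cost: float

    def __post_init__(self) -> None:
        for name in ("icu_cost", "ward_cost", "analytics_cost", "treatment_cost"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return (self.icu_cost + self.ward_cost
                + self.analytics_cost + self.treatment_cost)


@dataclass(frozen=True)
class ArmResult:
    """Expected per-patient results of one strategy arm."""

    arm: ArmLabel
    costs: CostBreakdown
    los_icu: float
    mv_days: float
    hosp_mortality: float
    life_years: float
    qalys: float

    @property
    def total_cost(self) -> float:
        return self.costs.total


@dataclass(frozen=True)
class CEResult:
    """Both arms plus incremental results and the dominance/ICER verdict."""

    current_care: ArmResult
    analytics: ArmResult
    price_analytics: float = field(default=0.0)

    @property
    def delta_cost(self) -> float:
        return self.analytics.total_cost - self.current_care.total_cost

    @property
    def delta_los(self) -> float:
        return self.analytics.los_icu - self.current_care.los_icu

    @property
    def delta_mv(self) -> float:
        return self.analytics.mv_days - self.current_care.mv_days

    @property
    def delta_mortality(self) -> float:
        return self.analytics.hosp_mortality - self.current_care.hosp_mortality

    @property
    def delta_life_years(self) -> float:
        return self.analytics.life_years - self.current_care.life_years

    @property
    def delta_qalys(self) -> float:
        return self.analytics.qalys - self.current_care.qalys

    @property
    def dominance(self) -> DominanceLabel:
        if self.delta_cost < 0.0 and self.delta_qalys > 0.0:
            return "dominant"
        if self.delta_cost > 0.0 and self.delta_qalys <= 0.0:
            return "dominated"
        return "icer"

    @property
    def icer(self) -> float | None:
        """EUR/QALY, or None when dominance makes the ratio meaningless."""
        if self.dominance != "icer":
            return None
        if self.delta_qalys == 0.0:
            return None
        return self.delta_cost / self.delta_qalys


@dataclass(frozen=True)
class HeadroomResult:
    """Maximum justifiable price at a willingness-to-pay threshold."""

    n_savings: float
    threshold: float
    q_gain: float
    device_days: float

    @property
    def headroom_per_patient(self) -> float:
        return self.n_savings + self.threshold * self.q_gain

    @property
    def headroom_per_bed(self) -> float:
        return self.headroom_per_patient * DAYS_PER_YEAR / self.device_days


def in_hospital_costs(profile: OutcomeProfile, params: ParameterSet) -> tuple[float, float]:
    """(ICU, ward) cost of one outcome profile, undiscounted EUR.

    Ventilated ICU days are charged in full; weaned days at the reduced daily
    rate.  Only ICU survivors accrue the post-ICU ward stay.
    """
    icu = (
        profile.mv_days * params.cost_icu_day
        + (profile.los_icu - profile.mv_days)
        * params.cost_icu_day * (1.0 - params.wean_reduction)
    )
    ward = profile.surv_icu * params.los_ward * params.cost_ward_day
    return icu, ward


def analytics_cost_per_patient(price: float, expected_mv_days: float) -> float:
    """Per-patient share of the annual per-bed licence fee.

    Apportioned over the expected days on mechanical ventilation, the period
    during which the patient occupies the monitored bed's data stream.
    """
    if price < 0.0:
        raise ValueError(f"analytics price must be >= 0, got {price}")
    return price * expected_mv_days / DAYS_PER_YEAR


def treatment_cost_per_patient(branch_mix: BranchMix, cost_treat: float) -> float:
    """Treatment cost charged once per alarm (true and false positives)."""
    return cost_treat * branch_mix.p_alarm


def _arm_result(
    params: ParameterSet,
    arm: ArmLabel,
    lt: LifeTable,
    age: float,
) -> ArmResult:
    mix = arm_outcome_mix(params, arm)
    with_p, without_p = profiles_from_params(params)
    st = expected_short_term(mix, with_p, without_p)
    cohort = run_cohort(mix, params, lt, age)

    icu_w, ward_w = in_hospital_costs(with_p, params)
    icu_n, ward_n = in_hospital_costs(without_p, params)
    w, v = mix.w_with, mix.w_without
    icu_cost = w * icu_w + v * icu_n
    # ward stay starts after the ICU stay; discount at the cost rate
    df_ward = (1.0 + params.disc_costs) ** -(st.los_icu / DAYS_PER_YEAR)
    ward_cost = (w * ward_w + v * ward_n) * df_ward

    if arm == "analytics":
        assert mix.branch_mix is not None
        analytics_cost = analytics_cost_per_patient(params.price_analytics, st.mv_days)
        treat_cost = treatment_cost_per_patient(mix.branch_mix, params.cost_treat)
    else:
        analytics_cost = 0.0
        treat_cost = 0.0

    return ArmResult(
        arm=arm,
        costs=CostBreakdown(icu_cost, ward_cost, analytics_cost, treat_cost),
        los_icu=st.los_icu,
        mv_days=st.mv_days,
        hosp_mortality=st.hosp_mortality,
        life_years=cohort.life_years,
        qalys=cohort.qalys,
    )


def evaluate(
    params: ParameterSet,
    lt: LifeTable,
    age: float = DEFAULT_AGE_AT_ADMISSION,
) -> CEResult:
    """Full cost-effectiveness comparison of the two strategies."""
    results = {arm: _arm_result(params, arm, lt, age) for arm in ARM_LABELS}
    return CEResult(
        current_care=results["current_care"],
        analytics=results["analytics"],
        price_analytics=params.price_analytics,
    )


def headroom(
    ce: CEResult,
    threshold: float,
    device_days: float = DEFAULT_DEVICE_DAYS,
) -> HeadroomResult:
    """Headroom ``N + threshold * Q`` from a price-zero evaluation.

    ``ce`` must have been evaluated with the analytics price set to 0 so that
    ``N = -delta_cost`` is the pure saving of the strategy.
    """
    if threshold < 0.0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    if device_days <= 0.0:
        raise ValueError("device_days must be > 0")
    if ce.price_analytics != 0.0:
        raise ValueError(
            "headroom requires a CEResult evaluated at analytics price 0 "
            f"(got price {ce.price_analytics})"
        )
    return HeadroomResult(
        n_savings=-ce.delta_cost,
        threshold=threshold,
        q_gain=ce.delta_qalys,
        device_days=device_days,
    )


def break_even_price(
    params: ParameterSet,
    lt: LifeTable,
    age: float = DEFAULT_AGE_AT_ADMISSION,
) -> float:
    """Licence price (EUR/bed/year) at which incremental cost crosses zero.

    Incremental cost is affine in the price with slope ``mv_days / 365``
    (expected ventilated days of the analytics arm), so the root is
    ``N / (mv_days / 365)`` with ``N`` the saving at price zero.  Returns 0
    with a warning when the strategy never saves money.
    """
    ce0 = evaluate(params.replace(price_analytics=0.0), lt, age)
    n_savings = -ce0.delta_cost
    if n_savings <= 0.0:
        warnings.warn(
            "analytics arm is not cost-saving at price 0; "
            "no positive break-even price exists",
            stacklevel=2,
        )
        return 0.0
    price = n_savings * DAYS_PER_YEAR / ce0.analytics.mv_days
    # self-check: re-evaluating at the root must return to (numerical) zero
    residual = evaluate(params.replace(price_analytics=price), lt, age).delta_cost
    if abs(residual) > 0.01:
        raise RuntimeError(
            f"break-even self-check failed: residual incremental cost {residual:.4f}"
        )
    return price


def net_monetary_benefit(ce: CEResult, threshold: float) -> float:
    """``threshold * delta_QALYs - delta_cost`` (EUR); positive = cost-effective."""
    return threshold * ce.delta_qalys - ce.delta_cost
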