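"""Diagnostic decision tree for real-time ineffective-effort-event detection.

The intervention arm runs every ventilated patient through the monitor and
treats on every alarm, giving five leaves:

* true positive, treatment succeeds  — patient adopts the without-IEEV profile
* true positive, treatment fails     — keeps the with-IEEV profile
* false negative                     — keeps the with-IEEV profile
* false positive                     — treated (cost) but outcome unchanged
* true negative                      — without-IEEV profile

The comparator arm is current care: no detection, no treatment, prevalence
``prior`` of the with-IEEV profile.  Short-term outcomes (ICU length of stay,
days on mechanical ventilation, survival) are mixture averages of the two
outcome profiles with arm-specific weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

from .parameters import ParameterSet

__all__ = [
    "BranchMix",
    "OutcomeProfile",
    "ArmMix",
    "ShortTermOutcome",
    "compute_branch_mix",
    "arm_outcome_mix",
    "expected_short_term",
    "profiles_from_params",
]

ArmLabel = Literal["current_care", "analytics"]
ARM_LABELS: tuple[ArmLabel, ...] = ("current_care", "analytics")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")


@dataclass(frozen=True)
class BranchMix:
    """Leaf probabilities of the intervention arm."""

    p_tp_success: float
    p_tp_fail: float
    p_fn: float
    p_fp: float
    p_tn: float

    def __post_init__(self) -> None:
        total = (self.p_tp_success + self.p_tp_fail + self.p_fn
                 + self.p_fp + self.p_tn)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"leaf probabilities sum to {total}, not 1")

    @property
    def p_alarm(self) -> float:
        """Probability an alarm sounds (all treated leaves)."""
        return self.p_tp_success + self.p_tp_fail + self.p_fp


@dataclass(frozen=True)
class OutcomeProfile:
    """Short-term outcome bundle of one patient group."""

    los_icu: float
    mv_days: float
    surv_icu: float
    surv_hosp: float
    label: Literal["with_ieev", "without_ieev"]

    def __post_init__(self) -> None:
        if self.mv_days > self.los_icu:
            raise ValueError(
                f"mv_days={self.mv_days} exceeds los_icu={self.los_icu}"
            )
        if self.surv_hosp > self.surv_icu:
            raise ValueError(
                f"surv_hosp={self.surv_hosp} exceeds surv_icu={self.surv_icu}"
            )


@dataclass(frozen=True)
class ArmMix:
    """Mixture weights over the two outcome profiles for one strategy arm."""

    arm: ArmLabel
    w_with: float
    w_without: float
    branch_mix: BranchMix | None = None

    def __post_init__(self) -> None:
        if abs(self.w_with + self.w_without - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        _check_prob("w_with", self.w_with)


class ShortTermOutcome(NamedTuple):
    los_icu: float
    mv_days: float
    surv_icu: float
    hosp_mortality: float


def compute_branch_mix(sens: float, spec: float, prior: float, eff: float) -> BranchMix:
    """Leaf probabilities from detection characteristics and prevalence.

    ``sens``/``spec`` are the monitor's sensitivity and specificity, ``prior``
    the prevalence of ineffective effort events, ``eff`` the probability a
    treatment triggered by a true alarm succeeds.
    """
    for name, v in (("sens", sens), ("spec", spec), ("prior", prior), ("eff", eff)):
        _check_prob(name, v)
    return BranchMix(
        p_tp_success=prior * sens * eff,
        p_tp_fail=prior * sens * (1.0 - eff),
        p_fn=prior * (1.0 - sens),
        p_fp=(1.0 - prior) * (1.0 - spec),
        p_tn=(1.0 - prior) * spec,
    )


def profiles_from_params(params: ParameterSet) -> tuple[OutcomeProfile, OutcomeProfile]:
    """(with-IEEV, without-IEEV) outcome profiles from a parameter set."""
    with_ieev = OutcomeProfile(
        los_icu=params.los_icu_ieev,
        mv_days=params.mv_ieev,
        surv_icu=params.surv_icu_ieev,
        surv_hosp=params.surv_hosp_ieev,
        label="with_ieev",
    )
    without = OutcomeProfile(
        los_icu=params.los_icu_no,
        mv_days=params.mv_no,
        surv_icu=params.surv_icu_no,
        surv_hosp=params.surv_hosp_no,
        label="without_ieev",
    )
    return with_ieev, without


def arm_outcome_mix(params: ParameterSet, arm: ArmLabel) -> ArmMix:
    """Mixture weights on the with/without-IEEV profiles for one arm.

    Under current care the with-IEEV weight is the prevalence.  Under the
    analytics arm successfully treated true positives move to the
    without-IEEV profile, so the weight drops by ``prior * sens * eff``;
    false positives already carry the without-IEEV profile and are unchanged.
    """
    if arm == "current_care":
        return ArmMix(arm=arm, w_with=params.prior, w_without=1.0 - params.prior)
    if arm == "analytics":
        mix = compute_branch_mix(params.sens, params.spec, params.prior, params.eff)
        w_with = params.prior - mix.p_tp_success
        return ArmMix(arm=arm, w_with=w_with, w_without=1.0 - w_with, branch_mix=mix)
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARM_LABELS}")


def expected_short_term(
    mix: ArmMix,
    with_ieev: OutcomeProfile,
    without_ieev: OutcomeProfile,
) -> ShortTermOutcome:
    """Mixture-weighted short-term outcomes for one arm.

    Hospital mortality is one minus the weighted hospital survival.
    """
    w, v = mix.w_with, mix.w_without

    def avg(a: float, b: float) -> float:
        return w * a + v * b

    return ShortTermOutcome(
        los_icu=avg(with_ieev.los_icu, without_ieev.los_icu),
        mv_days=avg(with_ieev.mv_days, without_ieev.mv_days),
        surv_icu=avg(with_ieev.surv_icu, without_ieev.surv_icu),
        hosp_mortality=1.0 - avg(with_ieev.surv_hosp, without_ieev.surv_hosp),
    )
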