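"""Deterministic uncertainty analyses: tornado, scenarios, price sweep.

The one-way (tornado) analysis moves each parameter that has a low/high
range to its bounds, one at a time, holding everything else at base.  Moving
one member of a linked pair can transiently violate a cross-field invariant
(e.g. hospital survival above ICU survival); the offending value is clipped
to the boundary and a notice is logged, so the analysis remains strictly
one-way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .cohort import DEFAULT_AGE_AT_ADMISSION
from .economics import CEResult, evaluate
from .life_table import LifeTable
from .parameters import ParameterSet, SCENARIO_PRESETS, apply_scenario

__all__ = [
    "TornadoEntry",
    "tornado",
    "tornado_frame",
    "run_scenarios",
    "scenario_table",
    "price_sweep",
]

logger = logging.getLogger(__name__)

Outcome = Literal["incremental_cost", "incremental_qalys"]

# (field, partner, relation): field must stay <= / >= partner
_CLIP_RULES = [
    ("mv_ieev", "los_icu_ieev", "le"),
    ("mv_no", "los_icu_no", "le"),
    ("surv_hosp_ieev", "surv_icu_ieev", "le"),
    ("surv_hosp_no", "surv_icu_no", "le"),
    ("los_icu_ieev", "mv_ieev", "ge"),
    ("los_icu_no", "mv_no", "ge"),
    ("surv_icu_ieev", "surv_hosp_ieev", "ge"),
    ("surv_icu_no", "surv_hosp_no", "ge"),
]


@dataclass(frozen=True)
class TornadoEntry:
    """One-way result for a single parameter."""

    parameter: str
    low: float
    high: float
    delta_at_low: float
    delta_at_high: float

    @property
    def width(self) -> float:
        return abs(self.delta_at_high - self.delta_at_low)


def _clipped_value(params: ParameterSet, name: str, value: float) -> float:
    for fld, partner, rel in _CLIP_RULES:
        if fld != name:
            continue
        bound = getattr(params, partner)
        if rel == "le" and value > bound:
            logger.warning(
                "tornado: clipping %s from %s to %s to keep %s <= %s",
                name, value, bound, name, partner,
            )
            return bound
        if rel == "ge" and value < bound:
            logger.warning(
                "tornado: clipping %s from %s to %s to keep %s >= %s",
                name, value, bound, name, partner,
            )
            return bound
    return value


def _outcome(ce: CEResult, outcome: Outcome) -> float:
    if outcome == "incremental_cost":
        return ce.delta_cost
    if outcome == "incremental_qalys":
        return ce.delta_qalys
    raise ValueError(f"unknown outcome {outcome!r}")


def tornado(
    params: ParameterSet,
    lt: LifeTable,
    outcome: Outcome = "incremental_cost",
    age: float = DEFAULT_AGE_AT_ADMISSION,
) -> list[TornadoEntry]:
    """One-way sensitivity of the incremental outcome to every ranged input.

    Returns entries ordered by descending bar width.  Parameters whose
    distribution spec carries no usable range (low == high == base) produce
    zero-width bars; parameters without a spec are skipped with a notice.
    """
    entries = []
    for name in params.values():
        spec = params.dists.get(name)
        if spec is None:
            logger.warning("tornado: parameter %s has no bounds; skipped", name)
            continue
        deltas = []
        for bound in (spec.low, spec.high):
            value = _clipped_value(params, name, bound)
            ce = evaluate(params.replace(**{name: value}), lt, age)
            deltas.append(_outcome(ce, outcome))
        entries.append(
            TornadoEntry(name, spec.low, spec.high, deltas[0], deltas[1])
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "delta_at_low": e.delta_at_low,
                "delta_at_high": e.delta_at_high,
                "width": e.width,
            }
            for e in entries
        ]
    )


def run_scenarios(
    params: ParameterSet,
    lt: LifeTable,
    age: float = DEFAULT_AGE_AT_ADMISSION,
    scenarios: Iterable[str] = ("base", "worst", "best", "high_icu_cost"),
) -> dict[str, CEResult]:
    """Evaluate the named scenario presets."""
    out = {}
    for name in scenarios:
        if name not in SCENARIO_PRESETS:
            raise ValueError(f"unknown scenario {name!r}")
        out[name] = evaluate(apply_scenario(params, name), lt, age)
    return out


def scenario_table(results: dict[str, CEResult]) -> pd.DataFrame:
    """Scenario results as a tidy frame: one row per scenario x arm plus
    an incremental row, column order mirroring the headline results table."""
    rows = []
    for scenario, ce in results.items():
        for arm_name, arm in (("current_care", ce.current_care),
                              ("analytics", ce.analytics)):
            rows.append(
                {
                    "scenario": scenario,
                    "row": arm_name,
                    "cost": arm.total_cost,
                    "los_icu": arm.los_icu,
                    "hosp_mortality": arm.hosp_mortality,
                    "life_years": arm.life_years,
                    "qalys": arm.qalys,
                    "icu_cost": arm.costs.icu_cost,
                    "ward_cost": arm.costs.ward_cost,
                    "analytics_cost": arm.costs.analytics_cost,
                    "treatment_cost": arm.costs.treatment_cost,
                }
            )
        rows.append(
            {
                "scenario": scenario,
                "row": "incremental",
                "cost": ce.delta_cost,
                "los_icu": ce.delta_los,
                "hosp_mortality": ce.delta_mortality,
                "life_years": ce.delta_life_years,
                "qalys": ce.delta_qalys,
                "icu_cost": np.nan,
                "ward_cost": np.nan,
                "analytics_cost": np.nan,
                "treatment_cost": np.nan,
            }
        )
        rows.append(
            {
                "scenario": scenario,
                "row": "icer",
                "cost": np.nan if ce.icer is None else ce.icer,
                "los_icu": np.nan,
                "hosp_mortality": np.nan,
                "life_years": np.nan,
                "qalys": np.nan,
                "icu_cost": np.nan,
                "ward_cost": np.nan,
                "analytics_cost": np.nan,
                "treatment_cost": np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["verdict"] = None
    for scenario, ce in results.items():
        df.loc[(df["scenario"] == scenario) & (df["row"] == "icer"), "verdict"] = (
            ce.dominance
        )
    return df


def price_sweep(
    params: ParameterSet,
    lt: LifeTable,
    prices: Iterable[float],
    age: float = DEFAULT_AGE_AT_ADMISSION,
) -> pd.DataFrame:
    """Incremental cost at each analytics licence price (all else base).

    The relationship is exactly affine; the sweep exists for reporting and
    as a cross-check on the closed-form break-even price.
    """
    prices = list(prices)
    if any(p < 0 for p in prices):
        raise ValueError("prices must be >= 0")
    rows = [
        {
            "price": p,
            "delta_cost": evaluate(
                params.replace(price_analytics=float(p)), lt, age
            ).delta_cost,
        }
        for p in prices
    ]
    return pd.DataFrame(rows)
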