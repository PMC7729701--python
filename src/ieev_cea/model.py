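"""Model/Results facade over the cost-effectiveness pipeline.

:class:`CostEffectivenessModel` bundles a parameter set, a life table and a
cohort age; :meth:`~CostEffectivenessModel.fit` evaluates both strategy arms
and returns a :class:`CEModelResults` carrying the arm-level and incremental
estimates, the dominance verdict and a formatted summary, with the
sensitivity, probabilistic and headroom analyses hanging off the two
objects.

Example
-------
>>> from ieev_cea import CostEffectivenessModel
>>> res = CostEffectivenessModel.from_defaults().fit()
>>> round(res.ce.delta_los, 2)
-0.6
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from . import economics, psa as psa_mod, sensitivity
from .cohort import DEFAULT_AGE_AT_ADMISSION
from .economics import CEResult, DEFAULT_DEVICE_DAYS, HeadroomResult
from .life_table import LifeTable, build_life_table
from .parameters import ParameterSet, apply_scenario, load_parameters
from .synthetic_cohort import estimate_parameters

__all__ = ["CostEffectivenessModel", "CEModelResults"]

# packaged synthetic life-table calibration: Gompertz stand-in for a
# high-income-country period table
DEFAULT_LIFE_EXPECTANCY = 81.0
DEFAULT_GOMPERTZ_SLOPE = 0.085


class CostEffectivenessModel:
    """Decision tree + Markov cohort model comparing real-time detection of
    ineffective effort events with current care.

    Parameters
    ----------
    params
        Validated model inputs; ``None`` loads the packaged base case.
    life_table
        General-population mortality for post-discharge extrapolation;
        ``None`` builds the packaged Gompertz stand-in (life expectancy 81.0,
        slope 0.085/yr).
    age_at_admission
        Mean cohort age at ICU admission in years (default 62).
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        life_table: LifeTable | None = None,
        age_at_admission: float = DEFAULT_AGE_AT_ADMISSION,
    ) -> None:
        self.params = params if params is not None else load_parameters(None)
        self.life_table = (
            life_table
            if life_table is not None
            else build_life_table(DEFAULT_LIFE_EXPECTANCY, DEFAULT_GOMPERTZ_SLOPE)
        )
        self.age_at_admission = float(age_at_admission)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_defaults(cls, **kwargs: Any) -> "CostEffectivenessModel":
        return cls(**kwargs)

    @classmethod
    def from_config(
        cls,
        config: str | Path | Mapping[str, Any],
        life_table: LifeTable | None = None,
        age_at_admission: float = DEFAULT_AGE_AT_ADMISSION,
    ) -> "CostEffectivenessModel":
        """Build from a YAML/JSON configuration file or mapping."""
        return cls(load_parameters(config), life_table, age_at_admission)

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        base: ParameterSet | None = None,
        seed: int = 0,
        **kwargs: Any,
    ) -> "CostEffectivenessModel":
        """Build with prevalence, survival and stay inputs re-estimated from
        patient-level records; all other inputs come from ``base``."""
        base = base if base is not None else load_parameters(None)
        est = estimate_parameters(cohort, seed=seed)
        return cls(base.replace(**est.point_overrides()), **kwargs)

    # -- evaluation ---------------------------------------------------------

    def _scenario_params(self, scenario: str) -> ParameterSet:
        return apply_scenario(self.params, scenario)

    def fit(self, scenario: str = "base") -> "CEModelResults":
        """Evaluate both arms under a scenario preset and wrap the results."""
        params = self._scenario_params(scenario)
        ce = economics.evaluate(params, self.life_table, self.age_at_admission)
        return CEModelResults(self, scenario, params, ce)

    def fit_scenarios(
        self,
        scenarios: Iterable[str] = ("base", "worst", "best", "high_icu_cost"),
    ) -> dict[str, "CEModelResults"]:
        return {name: self.fit(name) for name in scenarios}

    # -- deterministic sensitivity -----------------------------------------

    def tornado(
        self,
        outcome: sensitivity.Outcome = "incremental_cost",
    ) -> list[sensitivity.TornadoEntry]:
        return sensitivity.tornado(
            self.params, self.life_table, outcome, self.age_at_admission
        )

    def price_sweep(self, prices: Sequence[float]) -> pd.DataFrame:
        return sensitivity.price_sweep(
            self.params, self.life_table, prices, self.age_at_admission
        )

    def break_even_price(self) -> float:
        return economics.break_even_price(
            self.params, self.life_table, self.age_at_admission
        )

    # -- probabilistic sensitivity -----------------------------------------

    def run_psa(
        self,
        n_draws: int,
        seed: int,
        eff_level: float | None = None,
    ) -> list[psa_mod.PSADraw]:
        return psa_mod.run_psa(
            self.params, n_draws, seed, self.life_table,
            eff_level=eff_level, age=self.age_at_admission,
        )


class CEModelResults:
    """Fitted results of one scenario evaluation."""

    def __init__(
        self,
        model: CostEffectivenessModel,
        scenario: str,
        params: ParameterSet,
        ce: CEResult,
    ) -> None:
        self.model = model
        self.scenario = scenario
        self.params = params
        self.ce = ce

    # convenience accessors mirroring the headline outcomes
    @property
    def delta_cost(self) -> float:
        return self.ce.delta_cost

    @property
    def delta_qalys(self) -> float:
        return self.ce.delta_qalys

    @property
    def icer(self) -> float | None:
        return self.ce.icer

    @property
    def dominance(self) -> str:
        return self.ce.dominance

    def nmb(self, threshold: float) -> float:
        """Net monetary benefit at a willingness-to-pay threshold."""
        return economics.net_monetary_benefit(self.ce, threshold)

    def headroom(
        self,
        threshold: float,
        device_days: float = DEFAULT_DEVICE_DAYS,
    ) -> HeadroomResult:
        """Headroom at a threshold, re-evaluating this scenario at price 0."""
        price_free = economics.evaluate(
            self.params.replace(price_analytics=0.0),
            self.model.life_table,
            self.model.age_at_admission,
        )
        return economics.headroom(price_free, threshold, device_days)

    def to_frame(self) -> pd.DataFrame:
        """One row per arm plus the incremental row."""
        return sensitivity.scenario_table({self.scenario: self.ce})

    def summary(self) -> str:
        """Formatted results table (euros full precision; see to_frame)."""
        ce = self.ce
        rows = [
            ("", "Current care", "With analytics", "Incremental"),
            ("Total cost (EUR)",
             f"{ce.current_care.total_cost:,.0f}",
             f"{ce.analytics.total_cost:,.0f}",
             f"{ce.delta_cost:,.0f}"),
            ("ICU length of stay (d)",
             f"{ce.current_care.los_icu:.2f}",
             f"{ce.analytics.los_icu:.2f}",
             f"{ce.delta_los:.2f}"),
            ("Days on ventilation",
             f"{ce.current_care.mv_days:.2f}",
             f"{ce.analytics.mv_days:.2f}",
             f"{ce.delta_mv:.2f}"),
            ("Hospital mortality",
             f"{ce.current_care.hosp_mortality:.2f}",
             f"{ce.analytics.hosp_mortality:.2f}",
             f"{ce.delta_mortality:.2f}"),
            ("Life years (disc.)",
             f"{ce.current_care.life_years:.2f}",
             f"{ce.analytics.life_years:.2f}",
             f"{ce.delta_life_years:.2f}"),
            ("QALYs (disc.)",
             f"{ce.current_care.qalys:.2f}",
             f"{ce.analytics.qalys:.2f}",
             f"{ce.delta_qalys:.2f}"),
        ]
        widths = [max(len(r[i]) for r in rows) for i in range(4)]
        lines = [
            f"Cost-effectiveness results — scenario: {self.scenario}",
            "=" * (sum(widths) + 9),
        ]
        for r in rows:
            lines.append(
                "  ".join(cell.rjust(w) if i else cell.ljust(w)
                          for i, (cell, w) in enumerate(zip(r, widths)))
            )
        lines.append("-" * (sum(widths) + 9))
        verdict = ce.dominance
        if verdict == "icer":
            lines.append(f"ICER: {ce.icer:,.0f} EUR/QALY")
        else:
            lines.append(f"ICER: analytics arm is {verdict}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CEModelResults scenario={self.scenario!r} "
            f"dC={self.delta_cost:.1f} dQ={self.delta_qalys:.3f} "
            f"{self.dominance}>"
        )
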