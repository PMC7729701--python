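"""Probabilistic sensitivity analysis: distribution fitting, sampling, CEAC.

Distributions are fitted from each row's (base, low, high) summary:

* ``beta`` and ``gamma`` by method of moments with mean = base and
  sd = (high - low) / 3.92, reading the range as a central 95% interval;
* ``normal`` likewise, truncated below at zero (used for the hazard ratio);
* ``beta_pert`` directly from (low, base, high) as (min, mode, max) with the
  conventional shape constant 4 — its mean is (min + 4 mode + max) / 6, which
  is *not* the base value unless the range is symmetric;
* ``fixed`` rows (licence price, treatment effectiveness, discount rates)
  are never sampled.

Each draw uses its own counter-derived RNG stream, so draw ``j`` of a run is
the same regardless of the total number of draws: a scaled-down run is a
prefix of the full run.  Cross-field invariants (ventilation days within ICU
stay, hospital survival within ICU survival) are enforced by resampling the
offending components; resample counts are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DEFAULT_AGE_AT_ADMISSION
from .economics import evaluate
from .life_table import LifeTable
from .parameters import DistributionSpec, ParameterSet

__all__ = [
    "FittedDistribution",
    "PSADraw",
    "fit_distribution",
    "fit_all",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "ce_plane",
    "centroid",
]

logger = logging.getLogger(__name__)

_PERT_SHAPE = 4.0
# factor converting a central 95% range to a standard deviation
_RANGE_TO_SD = 2.0 * 1.959963984540054

_MAX_COMPONENT_RESAMPLES = 1000


@dataclass(frozen=True)
class FittedDistribution:
    """Natural parameters of one sampled input."""

    family: str
    args: tuple[float, ...]
    source: DistributionSpec

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "fixed":
            base = self.source.base
            return base if size is None else np.full(size, base)
        if self.family == "beta":
            a, b = self.args
            return rng.beta(a, b, size=size)
        if self.family == "beta_pert":
            a, b, lo, hi = self.args
            return lo + (hi - lo) * rng.beta(a, b, size=size)
        if self.family == "gamma":
            shape, scale = self.args
            return rng.gamma(shape, scale, size=size)
        if self.family == "normal":
            mean, sd = self.args
            # truncated below at zero
            a = (0.0 - mean) / sd
            return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                       size=size, random_state=rng)
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def mean(self) -> float:
        """Analytic mean of the fitted distribution (truncation ignored for
        the zero-truncated normal, negligible at the fitted parameters)."""
        if self.family == "fixed":
            return self.source.base
        if self.family == "beta":
            a, b = self.args
            return a / (a + b)
        if self.family == "beta_pert":
            s = self.source
            return (s.low + _PERT_SHAPE * s.base + s.high) / (_PERT_SHAPE + 2.0)
        if self.family == "gamma":
            shape, scale = self.args
            return shape * scale
        if self.family == "normal":
            return self.args[0]
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class PSADraw:
    """One sampled parameter vector with its incremental results."""

    index: int
    params: ParameterSet
    delta_cost: float
    delta_qalys: float


def fit_distribution(spec: DistributionSpec, name: str = "") -> FittedDistribution:
    """Fit the natural parameters of ``spec``'s family to its summary."""
    label = name or spec.family
    if spec.family == "fixed":
        return FittedDistribution("fixed", (), spec)

    if spec.family == "beta_pert":
        lo, mode, hi = spec.low, spec.base, spec.high
        if hi == lo:
            return FittedDistribution("fixed", (), spec)
        a = 1.0 + _PERT_SHAPE * (mode - lo) / (hi - lo)
        b = 1.0 + _PERT_SHAPE * (hi - mode) / (hi - lo)
        return FittedDistribution("beta_pert", (a, b, lo, hi), spec)

    mean = spec.base
    sd = (spec.high - spec.low) / _RANGE_TO_SD
    if sd <= 0.0:
        return FittedDistribution("fixed", (), spec)

    if spec.family == "beta":
        var = sd * sd
        if var >= mean * (1.0 - mean):
            raise ValueError(
                f"infeasible beta moments for {label}: "
                f"sd^2={var:.4g} >= m(1-m)={mean * (1 - mean):.4g}"
            )
        nu = mean * (1.0 - mean) / var - 1.0
        return FittedDistribution("beta", (mean * nu, (1.0 - mean) * nu), spec)
    if spec.family == "gamma":
        if mean <= 0.0:
            raise ValueError(f"gamma mean must be > 0 for {label}")
        return FittedDistribution("gamma", ((mean / sd) ** 2, sd * sd / mean), spec)
    if spec.family == "normal":
        return FittedDistribution("normal", (mean, sd), spec)
    raise ValueError(f"unknown family {spec.family!r} for {label}")


def fit_all(params: ParameterSet, frozen: Iterable[str] = ()) -> dict[str, FittedDistribution]:
    """Fitted distribution per parameter, with ``frozen`` names forced fixed."""
    frozen = set(frozen)
    fitted = {}
    for name, spec in params.dists.items():
        if name in frozen:
            spec = DistributionSpec("fixed", getattr(params, name), spec.low, spec.high)
        fitted[name] = fit_distribution(spec, name)
    return fitted


def _resample_pair(
    rng: np.random.Generator,
    fitted: dict[str, FittedDistribution],
    values: dict[str, float],
    small: str,
    large: str,
) -> int:
    """Redraw the (small, large) pair jointly until small <= large."""
    n = 0
    while values[small] > values[large]:
        if n >= _MAX_COMPONENT_RESAMPLES:
            raise RuntimeError(
                f"could not satisfy {small} <= {large} after "
                f"{_MAX_COMPONENT_RESAMPLES} resamples"
            )
        values[small] = float(fitted[small].sample(rng))
        values[large] = float(fitted[large].sample(rng))
        n += 1
    return n


def sample_parameter_set(
    params: ParameterSet,
    fitted: dict[str, FittedDistribution],
    rng: np.random.Generator,
) -> tuple[ParameterSet, int]:
    """One joint draw; returns (sampled set, number of constraint resamples)."""
    values = {name: float(d.sample(rng)) for name, d in fitted.items()}
    resamples = 0
    for small, large in (
        ("mv_ieev", "los_icu_ieev"),
        ("mv_no", "los_icu_no"),
        ("surv_hosp_ieev", "surv_icu_ieev"),
        ("surv_hosp_no", "surv_icu_no"),
    ):
        resamples += _resample_pair(rng, fitted, values, small, large)
    return params.replace(**values), resamples


def run_psa(
    params: ParameterSet,
    n_draws: int,
    seed: int,
    lt: LifeTable,
    eff_level: float | None = None,
    age: float = DEFAULT_AGE_AT_ADMISSION,
) -> list[PSADraw]:
    """Monte-Carlo evaluation of the model over ``n_draws`` joint draws.

    The licence price, the treatment effectiveness and the discount rates
    stay fixed (their rows carry no distribution); ``eff_level`` overrides
    the effectiveness at which the whole run is evaluated.

    Draw ``j`` uses the RNG stream ``(seed, j)``, so runs with the same seed
    and different ``n_draws`` share their leading draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if eff_level is not None:
        params = params.replace(eff=eff_level)
    fitted = fit_all(params)

    draws: list[PSADraw] = []
    total_resamples = 0
    for j in range(n_draws):
        rng = np.random.default_rng([seed, j])
        sampled, resamples = sample_parameter_set(params, fitted, rng)
        total_resamples += resamples
        ce = evaluate(sampled, lt, age)
        draws.append(PSADraw(j, sampled, ce.delta_cost, ce.delta_qalys))
    if total_resamples:
        logger.info(
            "psa: %d component resamples over %d draws to enforce "
            "cross-field invariants",
            total_resamples, n_draws,
        )
    return draws


def ceac(
    draws: Sequence[PSADraw],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Probability of positive net monetary benefit at each threshold."""
    if len(draws) == 0:
        raise ValueError("ceac requires at least one draw")
    dq = np.array([d.delta_qalys for d in draws])
    dc = np.array([d.delta_cost for d in draws])
    rows = [
        {
            "threshold": lam,
            "p_cost_effective": float(np.mean(lam * dq - dc > 0.0)),
        }
        for lam in thresholds
    ]
    return pd.DataFrame(rows)


def ce_plane(draws: Sequence[PSADraw]) -> pd.DataFrame:
    """Scatter table (draw, delta_qalys, delta_cost) for the CE plane."""
    if len(draws) == 0:
        raise ValueError("ce_plane requires at least one draw")
    return pd.DataFrame(
        {
            "draw": [d.index for d in draws],
            "delta_qalys": [d.delta_qalys for d in draws],
            "delta_cost": [d.delta_cost for d in draws],
        }
    )


def centroid(draws: Sequence[PSADraw]) -> tuple[float, float]:
    """(mean delta_QALYs, mean delta_cost) of a set of draws."""
    plane = ce_plane(draws)
    return float(plane["delta_qalys"].mean()), float(plane["delta_cost"].mean())
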