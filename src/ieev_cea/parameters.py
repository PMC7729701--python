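"""Model inputs: parameter values, uncertainty ranges and scenario presets.

Every input of the cost-effectiveness model lives in a single immutable
:class:`ParameterSet`.  Each field carries a :class:`DistributionSpec` giving
its base-case value, its deterministic low/high range (used by the one-way
sensitivity analysis) and the distribution family used by the probabilistic
sensitivity analysis; rows with no distribution are ``fixed``.

Probabilities and rates are stored as fractions (0.88, never 88).
Configuration files may use percentages by declaring ``units: percent``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "ParameterError",
    "SCENARIO_PRESETS",
    "load_parameters",
    "default_parameters",
    "apply_scenario",
    "default_config_path",
]

_FAMILIES = ("beta", "beta_pert", "gamma", "normal", "fixed")


class ParameterError(ValueError):
    """Raised when a model input violates a type or cross-field invariant."""


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution family plus base/low/high for one model input."""

    family: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if not (self.low <= self.base <= self.high):
            raise ParameterError(
                f"require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )


# field name -> (DistributionSpec, is_fraction)
# Base-case values, ranges and families for every model input.  Fractions are
# stored on [0, 1]; monetary values in 2019 euros; durations in days.
_DEFAULTS: dict[str, tuple[DistributionSpec, bool]] = {
    # diagnostic performance of the ineffective-effort monitor
    "sens": (DistributionSpec("beta", 0.88, 0.79, 0.94), True),
    "spec": (DistributionSpec("beta_pert", 0.99, 0.80, 1.00), True),
    # prevalence of ineffective effort events (IEEVs) and treatment success
    "prior": (DistributionSpec("beta_pert", 0.38, 0.10, 0.50), True),
    "eff": (DistributionSpec("fixed", 0.30, 0.00, 0.50), True),
    # survival by IEEV status
    "surv_icu_ieev": (DistributionSpec("beta", 0.63, 0.48, 0.77), True),
    "surv_icu_no": (DistributionSpec("beta", 0.75, 0.63, 0.84), True),
    "surv_hosp_ieev": (DistributionSpec("beta", 0.41, 0.27, 0.57), True),
    "surv_hosp_no": (DistributionSpec("beta", 0.67, 0.55, 0.77), True),
    # post-discharge excess mortality vs the general population
    "hr_post_icu": (DistributionSpec("normal", 2.01, 1.64, 2.46), False),
    # utilities
    "u_icu": (DistributionSpec("beta", 0.297, 0.24, 0.36), True),
    "u_ward": (DistributionSpec("beta", 0.60, 0.53, 0.67), True),
    "u_y1": (DistributionSpec("beta", 0.67, 0.62, 0.71), True),
    "u_y2_10": (DistributionSpec("beta", 0.70, 0.65, 0.75), True),
    "u_gt10": (DistributionSpec("beta", 0.68, 0.62, 0.74), True),
    # resource use (days)
    "los_icu_ieev": (DistributionSpec("gamma", 28.0, 23.0, 34.0), False),
    "los_icu_no": (DistributionSpec("gamma", 22.0, 18.0, 27.0), False),
    "mv_ieev": (DistributionSpec("gamma", 21.0, 17.0, 27.0), False),
    "mv_no": (DistributionSpec("gamma", 15.0, 12.0, 17.0), False),
    "los_ward": (DistributionSpec("gamma", 17.3, 14.0, 21.0), False),
    # unit costs (2019 EUR)
    "price_analytics": (DistributionSpec("fixed", 1918.0, 100.0, 20000.0), False),
    "cost_treat": (DistributionSpec("gamma", 100.0, 57.0, 155.0), False),
    "cost_icu_day": (DistributionSpec("gamma", 686.0, 392.0, 1060.0), False),
    "cost_ward_day": (DistributionSpec("gamma", 298.0, 170.0, 460.0), False),
    "wean_reduction": (DistributionSpec("beta_pert", 0.10, 0.00, 0.35), True),
    # annual discount rates (no distribution: fixed in PSA, varied in tornado)
    "disc_costs": (DistributionSpec("fixed", 0.035, 0.03, 0.05), True),
    "disc_health": (DistributionSpec("fixed", 0.035, 0.01, 0.05), True),
}

FRACTION_FIELDS = frozenset(k for k, (_, frac) in _DEFAULTS.items() if frac)

_PROBABILITY_FIELDS = frozenset(
    {
        "sens", "spec", "prior", "eff",
        "surv_icu_ieev", "surv_icu_no", "surv_hosp_ieev", "surv_hosp_no",
        "u_icu", "u_ward", "u_y1", "u_y2_10", "u_gt10",
        "wean_reduction", "disc_costs", "disc_health",
    }
)
_POSITIVE_FIELDS = frozenset(
    {"los_icu_ieev", "los_icu_no", "mv_ieev", "mv_no", "los_ward",
     "hr_post_icu", "cost_icu_day", "cost_ward_day"}
)
# monetary inputs that may legitimately be zero (break-even evaluates price 0)
_NONNEGATIVE_FIELDS = frozenset({"price_analytics", "cost_treat"})


@dataclass(frozen=True)
class ParameterSet:
    """Validated, immutable container for every model input.

    ``dists`` maps each field name to its :class:`DistributionSpec`; the
    ``base`` of each spec is kept in sync with the field value on
    :meth:`replace`, so a modified set can be re-used for sensitivity and
    probabilistic analyses around the modified point.
    """

    sens: float
    spec: float
    prior: float
    eff: float
    surv_icu_ieev: float
    surv_icu_no: float
    surv_hosp_ieev: float
    surv_hosp_no: float
    hr_post_icu: float
    u_icu: float
    u_ward: float
    u_y1: float
    u_y2_10: float
    u_gt10: float
    los_icu_ieev: float
    los_icu_no: float
    mv_ieev: float
    mv_no: float
    los_ward: float
    price_analytics: float
    cost_treat: float
    cost_icu_day: float
    cost_ward_day: float
    wean_reduction: float
    disc_costs: float
    disc_health: float
    dists: Mapping[str, DistributionSpec] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not v > 0.0:
                raise ParameterError(f"{name}={v} must be > 0")
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if v < 0.0:
                raise ParameterError(f"{name}={v} must be >= 0")
        if self.mv_ieev > self.los_icu_ieev:
            raise ParameterError(
                f"mv_ieev={self.mv_ieev} exceeds los_icu_ieev={self.los_icu_ieev}"
            )
        if self.mv_no > self.los_icu_no:
            raise ParameterError(
                f"mv_no={self.mv_no} exceeds los_icu_no={self.los_icu_no}"
            )
        if self.surv_hosp_ieev > self.surv_icu_ieev:
            raise ParameterError(
                "surv_hosp_ieev exceeds surv_icu_ieev "
                f"({self.surv_hosp_ieev} > {self.surv_icu_ieev})"
            )
        if self.surv_hosp_no > self.surv_icu_no:
            raise ParameterError(
                "surv_hosp_no exceeds surv_icu_no "
                f"({self.surv_hosp_no} > {self.surv_icu_no})"
            )

    # -- construction / derivation ------------------------------------------

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a new set with ``overrides`` applied and re-validated.

        Each overridden field's distribution base (and, if the new value falls
        outside the old range, its low/high) follows the new value.
        """
        unknown = set(overrides) - set(value_field_names())
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        dists = dict(self.dists)
        for name, value in overrides.items():
            d = dists.get(name)
            if d is not None:
                dists[name] = DistributionSpec(
                    d.family, value, min(d.low, value), max(d.high, value)
                )
        return dataclasses.replace(self, dists=dists, **overrides)

    def to_dict(self, include_dists: bool = True) -> dict[str, Any]:
        """Serialize to a plain dict (round-trips through load_parameters)."""
        out: dict[str, Any] = {"units": "fraction"}
        for name in value_field_names():
            d = self.dists.get(name)
            if include_dists and d is not None:
                out[name] = {
                    "base": getattr(self, name),
                    "low": d.low,
                    "high": d.high,
                    "family": d.family,
                }
            else:
                out[name] = getattr(self, name)
        return out

    def values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in value_field_names()}


def value_field_names() -> tuple[str, ...]:
    return tuple(f.name for f in fields(ParameterSet) if f.name != "dists")


def default_config_path() -> Path:
    """Path of the packaged base-case configuration file."""
    return Path(__file__).parent / "data" / "default_parameters.yaml"


def _coerce_entry(name: str, raw: Any, scale: float) -> tuple[float, DistributionSpec]:
    default_spec, _ = _DEFAULTS[name]
    s = scale if name in FRACTION_FIELDS else 1.0
    if isinstance(raw, Mapping):
        unknown = set(raw) - {"base", "low", "high", "family"}
        if unknown:
            raise ParameterError(
                f"unknown sub-key(s) {sorted(unknown)} for parameter {name!r}"
            )
        base = float(raw.get("base", default_spec.base / s)) * s
        low = float(raw.get("low", default_spec.low / s)) * s
        high = float(raw.get("high", default_spec.high / s)) * s
        family = str(raw.get("family", default_spec.family))
        spec = DistributionSpec(family, base, low, high)
    else:
        base = float(raw) * s
        spec = DistributionSpec(
            default_spec.family,
            base,
            min(default_spec.low, base),
            max(default_spec.high, base),
        )
    return base, spec


def load_parameters(config_source: str | Path | Mapping[str, Any] | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a config mapping or file.

    Parameters
    ----------
    config_source
        ``None`` for the packaged base-case defaults, a path to a YAML/JSON
        file, or an already-parsed mapping.  Each key is a parameter name
        whose value is either a scalar or a mapping with ``base``/``low``/
        ``high``/``family`` sub-keys.  The optional ``units`` key
        (``fraction`` | ``percent``) states how probability-like rows are
        written; the default file uses fractions.

    Raises
    ------
    ParameterError
        On unknown keys (nothing is silently ignored) or any invariant
        violation, naming the offending field.
    """
    if config_source is None:
        raw: dict[str, Any] = {}
    elif isinstance(config_source, Mapping):
        raw = dict(config_source)
    else:
        text = Path(config_source).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, Mapping):
            raise ParameterError(
                f"configuration {config_source} does not parse to a mapping"
            )
        raw = dict(loaded)

    units = str(raw.pop("units", "fraction")).lower()
    if units not in ("fraction", "percent"):
        raise ParameterError(f"units must be 'fraction' or 'percent', got {units!r}")
    scale = 0.01 if units == "percent" else 1.0

    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ParameterError(f"unknown parameter(s) in configuration: {sorted(unknown)}")

    values: dict[str, float] = {}
    dists: dict[str, DistributionSpec] = {}
    for name, (default_spec, _) in _DEFAULTS.items():
        if name in raw:
            values[name], dists[name] = _coerce_entry(name, raw[name], scale)
        else:
            values[name], dists[name] = default_spec.base, default_spec
    return ParameterSet(dists=dists, **values)


def default_parameters() -> ParameterSet:
    """The base-case parameter set."""
    return load_parameters(None)


# Scenario presets: partial overrides applied on top of any parameter set.
SCENARIO_PRESETS: dict[str, dict[str, float]] = {
    "base": {},
    "worst": {
        "price_analytics": 20000.0,
        "cost_treat": 155.0,
        "prior": 0.10,
        "sens": 0.79,
        "spec": 0.80,
        "eff": 0.0,
    },
    "best": {
        "price_analytics": 100.0,
        "cost_treat": 57.0,
        "prior": 0.50,
        "sens": 0.94,
        "spec": 1.00,
        "eff": 0.50,
    },
    "high_icu_cost": {"cost_icu_day": 2153.0},
}


def apply_scenario(params: ParameterSet, preset: str) -> ParameterSet:
    """Return ``params`` with the named scenario preset's overrides applied."""
    try:
        overrides = SCENARIO_PRESETS[preset]
    except KeyError:
        raise ParameterError(
            f"unknown scenario {preset!r}; valid names: {sorted(SCENARIO_PRESETS)}"
        ) from None
    if not overrides:
        return params
    return params.replace(**overrides)
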