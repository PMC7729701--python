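"""Synthetic patient-level ICU cohorts and parameter re-estimation.

The observational cohort behind the model's "hospital data" rows (110
ventilated patients, ~38% prevalence of ineffective effort events) is not
publicly deposited.  This module generates synthetic cohorts with the same
structure — an IEEV flag, group-specific ICU stay / ventilation days drawn
from gamma distributions centred (by median) on the model inputs, and ICU /
hospital survival flags — and re-estimates the model inputs from such
records, so the full data -> parameters -> model pipeline is exercisable
end to end.

The dispersion of the stay distributions is a generator knob (default
coefficient of variation 0.35); the source study publishes only centres and
ranges, so no claim is made about its true dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import ParameterSet

__all__ = [
    "COHORT_COLUMNS",
    "Estimate",
    "EstimatedParameters",
    "generate_cohort",
    "estimate_parameters",
    "read_cohort_csv",
    "write_cohort_csv",
]

COHORT_COLUMNS = (
    "patient_id",
    "has_ieev",
    "icu_los_days",
    "mv_days",
    "survived_icu",
    "survived_hospital",
)


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a 95% interval."""

    value: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.value <= self.high):
            raise ValueError(
                f"estimate {self.value} outside its own interval "
                f"[{self.low}, {self.high}]"
            )

    def covers(self, truth: float) -> bool:
        return self.low <= truth <= self.high


@dataclass(frozen=True)
class EstimatedParameters:
    """Model inputs re-estimated from a patient-level cohort."""

    prior: Estimate
    surv_icu_ieev: Estimate
    surv_icu_no: Estimate
    surv_hosp_ieev: Estimate
    surv_hosp_no: Estimate
    los_icu_ieev: Estimate
    los_icu_no: Estimate
    mv_ieev: Estimate
    mv_no: Estimate

    def as_dict(self) -> dict[str, Estimate]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def point_overrides(self) -> dict[str, float]:
        """Point estimates keyed by ParameterSet field name."""
        return {name: est.value for name, est in self.as_dict().items()}


def _gamma_with_median(center: float, cv: float) -> tuple[float, float]:
    """Gamma (shape, scale) with coefficient of variation ``cv`` and median
    at ``center``."""
    shape = 1.0 / (cv * cv)
    unit_median = stats.gamma.ppf(0.5, shape)
    return shape, center / unit_median


def _mv_gamma_clip_calibrated(
    mv_center: float, los_shape: float, los_scale: float, cv: float
) -> tuple[float, float]:
    """Gamma (shape, scale) for ventilation days whose *post-clipping* median
    equals ``mv_center``.

    Ventilation days are clipped to the ICU stay, so the clipped variable is
    ``min(MV, LOS)`` with CDF ``F_mv(m) + (1 - F_mv(m)) * F_los(m)`` under
    independence of the raw draws; the scale is solved so this CDF is 1/2 at
    the requested centre."""
    shape = 1.0 / (cv * cv)
    p_los = stats.gamma.cdf(mv_center / los_scale, los_shape)
    target = (0.5 - p_los) / (1.0 - p_los)
    if target <= 0.0:
        raise ValueError(
            f"ventilation-day centre {mv_center} is not below the median of "
            "the ICU-stay distribution; cannot calibrate the clipped median"
        )
    return shape, mv_center / stats.gamma.ppf(target, shape)


def generate_cohort(
    n: int,
    params: ParameterSet,
    seed: int,
    los_dispersion: float = 0.35,
) -> pd.DataFrame:
    """Draw ``n`` synthetic patient records at the given parameter values.

    IEEV status is Bernoulli(``prior``); per group, ICU stay and ventilation
    days come from gamma distributions whose medians equal the group's model
    inputs and whose coefficient of variation is ``los_dispersion``
    (ventilation days clipped to the ICU stay); survival flags are Bernoulli
    with the group probabilities, hospital survival conditional on ICU
    survival.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if los_dispersion <= 0.0:
        raise ValueError("los_dispersion must be > 0")
    rng = np.random.default_rng(seed)

    has_ieev = rng.random(n) < params.prior
    los = np.empty(n)
    mv = np.empty(n)
    surv_icu = np.empty(n, dtype=bool)
    surv_hosp = np.empty(n, dtype=bool)

    group_inputs = {
        True: (params.los_icu_ieev, params.mv_ieev,
               params.surv_icu_ieev, params.surv_hosp_ieev),
        False: (params.los_icu_no, params.mv_no,
                params.surv_icu_no, params.surv_hosp_no),
    }
    for flag, (c_los, c_mv, s_icu, s_hosp) in group_inputs.items():
        idx = np.flatnonzero(has_ieev == flag)
        if idx.size == 0:
            continue
        k_los, th_los = _gamma_with_median(c_los, los_dispersion)
        k_mv, th_mv = _mv_gamma_clip_calibrated(c_mv, k_los, th_los, los_dispersion)
        los[idx] = rng.gamma(k_los, th_los, size=idx.size)
        mv[idx] = np.minimum(rng.gamma(k_mv, th_mv, size=idx.size), los[idx])
        surv_icu[idx] = rng.random(idx.size) < s_icu
        # hospital survival conditional on leaving the ICU alive
        cond = s_hosp / s_icu if s_icu > 0 else 0.0
        surv_hosp[idx] = surv_icu[idx] & (rng.random(idx.size) < cond)

    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "has_ieev": has_ieev,
            "icu_los_days": los,
            "mv_days": mv,
            "survived_icu": surv_icu,
            "survived_hospital": surv_hosp,
        }
    )


def _proportion_ci(successes: int, total: int) -> Estimate:
    """Exact (Clopper-Pearson) binomial proportion with 95% interval."""
    if total == 0:
        raise ValueError("empty group")
    p = successes / total
    alpha = 0.05
    low = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, total - successes + 1)
    )
    high = 1.0 if successes == total else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, total - successes)
    )
    return Estimate(p, low, high)


def _median_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int
) -> Estimate:
    """Median with a percentile-bootstrap 95% interval."""
    med = float(np.median(values))
    if values.size == 1:
        return Estimate(med, med, med)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = np.median(values[idx], axis=1)
    low = float(np.percentile(boot, 2.5))
    high = float(np.percentile(boot, 97.5))
    return Estimate(med, min(low, med), max(high, med))


def estimate_parameters(
    cohort: pd.DataFrame,
    seed: int = 0,
    n_boot: int = 500,
) -> EstimatedParameters:
    """Re-estimate model inputs from patient-level records.

    Prevalence and survivals are proportions with exact binomial intervals;
    stay and ventilation centres are group medians with seeded bootstrap
    intervals.  Raises if either IEEV group is empty.
    """
    cohort = _normalize_cohort(cohort)
    rng = np.random.default_rng(seed)

    n = len(cohort)
    n_ieev = int(cohort["has_ieev"].sum())
    for label, size in (("with_ieev", n_ieev), ("without_ieev", n - n_ieev)):
        if size == 0:
            raise ValueError(f"cannot estimate parameters: group {label} is empty")

    out: dict[str, Estimate] = {"prior": _proportion_ci(n_ieev, n)}
    for flag, suffix in ((True, "ieev"), (False, "no")):
        grp = cohort[cohort["has_ieev"] == flag]
        out[f"surv_icu_{suffix}"] = _proportion_ci(
            int(grp["survived_icu"].sum()), len(grp)
        )
        out[f"surv_hosp_{suffix}"] = _proportion_ci(
            int(grp["survived_hospital"].sum()), len(grp)
        )
        out[f"los_icu_{suffix}"] = _median_ci(
            grp["icu_los_days"].to_numpy(float), rng, n_boot
        )
        out[f"mv_{suffix}"] = _median_ci(
            grp["mv_days"].to_numpy(float), rng, n_boot
        )
    return EstimatedParameters(**out)


_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


def _coerce_flag(series: pd.Series, name: str) -> pd.Series:
    def one(v) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise ValueError(f"unrecognized boolean {v!r} in column {name}")

    return series.map(one)


def _normalize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing column(s) {sorted(missing)}")
    out = cohort.copy()
    for col in ("has_ieev", "survived_icu", "survived_hospital"):
        out[col] = _coerce_flag(out[col], col)
    if (out["mv_days"] > out["icu_los_days"] + 1e-9).any():
        raise ValueError("mv_days exceeds icu_los_days for some records")
    if (out["survived_hospital"] & ~out["survived_icu"]).any():
        raise ValueError("survived_hospital set for a record that died in the ICU")
    return out


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (flags may be 0/1 or true/false)."""
    return _normalize_cohort(pd.read_csv(path))


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    out = cohort.copy()
    for col in ("has_ieev", "survived_icu", "survived_hospital"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
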