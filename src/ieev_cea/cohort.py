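"""Four-state Markov cohort model: ICU -> hospital ward -> discharged -> dead.

The cohort enters the ICU at admission.  Cycle 1 has length equal to the
arm's expected ICU length of stay; survivors (expected ICU survival) move to
the ward.  Cycle 2 has length equal to the post-ICU hospital stay; ward
occupants are discharged with the conditional ward survival (hospital
survival / ICU survival of the mixture), the rest die.  From then on annual
cycles extrapolate survival with the general-population hazard of a life
table multiplied by a constant post-discharge hazard ratio, with a
half-cycle correction on the annual cycles.

The two in-hospital cycles use their exact observed lengths with full-length
accrual and end-of-cycle transitions: the lengths of stay are directly
observed cohort medians, so there is no within-cycle timing uncertainty to
correct for, and short-stay outcomes then reproduce the decision-tree
mixture averages exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .decision_tree import ArmMix, expected_short_term, profiles_from_params
from .life_table import LifeTable
from .parameters import ParameterSet

__all__ = [
    "DEFAULT_AGE_AT_ADMISSION",
    "CohortTrace",
    "CohortOutcome",
    "post_discharge_trace",
    "run_cohort",
]

# Mean age at ICU admission of the modelled cohort (years).  The source
# cohort's mean age is not published; 62 is a representative mixed
# medical-surgical ICU mean and is a documented, overridable configuration
# value, not a constant of the model.
DEFAULT_AGE_AT_ADMISSION = 62.0

DAYS_PER_YEAR = 365.0
_ALIVE_EPS = 1e-8

_STATES = ("icu", "ward", "discharged", "dead")


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle record of one arm's cohort run.

    Columns: ``cycle``, ``t_start`` (years since admission), ``length``
    (years), the four state occupancies, and the discounted life-year and
    QALY increments of the cycle.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        occ = self.frame[list(_STATES)].to_numpy()
        sums = occ.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-10):
            raise ValueError("state occupancies must sum to 1 in every cycle")
        dead = self.frame["dead"].to_numpy()
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("dead-state occupancy must be non-decreasing")
        if np.any(self.frame["ly_disc"].to_numpy() < -1e-15):
            raise ValueError("discounted life-year increments must be >= 0")
        if np.any(self.frame["qaly_disc"].to_numpy() < -1e-15):
            raise ValueError("discounted QALY increments must be >= 0")

    @property
    def life_years(self) -> float:
        return float(self.frame["ly_disc"].sum())

    @property
    def qalys(self) -> float:
        return float(self.frame["qaly_disc"].sum())


class CohortOutcome(NamedTuple):
    life_years: float
    qalys: float
    trace: CohortTrace


def post_discharge_trace(
    age_at_discharge: float,
    hr: float,
    lt: LifeTable,
    disc_health: float,
    utilities: tuple[float, float, float],
    t0: float,
    alive0: float = 1.0,
) -> pd.DataFrame:
    """Annual post-discharge cycles for a cohort fraction ``alive0``.

    Death probability in year ``k`` is ``1 - exp(-hr * h(age + k))`` where
    ``h`` is the life table's integrated annual hazard.  Life years and QALYs
    per cycle use the half-cycle-corrected mean of the start- and
    end-of-cycle alive fractions, a utility picked by years since discharge
    (year 1, years 2-10, beyond 10) and a mid-cycle discount factor
    ``(1 + disc_health) ** -(t0 + k + 0.5)``.  Runs until the terminal age or
    until the alive fraction is negligible.
    """
    if hr <= 0.0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    u_y1, u_y2_10, u_gt10 = utilities

    age0 = int(np.floor(age_at_discharge))
    if age0 < lt.start_age or age0 > lt.terminal_age:
        raise ValueError(f"age {age_at_discharge} outside life table range")

    n_years = lt.terminal_age - age0 + 1
    hazards = np.array([lt.hazard(age0 + k) for k in range(n_years)])
    p_die = -np.expm1(-hr * hazards)  # 1 - exp(-hr*h), exact at h = inf
    alive = alive0 * np.concatenate([[1.0], np.cumprod(1.0 - p_die)])

    # truncate once the cohort fraction is negligible
    keep = alive[:-1] > _ALIVE_EPS
    n = int(keep.sum())
    alive = alive[: n + 1]

    k = np.arange(n)
    mean_alive = 0.5 * (alive[:-1] + alive[1:])
    disc = (1.0 + disc_health) ** -(t0 + k + 0.5)
    util = np.where(k == 0, u_y1, np.where(k < 10, u_y2_10, u_gt10))

    return pd.DataFrame(
        {
            "cycle": k + 3,  # cycles 1-2 are the in-hospital cycles
            "t_start": t0 + k.astype(float),
            "length": 1.0,
            "icu": 0.0,
            "ward": 0.0,
            "discharged": alive[:-1],
            "dead": 1.0 - alive[:-1],
            "ly_disc": mean_alive * disc,
            "qaly_disc": mean_alive * util * disc,
        }
    )


def run_cohort(
    arm_mix: ArmMix,
    params: ParameterSet,
    lt: LifeTable,
    age_at_admission: float = DEFAULT_AGE_AT_ADMISSION,
) -> CohortOutcome:
    """Run one arm's cohort through the four-state model.

    Returns discounted life years and QALYs per patient entering the ICU,
    together with the full :class:`CohortTrace`.
    """
    with_p, without_p = profiles_from_params(params)
    st = expected_short_term(arm_mix, with_p, without_p)

    s_icu = st.surv_icu
    s_hosp = 1.0 - st.hosp_mortality
    # conditional ward survival: per-profile hospital/ICU survival ratios
    # weighted by each profile's share of ward entrants, which reduces to the
    # mixture ratio
    s_ward = s_hosp / s_icu
    if 1.0 < s_ward <= 1.0 + 1e-12:  # floating-point noise in the ratio
        s_ward = 1.0
    if not 0.0 <= s_ward <= 1.0:
        raise ValueError(
            f"conditional ward survival {s_ward:.4f} outside [0, 1] "
            f"(hospital survival {s_hosp:.4f}, ICU survival {s_icu:.4f})"
        )

    dh = params.disc_health
    L1 = st.los_icu / DAYS_PER_YEAR
    L2 = params.los_ward / DAYS_PER_YEAR

    rows = [
        # cycle 1: everyone in the ICU for the expected ICU stay
        {
            "cycle": 1, "t_start": 0.0, "length": L1,
            "icu": 1.0, "ward": 0.0, "discharged": 0.0, "dead": 0.0,
            "ly_disc": L1,
            "qaly_disc": params.u_icu * L1,
        },
        # cycle 2: ICU survivors on the general ward
        {
            "cycle": 2, "t_start": L1, "length": L2,
            "icu": 0.0, "ward": s_icu, "discharged": 0.0, "dead": 1.0 - s_icu,
            "ly_disc": s_icu * L2 * (1.0 + dh) ** -L1,
            "qaly_disc": s_icu * params.u_ward * L2 * (1.0 + dh) ** -L1,
        },
    ]
    head = pd.DataFrame(rows)

    t0 = L1 + L2
    tail = post_discharge_trace(
        age_at_discharge=age_at_admission + t0,
        hr=params.hr_post_icu,
        lt=lt,
        disc_health=dh,
        utilities=(params.u_y1, params.u_y2_10, params.u_gt10),
        t0=t0,
        alive0=s_hosp,
    )
    trace = CohortTrace(pd.concat([head, tail], ignore_index=True))
    return CohortOutcome(trace.life_years, trace.qalys, trace)
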