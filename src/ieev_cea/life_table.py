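"""Period life tables for post-discharge survival extrapolation.

The national life table behind the general-population baseline hazard is not
bundled with the model; instead a synthetic stand-in is generated from a
Gompertz hazard ``h(a) = alpha * exp(b * a)`` whose level ``alpha`` is
calibrated numerically so that period life expectancy at birth matches a
requested value.  Any two-column (age, annual death probability) CSV can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["LifeTable", "build_life_table", "default_life_table_path"]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``q`` indexed by integer age.

    ``q[i]`` is the probability of dying between ages ``start_age + i`` and
    ``start_age + i + 1``; the final entry (terminal age) must be 1 so the
    table closes.
    """

    start_age: int
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if np.any((q < 0.0) | (q > 1.0)):
            raise ValueError("death probabilities must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ValueError("q at the terminal age must equal 1")

    @property
    def terminal_age(self) -> int:
        return self.start_age + self.q.size - 1

    def q_at(self, age: float) -> float:
        """Annual death probability for the year of age containing ``age``."""
        idx = int(np.floor(age)) - self.start_age
        if idx < 0 or idx >= self.q.size:
            raise ValueError(
                f"age {age} outside life table range "
                f"[{self.start_age}, {self.terminal_age}]"
            )
        return float(self.q[idx])

    def hazard(self, age: float) -> float:
        """Integrated annual hazard ``-log(1 - q)`` (inf at the terminal age)."""
        q = self.q_at(age)
        if q >= 1.0:
            return np.inf
        return float(-np.log1p(-q))

    def survival_from(self, age: float) -> np.ndarray:
        """Survival curve ``l_k`` at integer year offsets from ``age``.

        ``l_0 = 1``; ``l_k`` multiplies the annual survival probabilities of
        the year-of-age bands starting at ``floor(age)``.
        """
        idx = int(np.floor(age)) - self.start_age
        if idx < 0 or idx >= self.q.size:
            raise ValueError(f"age {age} outside life table range")
        surv = np.concatenate([[1.0], np.cumprod(1.0 - self.q[idx:])])
        return surv

    def life_expectancy(self, age: float = 0.0) -> float:
        """Remaining period life expectancy at ``age`` (trapezoid rule)."""
        l = self.survival_from(age)
        return float(0.5 * (l[:-1] + l[1:]).sum())

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.start_age, self.terminal_age + 1)
        return pd.DataFrame({"age": ages, "q": self.q})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "q"} - set(df.columns)
        if missing:
            raise ValueError(f"life table CSV missing column(s) {sorted(missing)}")
        df = df.sort_values("age")
        ages = df["age"].to_numpy()
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + ages.size)):
            raise ValueError("life table ages must be consecutive integers")
        return cls(start_age=int(ages[0]), q=df["q"].to_numpy(dtype=float))


def default_life_table_path() -> Path:
    """Packaged synthetic life table (Gompertz stand-in, expectancy 81.0)."""
    return Path(__file__).parent / "data" / "life_table_synthetic.csv"


def _gompertz_table(alpha: float, slope: float, start_age: int, terminal_age: int) -> np.ndarray:
    ages = np.arange(start_age, terminal_age + 1, dtype=float)
    h = alpha * np.exp(slope * ages)
    q = 1.0 - np.exp(-h)
    q[-1] = 1.0
    return q


def build_life_table(
    life_expectancy_at_birth: float,
    gompertz_slope: float = 0.085,
    start_age: int = 0,
    terminal_age: int = 110,
) -> LifeTable:
    """Calibrate a Gompertz life table to a target life expectancy at birth.

    The hazard level ``alpha`` is solved with Brent's method so that the
    period life expectancy recomputed from the returned table equals the
    target.  Raises a calibration error if no ``alpha`` in (1e-12, 1) works.
    """
    if not 0.0 < life_expectancy_at_birth < terminal_age:
        raise ValueError(
            "life expectancy at birth must lie in (0, terminal_age)"
        )
    if gompertz_slope <= 0.0:
        raise ValueError("gompertz_slope must be > 0")

    def gap(alpha: float) -> float:
        q = _gompertz_table(alpha, gompertz_slope, start_age, terminal_age)
        lt = LifeTable(start_age=start_age, q=q)
        return lt.life_expectancy(start_age) - life_expectancy_at_birth

    lo, hi = 1e-12, 1.0 - 1e-12
    if gap(lo) < 0.0 or gap(hi) > 0.0:
        raise ValueError(
            "cannot calibrate Gompertz level to requested life expectancy "
            f"{life_expectancy_at_birth} with slope {gompertz_slope}"
        )
    alpha = brentq(gap, lo, hi, xtol=1e-14, rtol=1e-12)
    return LifeTable(
        start_age=start_age,
        q=_gompertz_table(alpha, gompertz_slope, start_age, terminal_age),
    )
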