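"""Age- and sex-indexed background mortality from a period life table.

The Markov engine ages the cohort one year per cycle and looks up the annual
probability of death ``qx`` at the cohort's attained (floored) age.  Beyond
the last tabulated age ``qx`` is clamped to 1, which guarantees the chain is
absorbed within the table span regardless of the modelled horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "LifeTableError", "read_life_table", "annual_death_probability", "life_expectancy"]


class LifeTableError(ValueError):
    """Malformed or incomplete life-table input."""


@dataclass
class LifeTable:
    """Annual death probabilities for one sex over a contiguous age range."""

    sex_label: str
    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        if self.ages.size == 0:
            raise LifeTableError("life table is empty")
        if self.ages.size != self.qx.size:
            raise LifeTableError("ages and qx must have equal length")
        diffs = np.diff(self.ages)
        if np.any(diffs != 1):
            gap = int(self.ages[np.argmax(diffs != 1)])
            raise LifeTableError(f"age sequence not contiguous after age {gap}")
        if np.any((self.qx < 0) | (self.qx > 1)):
            bad = int(self.ages[np.argmax((self.qx < 0) | (self.qx > 1))])
            raise LifeTableError(f"qx outside [0, 1] at age {bad}")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_death_probability(self, age: float) -> float:
        """``qx`` at floor(age); 1.0 beyond the terminal age."""
        if age < self.min_age:
            raise LifeTableError(
                f"age {age} below life-table minimum {self.min_age}"
            )
        idx = int(math.floor(age)) - self.min_age
        if idx >= self.ages.size:
            return 1.0
        return float(self.qx[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "sex": self.sex_label, "qx": self.qx}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_life_table(csv_source: str | Path | IO[str], sex_label: str = "female") -> LifeTable:
    """Read a ``age,sex,qx`` CSV and return the table for ``sex_label``."""
    df = pd.read_csv(csv_source)
    missing = {"age", "sex", "qx"} - set(df.columns)
    if missing:
        raise LifeTableError(f"life-table CSV missing columns: {sorted(missing)}")
    df = df[df["sex"].astype(str).str.lower() == sex_label.lower()]
    if df.empty:
        raise LifeTableError(f"no rows for sex {sex_label!r}")
    df = df.sort_values("age")
    if df["age"].duplicated().any():
        raise LifeTableError("duplicate ages in life table")
    return LifeTable(sex_label=sex_label, ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


def annual_death_probability(lt: LifeTable, age: float) -> float:
    """Module-level convenience wrapper for :meth:`LifeTable.annual_death_probability`."""
    return lt.annual_death_probability(age)


def life_expectancy(lt: LifeTable, age: float) -> float:
    """Remaining life expectancy at ``age`` by summing the survival curve.

    Uses the standard half-year continuity correction (deaths mid-year on
    average): e(x) = 0.5 + sum over whole years of cumulative survival.
    """
    survival = 1.0
    total = 0.0
    a = age
    # the terminal clamp guarantees survival reaches 0 within the table span
    for _ in range(lt.max_age - int(math.floor(age)) + 2):
        survival *= 1.0 - lt.annual_death_probability(a)
        total += survival
        a += 1.0
        if survival == 0.0:
            break
    return 0.5 + total
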