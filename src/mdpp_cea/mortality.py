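"""Baseline all-cause mortality by age and sex, and per-cycle death risks.

The model's background mortality is an annual probability of death q(age,
sex). The bundled default table (``data/life_table_us2000_synthetic.csv``)
is a synthetic Gompertz life table calibrated to published year-2000 US
anchor values, covering ages 45-70 for both sexes; any table in the same
CSV layout can be substituted.

State-specific death risk is obtained by (1) mixing the female and male
annual probabilities with the cohort's female fraction, (2) treating the
state's relative risk of death as a hazard ratio, and (3) converting to a
monthly probability: ``q_month = 1 - (1 - q_mix) ** (rr / 12)``. Twelve
successive monthly applications at rr = 1 compound exactly back to the
annual probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "MortalityModel",
    "load_life_table",
    "generate_synthetic_life_table",
    "default_life_table",
    "default_life_table_path",
]

SEXES = ("F", "M")


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability by integer age and sex."""

    ages: np.ndarray  # contiguous integer ages, sorted
    q_female: np.ndarray
    q_male: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        if ages.size == 0 or np.any(np.diff(ages) != 1):
            raise ValueError("life table ages must be contiguous integers")
        for sex, q in (("F", self.q_female), ("M", self.q_male)):
            q = np.asarray(q, dtype=float)
            if q.shape != ages.shape:
                raise ValueError("life table q arrays must match the age grid")
            if np.any(q <= 0.0) or np.any(q >= 1.0):
                bad = ages[(q <= 0.0) | (q >= 1.0)]
                raise ValueError(
                    f"q_annual must lie strictly in (0, 1); offending ages "
                    f"({sex}): {bad.tolist()}"
                )
            if np.any(np.diff(q) < 0.0):
                warnings.warn(
                    f"life table q_annual not non-decreasing with age for sex {sex}",
                    stacklevel=2,
                )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def covers(self, age: int) -> bool:
        return self.min_age <= age <= self.max_age

    def q(self, age: int, sex: str) -> float:
        if not self.covers(age):
            raise ValueError(
                f"age {age} outside life-table coverage "
                f"[{self.min_age}, {self.max_age}]; extend the table"
            )
        i = int(age) - self.min_age
        if sex == "F":
            return float(self.q_female[i])
        if sex == "M":
            return float(self.q_male[i])
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, q in (("F", self.q_female), ("M", self.q_male)):
            for age, qv in zip(self.ages, q):
                rows.append({"age": int(age), "sex": sex, "q_annual": float(qv)})
        return pd.DataFrame(rows)


def load_life_table(path: str | Path, required_span: tuple[int, int] = (45, 70)) -> LifeTable:
    """Load a life table from CSV with columns ``age,sex,q_annual``.

    Duplicate (age, sex) rows are deduplicated (first wins). Raises on any
    gap or missing sex within ``required_span`` and on q outside (0, 1).
    """
    df = pd.read_csv(path)
    missing_cols = {"age", "sex", "q_annual"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"life table {path} missing columns: {sorted(missing_cols)}")
    df = df.drop_duplicates(subset=["age", "sex"], keep="first")
    lo, hi = required_span
    span = range(lo, hi + 1)
    by_sex = {}
    for sex in SEXES:
        sub = df[df["sex"] == sex].set_index("age")["q_annual"]
        absent = [a for a in span if a not in sub.index]
        if absent:
            raise ValueError(
                f"life table {path} missing ages {absent} for sex {sex} "
                f"(required span {lo}-{hi})"
            )
        ages = np.array(sorted(a for a in sub.index if lo <= a <= hi))
        by_sex[sex] = sub.loc[ages].to_numpy(dtype=float)
    return LifeTable(ages=np.arange(lo, hi + 1), q_female=by_sex["F"], q_male=by_sex["M"])


def generate_synthetic_life_table(
    a: float = 8.75e-5,
    b: float = 0.085,
    female_factor: float = 0.57,
    ages: Iterable[int] = range(45, 71),
) -> LifeTable:
    """Synthetic Gompertz life table: male hazard ``a * exp(b * age)``.

    Female mortality multiplies the hazard by ``female_factor``. Defaults
    are calibrated so that q(45), q(55) and q(70) by sex approximate
    published year-2000 US all-cause values. Produces a table that is
    strictly monotone in age whenever ``b > 0``.
    """
    if a <= 0.0:
        raise ValueError("hazard scale a must be positive")
    if b < 0.0:
        raise ValueError("hazard growth b must be non-negative")
    if not (0.0 < female_factor <= 1.0):
        raise ValueError("female_factor must lie in (0, 1]")
    ages_arr = np.asarray(sorted(ages), dtype=int)
    hazard = a * np.exp(b * ages_arr)
    q_male = 1.0 - np.exp(-hazard)
    q_female = 1.0 - np.exp(-female_factor * hazard)
    if np.any(q_male >= 1.0 - 1e-12):
        raise ValueError("parameters yield q >= 1 within the requested age range")
    return LifeTable(ages=ages_arr, q_female=q_female, q_male=q_male)


def default_life_table_path() -> Path:
    from importlib.resources import files

    return Path(str(files("mdpp_cea").joinpath("data/life_table_us2000_synthetic.csv")))


def default_life_table() -> LifeTable:
    """The bundled synthetic year-2000-calibrated life table (ages 45-70)."""
    return load_life_table(default_life_table_path())


@dataclass(frozen=True)
class MortalityModel:
    """Sex-mixed baseline mortality for the modelled cohort.

    The cohort is propagated as a single pooled arm, so female and male
    annual probabilities are mixed with the cohort's female fraction before
    the hazard-scale relative risk and monthly conversion are applied.
    """

    life_table: LifeTable
    fraction_female: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_female <= 1.0):
            raise ValueError("fraction_female must lie in [0, 1]")

    def annual_q_mix(self, age: int) -> float:
        w = self.fraction_female
        return w * self.life_table.q(age, "F") + (1.0 - w) * self.life_table.q(age, "M")

    def monthly_death_prob(self, age: int, rr: float) -> float:
        """Monthly death probability at ``age`` under hazard ratio ``rr``."""
        if rr <= 0.0:
            raise ValueError("relative risk of death must be positive")
        q_mix = self.annual_q_mix(age)
        q_month = 1.0 - (1.0 - q_mix) ** (rr / 12.0)
        if not (0.0 <= q_month < 1.0):
            raise ValueError(
                f"monthly death probability {q_month} outside [0, 1) at age {age}, rr {rr}"
            )
        return q_month


def monthly_death_prob(m: MortalityModel, age: int, rr: float) -> float:
    """Module-level convenience wrapper for :meth:`MortalityModel.monthly_death_prob`."""
    return m.monthly_death_prob(age, rr)
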