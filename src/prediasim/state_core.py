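"""Core domain types for the diabetes-progression microsimulation.

The model tracks each simulated adult through an annual cycle with a fixed
phase order: (1) mortality decision, (2) intervention application (first
simulated year only), (3) age increment and stochastic BMI update,
(4) glycemic Markov transition.  Glycemic status is a three-state
discretization of fasting glucose (no diabetes <100 mg/dl, prediabetes
100-125 mg/dl, diabetes >125 mg/dl); diabetes is absorbing.  Age is binned
into seventeen 5-year groups (20-25 ... 100+) and BMI into three categories
(normal <25, overweight [25,30), obese >=30 kg/m^2).  All category
intervals are half-open [a, b).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GlycemicState",
    "Gender",
    "BmiCategory",
    "AgeGroup",
    "Individual",
    "ANNUAL_CYCLE_PHASES",
    "N_AGE_GROUPS",
    "AGE_GROUP_LABELS",
    "BMI_CATEGORY_BOUNDS",
    "categorize_bmi",
    "categorize_age",
    "age_group_of",
    "bmi_category_of",
]


class GlycemicState(enum.IntEnum):
    """Three-state fasting-glucose discretization (ordinal codes 1, 2, 3)."""

    NO_DIABETES = 1
    PREDIABETES = 2
    DIABETES = 3

    @classmethod
    def parse(cls, value) -> "GlycemicState":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        key = str(value).strip().upper()
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown glycemic state: {value!r}") from None


class Gender(enum.IntEnum):
    MALE = 0
    FEMALE = 1

    @classmethod
    def parse(cls, value) -> "Gender":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        key = str(value).strip().upper()
        if key in ("M", "MALE"):
            return cls.MALE
        if key in ("F", "FEMALE"):
            return cls.FEMALE
        raise ValueError(f"unknown gender: {value!r}")


class BmiCategory(enum.IntEnum):
    NORMAL = 0
    OVERWEIGHT = 1
    OBESE = 2

    @classmethod
    def parse(cls, value) -> "BmiCategory":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        key = str(value).strip().upper()
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown BMI category: {value!r}") from None


#: Boundaries between BMI categories (kg/m^2); intervals are half-open [a, b).
BMI_CATEGORY_BOUNDS = (25.0, 30.0)

#: Number of 5-year age groups: 20-25, 25-30, ..., 95-100, 100+.
N_AGE_GROUPS = 17

AGE_GROUP_LABELS = tuple(
    f"{20 + 5 * i}-{25 + 5 * i}" for i in range(N_AGE_GROUPS - 1)
) + ("100+",)

#: Phase order of the annual cycle, identical for every individual in a year.
ANNUAL_CYCLE_PHASES = ("mortality", "intervention", "age_bmi", "glycemic")


class AgeGroup(int):
    """Index 0..16 into the 5-year age bands 20-25, 25-30, ..., 100+."""

    def __new__(cls, index: int):
        index = int(index)
        if not 0 <= index < N_AGE_GROUPS:
            raise ValueError(f"age group index must be in 0..{N_AGE_GROUPS - 1}, got {index}")
        return super().__new__(cls, index)

    @property
    def label(self) -> str:
        return AGE_GROUP_LABELS[int(self)]


def categorize_bmi(bmi: float) -> BmiCategory:
    """Map a continuous BMI (kg/m^2) to its category.

    Intervals are half-open: normal [0, 25), overweight [25, 30),
    obese [30, inf).  Values below the nominal normal-weight lower bound
    still map to NORMAL; the underweight guard (BMI < 18.5) belongs to the
    intervention logic, not the category map.
    """
    bmi = float(bmi)
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi!r}")
    if bmi < BMI_CATEGORY_BOUNDS[0]:
        return BmiCategory.NORMAL
    if bmi < BMI_CATEGORY_BOUNDS[1]:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE


def categorize_age(age: float) -> AgeGroup:
    """Map an adult age (years, >=20) to its 5-year group index.

    group = floor((min(age, 100) - 20) / 5); ages 100 and above share the
    final open-ended band.
    """
    age = float(age)
    if not np.isfinite(age) or age < 20:
        raise ValueError(f"age must be >= 20, got {age!r}")
    return AgeGroup(int(min(age, 100.0) - 20.0) // 5 if age < 100 else N_AGE_GROUPS - 1)


def age_group_of(age: np.ndarray) -> np.ndarray:
    """Vectorized ``categorize_age`` for integer/float age arrays."""
    a = np.minimum(np.asarray(age, dtype=np.float64), 100.0)
    if np.any(a < 20):
        raise ValueError("all ages must be >= 20")
    return np.minimum(((a - 20.0) // 5.0).astype(np.int64), N_AGE_GROUPS - 1)


def bmi_category_of(bmi: np.ndarray) -> np.ndarray:
    """Vectorized ``categorize_bmi``; returns int codes 0/1/2."""
    b = np.asarray(bmi, dtype=np.float64)
    if np.any(~np.isfinite(b)) or np.any(b <= 0):
        raise ValueError("all BMI values must be positive and finite")
    return np.digitize(b, BMI_CATEGORY_BOUNDS).astype(np.int64)


@dataclass
class Individual:
    """One simulated person's evolving state.

    ``diabetes_onset_year`` is the simulation-year index at which the
    individual entered the (absorbing) diabetes state; -1 marks onset before
    the simulation started (prevalent at baseline); ``None`` marks no onset.
    """

    id: int
    age: int
    gender: Gender
    bmi: float
    glycemic: GlycemicState
    alive: bool = True
    diabetes_onset_year: Optional[int] = None
    death_year: Optional[int] = None
    ever_diabetic: bool = field(default=False)

    def __post_init__(self) -> None:
        self.gender = Gender.parse(self.gender)
        self.glycemic = GlycemicState.parse(self.glycemic)
        if self.age < 20:
            raise ValueError(f"age must be >= 20, got {self.age}")
        if not self.bmi > 0:
            raise ValueError(f"BMI must be positive, got {self.bmi}")
        if self.glycemic == GlycemicState.DIABETES:
            self.ever_diabetic = True
            if self.diabetes_onset_year is None:
                self.diabetes_onset_year = -1
        self.validate()

    def validate(self) -> None:
        if self.ever_diabetic != (self.diabetes_onset_year is not None):
            raise ValueError("diabetes_onset_year must be set iff ever_diabetic")
        if self.alive == (self.death_year is not None):
            raise ValueError("death_year must be set iff not alive")
        if self.glycemic == GlycemicState.DIABETES and not self.ever_diabetic:
            raise ValueError("glycemic DIABETES implies ever_diabetic")

    @property
    def age_group(self) -> AgeGroup:
        return categorize_age(self.age)

    @property
    def bmi_category(self) -> BmiCategory:
        return categorize_bmi(self.bmi)
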