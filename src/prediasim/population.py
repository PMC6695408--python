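"""Baseline population construction and annual entrants.

The initial population is sampled from a joint distribution over
age group x gender x BMI category x glycemic state; each year of the
simulation a cohort of new 20-24 year-olds enters according to an
``EntrySchedule``.  Agents live in a structure-of-arrays ``Cohort`` so the
annual-cycle kernels can operate on the whole population at once; dead
agents are retained (flagged) so denominators, paired-arm alignment and
averted-case bookkeeping stay well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

from .state_core import (
    N_AGE_GROUPS,
    BmiCategory,
    Gender,
    GlycemicState,
    Individual,
)

__all__ = [
    "Cohort",
    "PopulationDistribution",
    "EntrySchedule",
    "build_initial_population",
    "inject_entrants",
    "read_population_distribution",
    "write_population_distribution",
    "read_entry_schedule",
    "write_entry_schedule",
]

#: Continuous-BMI sampling interval per category (upper bound of OBESE is
#: configurable on the distribution; 60 kg/m^2 by default).
_BMI_INTERVALS = {0: (20.0, 25.0), 1: (25.0, 30.0), 2: (30.0, 60.0)}

_CELL_SHAPE = (N_AGE_GROUPS, 2, 3, 3)


@dataclass
class Cohort:
    """Structure-of-arrays container for the simulated population.

    Arrays are index-aligned with agent ids (``ids[i]`` is the id of row
    ``i``); rows are never removed, so paired runs started from copies of
    the same cohort keep identical id layouts for the whole horizon.
    ``diabetes_onset_year``/``death_year`` use NaN for "never" and -1.0 for
    events that predate the simulation.
    """

    ids: np.ndarray
    age: np.ndarray
    gender: np.ndarray
    bmi: np.ndarray
    glycemic: np.ndarray
    alive: np.ndarray
    diabetes_onset_year: np.ndarray
    death_year: np.ndarray
    ever_diabetic: np.ndarray

    @classmethod
    def empty(cls) -> "Cohort":
        return cls(
            ids=np.empty(0, dtype=np.int64),
            age=np.empty(0, dtype=np.int64),
            gender=np.empty(0, dtype=np.int8),
            bmi=np.empty(0, dtype=np.float64),
            glycemic=np.empty(0, dtype=np.int8),
            alive=np.empty(0, dtype=bool),
            diabetes_onset_year=np.empty(0, dtype=np.float64),
            death_year=np.empty(0, dtype=np.float64),
            ever_diabetic=np.empty(0, dtype=bool),
        )

    @property
    def size(self) -> int:
        return int(self.ids.size)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def copy(self) -> "Cohort":
        return Cohort(**{k: getattr(self, k).copy() for k in self.__dataclass_fields__})

    def append(self, other: "Cohort") -> None:
        for k in self.__dataclass_fields__:
            setattr(self, k, np.concatenate([getattr(self, k), getattr(other, k)]))

    def validate(self) -> None:
        n = self.size
        for k in self.__dataclass_fields__:
            if getattr(self, k).shape != (n,):
                raise ValueError(f"cohort array {k!r} is not aligned")
        if np.any(self.age < 20):
            raise ValueError("cohort contains ages below 20")
        if np.any(self.bmi <= 0):
            raise ValueError("cohort contains non-positive BMI")
        if not np.all(np.isin(self.glycemic, [1, 2, 3])):
            raise ValueError("cohort contains invalid glycemic codes")
        onset_set = ~np.isnan(self.diabetes_onset_year)
        if np.any(onset_set != self.ever_diabetic):
            raise ValueError("diabetes_onset_year set iff ever_diabetic violated")
        if np.any(~np.isnan(self.death_year) != ~self.alive):
            raise ValueError("death_year set iff dead violated")
        if np.any((self.glycemic == 3) & ~self.ever_diabetic):
            raise ValueError("DIABETES state without ever_diabetic")

    def to_individuals(self) -> List[Individual]:
        out = []
        for i in range(self.size):
            onset = self.diabetes_onset_year[i]
            death = self.death_year[i]
            out.append(
                Individual(
                    id=int(self.ids[i]),
                    age=int(self.age[i]),
                    gender=Gender(int(self.gender[i])),
                    bmi=float(self.bmi[i]),
                    glycemic=GlycemicState(int(self.glycemic[i])),
                    alive=bool(self.alive[i]),
                    diabetes_onset_year=None if np.isnan(onset) else int(onset),
                    death_year=None if np.isnan(death) else int(death),
                    ever_diabetic=bool(self.ever_diabetic[i]),
                )
            )
        return out

    @classmethod
    def from_individuals(cls, people: Iterable[Individual]) -> "Cohort":
        people = list(people)
        nan = float("nan")
        return cls(
            ids=np.array([p.id for p in people], dtype=np.int64),
            age=np.array([p.age for p in people], dtype=np.int64),
            gender=np.array([int(p.gender) for p in people], dtype=np.int8),
            bmi=np.array([p.bmi for p in people], dtype=np.float64),
            glycemic=np.array([int(p.glycemic) for p in people], dtype=np.int8),
            alive=np.array([p.alive for p in people], dtype=bool),
            diabetes_onset_year=np.array(
                [nan if p.diabetes_onset_year is None else p.diabetes_onset_year for p in people],
                dtype=np.float64,
            ),
            death_year=np.array(
                [nan if p.death_year is None else p.death_year for p in people], dtype=np.float64
            ),
            ever_diabetic=np.array([p.ever_diabetic for p in people], dtype=bool),
        )


@dataclass
class PopulationDistribution:
    """Joint probability table over age group x gender x BMI category x
    glycemic state, plus the within-category continuous sampling rules.

    ``probs`` has shape (17, 2, 3, 3) and sums to 1.  Continuous BMI within
    a category is sampled uniformly over the category interval (the obese
    interval is truncated at ``bmi_max``); exact ages within a 5-year band
    are sampled uniformly over the integer ages of the band.
    """

    probs: np.ndarray
    bmi_max: float = 60.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.probs.shape != _CELL_SHAPE:
            raise ValueError(
                f"distribution table must have shape {_CELL_SHAPE}, got {self.probs.shape}"
            )
        if np.any(self.probs < 0):
            raise ValueError("distribution contains negative cell probabilities")
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-9:
            margins = {
                "age_group": self.probs.sum(axis=(1, 2, 3)),
                "gender": self.probs.sum(axis=(0, 2, 3)),
            }
            raise ValueError(
                f"distribution cells sum to {total:.12g}, not 1 "
                f"(age-group margin: {np.array2string(margins['age_group'], precision=4)}; "
                f"gender margin: {np.array2string(margins['gender'], precision=4)})"
            )
        if self.bmi_max <= 30.0:
            raise ValueError("bmi_max must exceed the obese lower bound (30)")

    def bmi_interval(self, category: int) -> tuple:
        lo, hi = _BMI_INTERVALS[int(category)]
        if int(category) == int(BmiCategory.OBESE):
            hi = self.bmi_max
        return lo, hi

    def sample_cells(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample ``n`` flat cell indices from the joint table."""
        flat = self.probs.ravel()
        return rng.choice(flat.size, size=n, p=flat / flat.sum())

    def sample(self, n: int, rng: np.random.Generator, start_id: int = 0) -> Cohort:
        """Draw ``n`` alive agents from the joint distribution."""
        cells = self.sample_cells(n, rng)
        ag, gender, bcat, state = np.unravel_index(cells, _CELL_SHAPE)
        age_lo = 20 + 5 * ag
        age = age_lo + rng.integers(0, 5, size=n)
        lo = np.empty(n)
        hi = np.empty(n)
        for c in range(3):
            m = bcat == c
            lo[m], hi[m] = self.bmi_interval(c)
        bmi = lo + rng.random(n) * (hi - lo)
        glycemic = (state + 1).astype(np.int8)
        diabetic = glycemic == 3
        onset = np.full(n, np.nan)
        onset[diabetic] = -1.0
        return Cohort(
            ids=start_id + np.arange(n, dtype=np.int64),
            age=age.astype(np.int64),
            gender=gender.astype(np.int8),
            bmi=bmi,
            glycemic=glycemic,
            alive=np.ones(n, dtype=bool),
            diabetes_onset_year=onset,
            death_year=np.full(n, np.nan),
            ever_diabetic=diabetic.copy(),
        )


@dataclass
class EntrySchedule:
    """Per-year entrant ("birth") counts and entrant distributions.

    Entrants model people turning 20: their distribution is restricted to
    the youngest age band.  ``cells[year]`` holds non-negative weights of
    shape (2, 3, 3) over gender x BMI category x glycemic state whose sum is
    the entrant count for that year (in agents, before any agent-scale
    rescaling of *reported* person counts).
    """

    cells: Dict[int, np.ndarray]
    bmi_max: float = 60.0

    def __post_init__(self) -> None:
        for year, table in self.cells.items():
            table = np.asarray(table, dtype=np.float64)
            if table.shape != (2, 3, 3):
                raise ValueError(f"entry table for year {year} must have shape (2,3,3)")
            if np.any(table < 0):
                raise ValueError(f"entry table for year {year} has negative counts")
            self.cells[year] = table

    def count(self, year: int) -> int:
        if year not in self.cells:
            raise KeyError(f"year {year} outside entry schedule")
        return int(round(float(self.cells[year].sum())))

    def distribution(self, year: int) -> np.ndarray:
        table = self.cells[year]
        total = table.sum()
        if total == 0:
            return np.zeros_like(table)
        return table / total


def build_initial_population(
    dist: PopulationDistribution, n_agents: int, seed_or_rng
) -> Cohort:
    """Sample the baseline population of ``n_agents`` alive adults."""
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    dist.validate()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    cohort = dist.sample(n_agents, rng)
    cohort.validate()
    return cohort


def inject_entrants(
    pop: Cohort, schedule: EntrySchedule, year: int, rng: np.random.Generator
) -> int:
    """Append the scheduled entrants for ``year``; returns how many."""
    n = schedule.count(year)
    if n == 0:
        return 0
    table = schedule.distribution(year)
    flat = table.ravel()
    cells = rng.choice(flat.size, size=n, p=flat)
    gender, bcat, state = np.unravel_index(cells, (2, 3, 3))
    age = 20 + rng.integers(0, 5, size=n)
    lo = np.empty(n)
    hi = np.empty(n)
    intervals = {c: (_BMI_INTERVALS[c][0], schedule.bmi_max if c == 2 else _BMI_INTERVALS[c][1]) for c in range(3)}
    for c in range(3):
        m = bcat == c
        lo[m], hi[m] = intervals[c]
    bmi = lo + rng.random(n) * (hi - lo)
    glycemic = (state + 1).astype(np.int8)
    diabetic = glycemic == 3
    onset = np.full(n, np.nan)
    onset[diabetic] = -1.0
    start_id = int(pop.ids.max()) + 1 if pop.size else 0
    entrants = Cohort(
        ids=start_id + np.arange(n, dtype=np.int64),
        age=age.astype(np.int64),
        gender=gender.astype(np.int8),
        bmi=bmi,
        glycemic=glycemic,
        alive=np.ones(n, dtype=bool),
        diabetes_onset_year=onset,
        death_year=np.full(n, np.nan),
        ever_diabetic=diabetic.copy(),
    )
    pop.append(entrants)
    return n


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_DIST_COLUMNS = ["age_group", "gender", "bmi_cat", "glycemic_state", "probability"]
_ENTRY_COLUMNS = ["year", "age_group", "gender", "bmi_cat", "glycemic_state", "count"]


def _require_columns(df: pd.DataFrame, columns: List[str], path) -> None:
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )


def write_population_distribution(dist: PopulationDistribution, path) -> None:
    rows = []
    for ag in range(N_AGE_GROUPS):
        for g in Gender:
            for b in BmiCategory:
                for s in GlycemicState:
                    rows.append(
                        (ag, g.name.lower(), b.name.lower(), s.name.lower(),
                         repr(float(dist.probs[ag, g, b, s - 1])))
                    )
    pd.DataFrame(rows, columns=_DIST_COLUMNS).to_csv(path, index=False)


def read_population_distribution(path, bmi_max: float = 60.0) -> PopulationDistribution:
    df = pd.read_csv(path, dtype={"probability": float}, float_precision="round_trip")
    _require_columns(df, _DIST_COLUMNS, path)
    probs = np.zeros(_CELL_SHAPE)
    for row in df.itertuples(index=False):
        probs[
            int(row.age_group),
            Gender.parse(row.gender),
            BmiCategory.parse(row.bmi_cat),
            GlycemicState.parse(row.glycemic_state) - 1,
        ] = row.probability
    return PopulationDistribution(probs, bmi_max=bmi_max)


def write_entry_schedule(schedule: EntrySchedule, path) -> None:
    rows = []
    for year in sorted(schedule.cells):
        table = schedule.cells[year]
        for g in Gender:
            for b in BmiCategory:
                for s in GlycemicState:
                    rows.append(
                        (year, 0, g.name.lower(), b.name.lower(), s.name.lower(),
                         repr(float(table[g, b, s - 1])))
                    )
    pd.DataFrame(rows, columns=_ENTRY_COLUMNS).to_csv(path, index=False)


def read_entry_schedule(path, bmi_max: float = 60.0) -> EntrySchedule:
    df = pd.read_csv(path, dtype={"count": float}, float_precision="round_trip")
    _require_columns(df, _ENTRY_COLUMNS, path)
    cells: Dict[int, np.ndarray] = {}
    for row in df.itertuples(index=False):
        if int(row.age_group) != 0:
            raise ValueError(f"{path}: entrants must be restricted to age group 0")
        table = cells.setdefault(int(row.year), np.zeros((2, 3, 3)))
        table[
            Gender.parse(row.gender),
            BmiCategory.parse(row.bmi_cat),
            GlycemicState.parse(row.glycemic_state) - 1,
        ] = row.count
    return EntrySchedule(cells, bmi_max=bmi_max)
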