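"""The microsimulation annual cycle.

Each simulated year runs four phases in a fixed order for every agent:

1. mortality — at the beginning of the year each alive agent dies with an
   annual probability taken from an age-gender life table (never-diabetic
   agents) or from a proportional-hazards model with a calibratable
   baseline-hazard shift (agents who have ever had diabetes);
2. intervention — first simulated year only (see ``interventions``);
3. age/BMI — age increments deterministically by one year; BMI moves with
   probability ``p_change`` by a draw whose conditional mean ``d/p_change``
   makes the unconditional annual mean change equal the regression trend
   ``d`` for the agent's (age group, gender) stratum;
4. glycemic transition — the three-state fasting-glucose Markov step using
   the transition matrix of the agent's current (age group, gender, BMI
   category) stratum; diabetes is absorbing.

Agents dying in phase 1 contribute to that year's mortality but not to the
same year's transition; a newly incident diabetic therefore faces diabetic
mortality only from the following year.  Entrants are injected after the
transition phase, so they first progress in their second calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .population import Cohort, EntrySchedule, inject_entrants
from .rng import substream
from .state_core import (
    N_AGE_GROUPS,
    BmiCategory,
    Gender,
    GlycemicState,
    Individual,
    age_group_of,
    bmi_category_of,
)

__all__ = [
    "LifeTable",
    "DiabeticMortalityModel",
    "BmiDriftModel",
    "TransitionMatrixSet",
    "MissingStratumError",
    "ModelSet",
    "SimulationSettings",
    "RunResult",
    "annual_death_probability",
    "apply_mortality",
    "update_age_bmi",
    "glycemic_transition",
    "simulate_horizon",
    "read_life_table",
    "write_life_table",
    "read_diabetic_mortality",
    "write_diabetic_mortality",
    "read_bmi_drift",
    "write_bmi_drift",
    "read_tpms",
    "write_tpms",
]

_MIN_AGE, _MAX_AGE = 20, 110


class MissingStratumError(KeyError):
    """Raised when a transition matrix is requested for an undefined stratum."""


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class LifeTable:
    """Annual death probability q(age, gender) for non-diabetic adults.

    ``q`` has shape (91, 2) covering integer ages 20..110; the last value is
    reused beyond age 110.
    """

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        if self.q.shape != (_MAX_AGE - _MIN_AGE + 1, 2):
            raise ValueError(f"life table must have shape (91, 2), got {self.q.shape}")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("life-table probabilities must lie in [0, 1]")

    def lookup(self, age, gender) -> np.ndarray:
        a = np.asarray(age)
        if np.any(a < _MIN_AGE):
            raise ValueError("life table is defined for ages >= 20 only")
        idx = np.minimum(a - _MIN_AGE, _MAX_AGE - _MIN_AGE)
        return self.q[idx, np.asarray(gender, dtype=np.int64)]


@dataclass
class DiabeticMortalityModel:
    """Annual death probability for diabetic agents.

    A proportional-hazards form restricted to age, gender and BMI:
    ``p = 1 - exp(-h0 * exp(beta_age*age + beta_male*1[male] + beta_bmi*bmi + c))``
    where ``c`` is the calibration constant that shifts the log baseline
    hazard to absorb the risk factors the covariate set omits.
    """

    beta_age: float
    beta_male: float
    beta_bmi: float
    h0: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.h0 < 0:
            raise ValueError("baseline annual hazard h0 must be non-negative")

    def annual_probability(self, age, gender, bmi, c: Optional[float] = None) -> np.ndarray:
        c = self.c if c is None else float(c)
        male = (np.asarray(gender, dtype=np.int64) == int(Gender.MALE)).astype(np.float64)
        lp = (
            self.beta_age * np.asarray(age, dtype=np.float64)
            + self.beta_male * male
            + self.beta_bmi * np.asarray(bmi, dtype=np.float64)
            + c
        )
        return 1.0 - np.exp(-self.h0 * np.exp(lp))

    def with_constant(self, c: float) -> "DiabeticMortalityModel":
        return DiabeticMortalityModel(self.beta_age, self.beta_male, self.beta_bmi, self.h0, c)


@dataclass
class BmiDriftModel:
    """Stochastic annual BMI change per (age group, gender) stratum.

    ``mean_change`` (kg/m^2/yr) is the regression trend d; each year the BMI
    changes with probability ``p_change`` by a Normal(d/p_change, sigma)
    draw, so the unconditional expected change equals d exactly (before the
    BMI floor truncation).
    """

    mean_change: np.ndarray
    p_change: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        shape = (N_AGE_GROUPS, 2)
        self.mean_change = np.broadcast_to(np.asarray(self.mean_change, float), shape).copy()
        self.p_change = np.broadcast_to(np.asarray(self.p_change, float), shape).copy()
        self.sigma = np.broadcast_to(np.asarray(self.sigma, float), shape).copy()
        if np.any((self.p_change <= 0) | (self.p_change > 1)):
            raise ValueError("p_change must lie in (0, 1]")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


@dataclass
class TransitionMatrixSet:
    """3x3 row-stochastic glycemic transition matrices stratified by
    (age group, gender, BMI category).

    ``tensor`` has shape (17, 2, 3, 3, 3); strata may be left undefined
    (NaN) when estimated on a restricted grid.  ``counts`` optionally holds
    the observed transition-pair counts behind an estimated set (used by
    additive smoothing).
    """

    tensor: np.ndarray
    counts: Optional[np.ndarray] = None

    _SHAPE = (N_AGE_GROUPS, 2, 3, 3, 3)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.shape != self._SHAPE:
            raise ValueError(f"TPM tensor must have shape {self._SHAPE}")

    @classmethod
    def from_single(cls, P) -> "TransitionMatrixSet":
        P = np.asarray(P, dtype=np.float64)
        tensor = np.broadcast_to(P, cls._SHAPE).copy()
        return cls(tensor)

    @classmethod
    def from_function(cls, fn) -> "TransitionMatrixSet":
        """Build a complete set from ``fn(age_group, gender, bmi_cat) -> 3x3``."""
        tensor = np.empty(cls._SHAPE)
        for ag in range(N_AGE_GROUPS):
            for g in range(2):
                for b in range(3):
                    tensor[ag, g, b] = np.asarray(fn(ag, g, b), dtype=np.float64)
        return cls(tensor)

    def copy(self) -> "TransitionMatrixSet":
        return TransitionMatrixSet(
            self.tensor.copy(), None if self.counts is None else self.counts.copy()
        )

    def defined(self) -> np.ndarray:
        """Boolean (17, 2, 3) mask of strata with a defined matrix."""
        return ~np.isnan(self.tensor).any(axis=(3, 4))

    def matrix(self, age_group: int, gender: int, bmi_cat: int) -> np.ndarray:
        P = self.tensor[int(age_group), int(gender), int(bmi_cat)]
        if np.isnan(P).any():
            raise MissingStratumError(
                f"no transition matrix for stratum (age group {int(age_group)}, "
                f"{Gender(int(gender)).name.lower()}, {BmiCategory(int(bmi_cat)).name.lower()})"
            )
        return P

    def validate(self, require_complete: bool = True) -> None:
        mask = self.defined()
        if require_complete and not mask.all():
            missing = np.argwhere(~mask)
            raise MissingStratumError(f"undefined strata: {missing.tolist()[:5]}...")
        rows = self.tensor[mask]  # (k, 3, 3)
        if rows.size == 0:
            return
        if np.any(rows < -1e-12):
            raise ValueError("TPM entries must be non-negative")
        sums = rows.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("every TPM row must sum to 1 within 1e-9")
        absorbing = rows[:, 2, :]
        if np.any(np.abs(absorbing - np.array([0.0, 0.0, 1.0])) > 1e-9):
            raise ValueError("the DIABETES row must be (0, 0, 1)")

    def force_absorbing(self) -> None:
        """Overwrite every defined DIABETES row with (0, 0, 1)."""
        mask = self.defined()
        self.tensor[mask, 2, :] = np.array([0.0, 0.0, 1.0])


@dataclass
class ModelSet:
    """All stochastic-progression models needed by the annual cycle."""

    life_table: LifeTable
    diabetic_mortality: DiabeticMortalityModel
    bmi_drift: BmiDriftModel
    tpms: TransitionMatrixSet

    def validate(self) -> None:
        self.tpms.validate(require_complete=True)


@dataclass
class SimulationSettings:
    """Scenario-level settings of one simulation run."""

    horizon: int
    start_year: int = 2010
    agent_scale: float = 1.0
    bmi_floor: float = 15.0
    entry_schedule: Optional[EntrySchedule] = None

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.agent_scale <= 0:
            raise ValueError("agent_scale must be positive")


@dataclass
class RunResult:
    """Per-year outcome records plus the final population of one run."""

    series: "pd.DataFrame"
    cohort: Cohort
    participants: int = 0
    achievers: int = 0


# ---------------------------------------------------------------------------
# Scalar operations (single-individual semantics)
# ---------------------------------------------------------------------------


def annual_death_probability(
    ind: Individual, lt: LifeTable, dm: DiabeticMortalityModel
) -> float:
    """Annual probability that ``ind`` dies this year.

    Never-diabetic individuals use the life table; anyone who has ever been
    diabetic uses the proportional-hazards model with its calibration
    constant.
    """
    if not ind.alive:
        raise ValueError("death probability is defined for alive individuals")
    if ind.ever_diabetic:
        return float(dm.annual_probability(ind.age, int(ind.gender), ind.bmi))
    return float(lt.lookup(ind.age, int(ind.gender)))


def update_age_bmi(
    ind: Individual,
    drift: BmiDriftModel,
    rng: np.random.Generator,
    bmi_floor: float = 15.0,
) -> Individual:
    """Increment age by one year and apply the stochastic BMI change."""
    if not ind.alive:
        raise ValueError("cannot age a dead individual")
    ind.age += 1
    ag, g = int(ind.age_group), int(ind.gender)
    d, p, s = drift.mean_change[ag, g], drift.p_change[ag, g], drift.sigma[ag, g]
    if rng.random() < p:
        ind.bmi = max(ind.bmi + d / p + s * rng.standard_normal(), bmi_floor)
    return ind


def glycemic_transition(
    ind: Individual, tpms: TransitionMatrixSet, rng: np.random.Generator, year: int = 0
) -> Individual:
    """Draw the next glycemic state from the individual's stratum row."""
    if not ind.alive:
        raise ValueError("cannot transition a dead individual")
    row = tpms.matrix(int(ind.age_group), int(ind.gender), int(ind.bmi_category))[
        int(ind.glycemic) - 1
    ]
    u = rng.random()
    nxt = int(min(np.searchsorted(np.cumsum(row), u, side="right"), 2)) + 1
    if nxt == int(GlycemicState.DIABETES) and ind.glycemic != GlycemicState.DIABETES:
        ind.diabetes_onset_year = year
        ind.ever_diabetic = True
    ind.glycemic = GlycemicState(nxt)
    return ind


# ---------------------------------------------------------------------------
# Vectorized annual-cycle kernels
# ---------------------------------------------------------------------------


def _death_probabilities(pop: Cohort, lt: LifeTable, dm: DiabeticMortalityModel) -> np.ndarray:
    q = lt.lookup(pop.age, pop.gender)
    p = dm.annual_probability(pop.age, pop.gender, pop.bmi)
    return np.where(pop.ever_diabetic, p, q)


def apply_mortality(
    pop: Cohort,
    lt: LifeTable,
    dm: DiabeticMortalityModel,
    year: int,
    rng: np.random.Generator,
) -> Tuple[int, int]:
    """Kill each alive agent independently with its annual probability.

    Uniforms are drawn for every agent row (dead included) so paired arms
    sharing the stream stay aligned.  Returns (deaths, diabetic deaths).
    """
    p = _death_probabilities(pop, lt, dm)
    u = rng.random(pop.size)
    dying = pop.alive & (u < p)
    pop.alive[dying] = False
    pop.death_year[dying] = year
    return int(dying.sum()), int((dying & pop.ever_diabetic).sum())


def _update_age_bmi_cohort(
    pop: Cohort, drift: BmiDriftModel, rng: np.random.Generator, bmi_floor: float
) -> None:
    n = pop.size
    u = rng.random(n)
    z = rng.standard_normal(n)
    alive = pop.alive
    pop.age[alive] += 1
    ag = age_group_of(pop.age)
    g = pop.gender.astype(np.int64)
    d = drift.mean_change[ag, g]
    p = drift.p_change[ag, g]
    s = drift.sigma[ag, g]
    change = np.where(u < p, d / p + s * z, 0.0)
    new_bmi = np.maximum(pop.bmi + change, bmi_floor)
    pop.bmi[alive] = new_bmi[alive]


def _glycemic_transition_cohort(
    pop: Cohort, tpms: TransitionMatrixSet, rng: np.random.Generator, year: int
) -> int:
    n = pop.size
    u = rng.random(n)
    ag = age_group_of(pop.age)
    bc = bmi_category_of(pop.bmi)
    rows = tpms.tensor[ag, pop.gender.astype(np.int64), bc, pop.glycemic.astype(np.int64) - 1]
    if np.isnan(rows[pop.alive]).any():
        bad = np.argwhere(pop.alive & np.isnan(rows).any(axis=1))[:1]
        i = int(bad[0, 0])
        raise MissingStratumError(
            f"no transition matrix for stratum (age group {int(ag[i])}, "
            f"{Gender(int(pop.gender[i])).name.lower()}, "
            f"{BmiCategory(int(bc[i])).name.lower()})"
        )
    cum = np.cumsum(np.nan_to_num(rows), axis=1)
    nxt = (np.minimum((u[:, None] >= cum).sum(axis=1), 2) + 1).astype(np.int8)
    newly = pop.alive & (pop.glycemic != 3) & (nxt == 3)
    pop.glycemic[pop.alive] = nxt[pop.alive]
    pop.diabetes_onset_year[newly] = year
    pop.ever_diabetic[newly] = True
    return int(newly.sum())


_SERIES_COLUMNS = [
    "year",
    "calendar_year",
    "n_alive_start",
    "deaths",
    "diabetes_deaths",
    "entrants",
    "new_cases",
    "n_alive_end",
    "n_diabetes_end",
    "n_prediabetes_end",
    "at_risk",
    "incidence_per100",
    "prevalence_per100",
    "diabetes_mortality_per100",
]


def simulate_horizon(
    pop: Cohort,
    models: ModelSet,
    settings: SimulationSettings,
    intervention=None,
    master_seed: int = 0,
) -> RunResult:
    """Run the annual cycle for ``settings.horizon`` years.

    The input cohort is not modified; per-year counts and rates are
    recorded after the transition phase and entrant injection.  With a
    fixed ``master_seed`` and fixed inputs the event stream is
    bit-reproducible.
    """
    from .interventions import apply_intervention  # local to avoid cycle at import time

    models.validate()
    pop = pop.copy()
    records = []
    participants = achievers = 0
    for t in range(settings.horizon):
        n_start = pop.n_alive
        deaths, dm_deaths = apply_mortality(
            pop, models.life_table, models.diabetic_mortality, t,
            substream(master_seed, "mortality", t),
        )
        if t == 0 and intervention is not None:
            participants, achievers = apply_intervention(
                pop, intervention, substream(master_seed, "intervention", 0), year=t
            )
        _update_age_bmi_cohort(
            pop, models.bmi_drift, substream(master_seed, "age_bmi", t), settings.bmi_floor
        )
        new_cases = _glycemic_transition_cohort(
            pop, models.tpms, substream(master_seed, "glycemic", t), t
        )
        entrants = 0
        if settings.entry_schedule is not None:
            entrants = inject_entrants(
                pop, settings.entry_schedule, t, substream(master_seed, "entry", t)
            )
        alive = pop.alive
        n_end = int(alive.sum())
        n_diab = int((alive & (pop.glycemic == 3)).sum())
        n_pre = int((alive & (pop.glycemic == 2)).sum())
        previously = int(
            (alive & pop.ever_diabetic & (np.nan_to_num(pop.diabetes_onset_year, nan=np.inf) < t)).sum()
        )
        at_risk = n_end - previously
        records.append(
            (
                t,
                settings.start_year + t,
                n_start,
                deaths,
                dm_deaths,
                entrants,
                new_cases,
                n_end,
                n_diab,
                n_pre,
                at_risk,
                100.0 * new_cases / at_risk if at_risk > 0 else np.nan,
                100.0 * n_diab / n_end if n_end > 0 else np.nan,
                100.0 * dm_deaths / n_start if n_start > 0 else np.nan,
            )
        )
    series = pd.DataFrame(records, columns=_SERIES_COLUMNS)
    return RunResult(series=series, cohort=pop, participants=participants, achievers=achievers)


# ---------------------------------------------------------------------------
# CSV interfaces (lossless to full float precision via repr round-trip)
# ---------------------------------------------------------------------------


def write_life_table(lt: LifeTable, path) -> None:
    rows = [
        (age, g.name.lower(), repr(float(lt.q[age - _MIN_AGE, g])))
        for age in range(_MIN_AGE, _MAX_AGE + 1)
        for g in Gender
    ]
    pd.DataFrame(rows, columns=["age", "gender", "q"]).to_csv(path, index=False)


def read_life_table(path) -> LifeTable:
    df = pd.read_csv(path, dtype={"q": float}, float_precision="round_trip")
    if list(df.columns) != ["age", "gender", "q"]:
        raise ValueError(f"{path}: expected columns [age, gender, q]")
    q = np.full((_MAX_AGE - _MIN_AGE + 1, 2), np.nan)
    for row in df.itertuples(index=False):
        q[int(row.age) - _MIN_AGE, Gender.parse(row.gender)] = row.q
    if np.isnan(q).any():
        raise ValueError(f"{path}: life table must cover ages 20..110 for both genders")
    return LifeTable(q)


def write_diabetic_mortality(dm: DiabeticMortalityModel, path) -> None:
    rows = [
        ("beta_age", repr(dm.beta_age)),
        ("beta_male", repr(dm.beta_male)),
        ("beta_bmi", repr(dm.beta_bmi)),
        ("h0", repr(dm.h0)),
        ("c", repr(dm.c)),
    ]
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)


def read_diabetic_mortality(path) -> DiabeticMortalityModel:
    df = pd.read_csv(path, dtype={"value": float}, float_precision="round_trip")
    if list(df.columns) != ["parameter", "value"]:
        raise ValueError(f"{path}: expected columns [parameter, value]")
    params = dict(zip(df["parameter"], df["value"]))
    missing = {"beta_age", "beta_male", "beta_bmi", "h0"} - set(params)
    if missing:
        raise ValueError(f"{path}: missing parameters {sorted(missing)}")
    return DiabeticMortalityModel(
        beta_age=params["beta_age"],
        beta_male=params["beta_male"],
        beta_bmi=params["beta_bmi"],
        h0=params["h0"],
        c=params.get("c", 0.0),
    )


def write_bmi_drift(drift: BmiDriftModel, path) -> None:
    rows = [
        (
            ag,
            g.name.lower(),
            repr(float(drift.mean_change[ag, g])),
            repr(float(drift.p_change[ag, g])),
            repr(float(drift.sigma[ag, g])),
        )
        for ag in range(N_AGE_GROUPS)
        for g in Gender
    ]
    pd.DataFrame(
        rows, columns=["age_group", "gender", "annual_change", "p_change", "sigma"]
    ).to_csv(path, index=False)


def read_bmi_drift(path) -> BmiDriftModel:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["age_group", "gender", "annual_change", "p_change", "sigma"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    d = np.full((N_AGE_GROUPS, 2), np.nan)
    p = np.full((N_AGE_GROUPS, 2), np.nan)
    s = np.full((N_AGE_GROUPS, 2), np.nan)
    for row in df.itertuples(index=False):
        g = Gender.parse(row.gender)
        d[int(row.age_group), g] = row.annual_change
        p[int(row.age_group), g] = row.p_change
        s[int(row.age_group), g] = row.sigma
    if np.isnan(d).any():
        raise ValueError(f"{path}: BMI drift must cover all 17x2 strata")
    return BmiDriftModel(mean_change=d, p_change=p, sigma=s)


def write_tpms(tpms: TransitionMatrixSet, path) -> None:
    rows = []
    mask = tpms.defined()
    for ag in range(N_AGE_GROUPS):
        for g in Gender:
            for b in BmiCategory:
                if not mask[ag, g, b]:
                    continue
                for i in GlycemicState:
                    for j in GlycemicState:
                        rows.append(
                            (
                                ag,
                                g.name.lower(),
                                b.name.lower(),
                                i.name.lower(),
                                j.name.lower(),
                                repr(float(tpms.tensor[ag, g, b, i - 1, j - 1])),
                            )
                        )
    pd.DataFrame(
        rows,
        columns=["age_group", "gender", "bmi_cat", "from_state", "to_state", "probability"],
    ).to_csv(path, index=False)


def read_tpms(path) -> TransitionMatrixSet:
    df = pd.read_csv(path, dtype={"probability": float}, float_precision="round_trip")
    expected = ["age_group", "gender", "bmi_cat", "from_state", "to_state", "probability"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    tensor = np.full(TransitionMatrixSet._SHAPE, np.nan)
    for row in df.itertuples(index=False):
        tensor[
            int(row.age_group),
            Gender.parse(row.gender),
            BmiCategory.parse(row.bmi_cat),
            GlycemicState.parse(row.from_state) - 1,
            GlycemicState.parse(row.to_state) - 1,
        ] = row.probability
    return TransitionMatrixSet(tensor)
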