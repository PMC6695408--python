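"""Synthetic study fixtures.

The longitudinal panel the transition matrices were originally estimated
from, and the census/survey tables behind the initial population, entrant
schedule, life table and BMI trend regressions, are not publicly
deposited.  This module generates documented, plausible stand-ins for all
of them — a complete ``Scenario`` whose ground-truth models are recorded
alongside the data they generate, so estimation code can be tested by
parameter recovery and the simulator can be exercised end to end without
any external download.

Default magnitudes are chosen so the simulated adult population looks
broadly like the contemporary U.S.: diabetes prevalence around 8-10 per
100, annual incidence around 1-1.5 per 100 at-risk, prediabetes prevalence
around 20-25 per 100, mortality rising Gompertz-like with age, and BMI
drifting up in early adulthood and down in old age.  These are fixture
choices, not claims of calibration to any survey.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .population import (
    Cohort,
    EntrySchedule,
    PopulationDistribution,
    build_initial_population,
    write_entry_schedule,
    write_population_distribution,
)
from .progression import (
    BmiDriftModel,
    DiabeticMortalityModel,
    LifeTable,
    ModelSet,
    RunResult,
    SimulationSettings,
    TransitionMatrixSet,
    simulate_horizon,
    write_bmi_drift,
    write_diabetic_mortality,
    write_life_table,
    write_tpms,
)
from .rng import substream
from .state_core import N_AGE_GROUPS

__all__ = ["Scenario", "make_default_scenario", "generate_panel", "write_scenario"]


@dataclass
class Scenario:
    """A complete simulation scenario with recorded ground truth."""

    models: ModelSet
    dist: PopulationDistribution
    settings: SimulationSettings
    n_agents: int
    seed: int

    def build_population(self, master_seed: Optional[int] = None) -> Cohort:
        seed = self.seed if master_seed is None else master_seed
        return build_initial_population(self.dist, self.n_agents, substream(seed, "init"))

    def run(self, intervention=None, master_seed: Optional[int] = None) -> RunResult:
        seed = self.seed if master_seed is None else master_seed
        pop = self.build_population(seed)
        return simulate_horizon(pop, self.models, self.settings, intervention, seed)


def _default_tpm_row_params(ag: int, bcat: int) -> np.ndarray:
    """3x3 annual transition matrix rising in age group and BMI category."""
    p_nd_pd = 0.020 + 0.003 * ag + 0.008 * bcat
    p_nd_dm = 0.0008 + 0.0003 * ag + 0.0007 * bcat
    p_pd_dm = 0.015 + 0.002 * ag + 0.008 * bcat
    p_pd_nd = 0.12
    return np.array(
        [
            [1.0 - p_nd_pd - p_nd_dm, p_nd_pd, p_nd_dm],
            [p_pd_nd, 1.0 - p_pd_nd - p_pd_dm, p_pd_dm],
            [0.0, 0.0, 1.0],
        ]
    )


def default_tpms() -> TransitionMatrixSet:
    return TransitionMatrixSet.from_function(lambda ag, g, b: _default_tpm_row_params(ag, b))


def default_life_table() -> LifeTable:
    """Gompertz-shaped annual death probabilities, male above female."""
    ages = np.arange(20, 111)
    q = np.empty((ages.size, 2))
    q[:, 0] = np.minimum(6.7e-5 * np.exp(0.085 * (ages - 20)) * np.exp(1.7), 0.95)
    q[:, 1] = np.minimum(4.5e-5 * np.exp(0.085 * (ages - 20)) * np.exp(1.7), 0.95)
    return LifeTable(q)


def default_diabetic_mortality() -> DiabeticMortalityModel:
    # roughly 1.5-2x the non-diabetic hazard at matched age before calibration
    return DiabeticMortalityModel(
        beta_age=0.085, beta_male=0.35, beta_bmi=0.01, h0=1.0e-4, c=0.0
    )


def default_bmi_drift() -> BmiDriftModel:
    ag = np.arange(N_AGE_GROUPS, dtype=float)
    d = np.clip(0.18 - 0.03 * ag, -0.15, None)
    mean = np.stack([d, d], axis=1)
    return BmiDriftModel(mean_change=mean, p_change=0.7, sigma=0.5)


def default_population_distribution() -> PopulationDistribution:
    age_w = np.array(
        [9.5, 9.5, 9.5, 9.5, 10.0, 10.0, 9.5, 8.5, 7.5, 6.0, 4.5, 3.0, 2.0, 1.2, 0.5, 0.2, 0.1]
    )
    age_w /= age_w.sum()
    gender_w = np.array([0.49, 0.51])
    probs = np.zeros((N_AGE_GROUPS, 2, 3, 3))
    for ag in range(N_AGE_GROUPS):
        normal = max(0.45 - 0.012 * min(ag, 10), 0.2)
        bmi_w = np.array([normal, 0.34, 1.0 - normal - 0.34])
        for g in range(2):
            for b in range(3):
                p_dm = min(0.008 + 0.006 * ag + 0.020 * b, 0.25)
                p_pd = min(0.12 + 0.008 * ag + 0.025 * b, 0.45)
                glyc_w = np.array([1.0 - p_pd - p_dm, p_pd, p_dm])
                probs[ag, g, b] = age_w[ag] * gender_w[g] * bmi_w[b] * glyc_w
    probs /= probs.sum()
    return PopulationDistribution(probs)


def default_entry_schedule(n_agents: int, horizon: int) -> EntrySchedule:
    """Annual entrants: ~1.8% of the baseline adult population turns 20."""
    count = max(int(round(0.018 * n_agents)), 1)
    gender_w = np.array([0.51, 0.49])
    bmi_w = np.array([0.62, 0.24, 0.14])
    glyc_w = np.array([0.88, 0.115, 0.005])
    table = count * gender_w[:, None, None] * bmi_w[None, :, None] * glyc_w[None, None, :]
    return EntrySchedule({year: table.copy() for year in range(max(horizon, 1))})


def make_default_scenario(
    seed: int,
    n_agents: int = 50_000,
    horizon: int = 15,
    agent_scale: float = 1.0,
    with_entrants: bool = True,
) -> Scenario:
    """The default synthetic scenario (fully seed-deterministic)."""
    models = ModelSet(
        life_table=default_life_table(),
        diabetic_mortality=default_diabetic_mortality(),
        bmi_drift=default_bmi_drift(),
        tpms=default_tpms(),
    )
    settings = SimulationSettings(
        horizon=horizon,
        start_year=2010,
        agent_scale=agent_scale,
        entry_schedule=default_entry_schedule(n_agents, horizon) if with_entrants else None,
    )
    return Scenario(
        models=models,
        dist=default_population_distribution(),
        settings=settings,
        n_agents=n_agents,
        seed=int(seed),
    )


def generate_panel(
    truth: TransitionMatrixSet,
    n_subjects: int,
    n_visits: int,
    interval_months: float = 12.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a short longitudinal panel from known transition matrices.

    Subjects are drawn with fixed gender and BMI and an age advancing with
    the visit clock; glycemic states evolve by the interval-step matrix
    (the ``interval/12`` matrix power of the annual truth), so the
    estimator applied at the same interval should recover the truth.
    """
    if n_subjects < 1 or n_visits < 2:
        raise ValueError("need at least 1 subject and 2 visits")
    rng = substream(seed, "panel")
    from .tpm import annualize_matrix  # late import: tpm imports progression

    steps = interval_months / 12.0
    age0 = rng.uniform(25.0, 70.0, size=n_subjects)
    gender = rng.integers(0, 2, size=n_subjects)
    bmi = rng.uniform(21.0, 42.0, size=n_subjects)
    state = rng.choice([1, 2, 3], size=n_subjects, p=[0.55, 0.40, 0.05])

    # cache interval-step matrices per stratum
    from .state_core import age_group_of, bmi_category_of

    step_cache: Dict[tuple, np.ndarray] = {}

    rows = []
    for v in range(n_visits):
        month = v * interval_months
        age = age0 + month / 12.0
        for s in range(n_subjects):
            rows.append((s, month, age[s], int(gender[s]), float(bmi[s]), int(state[s])))
        if v == n_visits - 1:
            break
        ag = age_group_of(np.maximum(age, 20.0))
        bc = bmi_category_of(bmi)
        u = rng.random(n_subjects)
        nxt = np.empty(n_subjects, dtype=np.int64)
        for s in range(n_subjects):
            key = (int(ag[s]), int(gender[s]), int(bc[s]))
            if key not in step_cache:
                P = truth.matrix(*key)
                step_cache[key] = np.cumsum(
                    P if abs(steps - 1.0) < 1e-12 else annualize_matrix(P, steps), axis=1
                )
            cum = step_cache[key][state[s] - 1]
            nxt[s] = min(int(np.searchsorted(cum, u[s], side="right")), 2) + 1
        state = nxt
    return pd.DataFrame(
        rows, columns=["subject_id", "visit_month", "age", "gender", "bmi", "glycemic_state"]
    )


def write_scenario(scenario: Scenario, directory) -> Dict[str, Path]:
    """Write every scenario input table as CSV; returns name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "population_distribution": directory / "population_distribution.csv",
        "entry_schedule": directory / "entry_schedule.csv",
        "life_table": directory / "life_table.csv",
        "diabetic_mortality": directory / "diabetic_mortality.csv",
        "bmi_drift": directory / "bmi_drift.csv",
        "tpms": directory / "tpms.csv",
    }
    write_population_distribution(scenario.dist, paths["population_distribution"])
    if scenario.settings.entry_schedule is not None:
        write_entry_schedule(scenario.settings.entry_schedule, paths["entry_schedule"])
    else:
        paths.pop("entry_schedule")
    write_life_table(scenario.models.life_table, paths["life_table"])
    write_diabetic_mortality(scenario.models.diabetic_mortality, paths["diabetic_mortality"])
    write_bmi_drift(scenario.models.bmi_drift, paths["bmi_drift"])
    write_tpms(scenario.models.tpms, paths["tpms"])
    return paths
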