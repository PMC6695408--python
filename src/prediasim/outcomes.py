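"""Performance measures and cost-effectiveness accounting.

Three per-year population measures are tracked: diabetes incidence (new
cases over the population not previously diagnosed), diabetes prevalence
(cases over the alive population) and diabetes mortality (deaths of
diabetics over the population), all per 100.  Intervention effects are
measured by running two arms from a bit-identical starting population with
common random numbers, so per-individual trajectories can be paired: the
difference and relative improvement of each rate, the number of diabetes
cases and deaths averted, the mean per-person gain in diabetes-free
survival time, and the net monetary savings (averted cases times the
per-case lifetime medical cost of diabetes, minus total program cost).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .interventions import InterventionSpec, total_intervention_cost
from .population import Cohort, PopulationDistribution, build_initial_population
from .progression import ModelSet, RunResult, SimulationSettings, simulate_horizon
from .rng import substream

__all__ = [
    "DEFAULT_PER_CASE_BENEFIT",
    "AGE_BANDS",
    "ImprovementResult",
    "CEResult",
    "PairedResult",
    "incidence_rate",
    "prevalence_rate",
    "diabetes_mortality_rate",
    "improvement",
    "paired_run",
    "dfs_gain",
    "cost_effectiveness",
    "ce_from_accounting",
    "discounted_savings",
    "optimal_age_band",
]

#: Age-gender weighted average lifetime medical cost associated with one
#: diabetes case (dollars); configuration default, not a model constant.
DEFAULT_PER_CASE_BENEFIT = 85_200.0

#: The four candidate target-population age bands for the optimal-band search.
AGE_BANDS: Tuple[Tuple[int, int], ...] = ((25, 65), (35, 65), (45, 65), (55, 65))


def incidence_rate(new_cases: int, alive: int, previously_diagnosed: int) -> float:
    """Diabetes incidence per 100: new cases over the population excluding
    those previously diagnosed."""
    at_risk = alive - previously_diagnosed
    if at_risk <= 0:
        raise ZeroDivisionError("incidence undefined: at-risk denominator is zero")
    return 100.0 * new_cases / at_risk


def prevalence_rate(cases: int, alive: int) -> float:
    """Diabetes prevalence per 100 of the alive population."""
    if alive <= 0:
        raise ZeroDivisionError("prevalence undefined: population is empty")
    return 100.0 * cases / alive


def diabetes_mortality_rate(diabetes_deaths: int, population: int) -> float:
    """Diabetes deaths per 100 of the population at risk that year."""
    if population <= 0:
        raise ZeroDivisionError("mortality rate undefined: population is empty")
    return 100.0 * diabetes_deaths / population


@dataclass(frozen=True)
class ImprovementResult:
    """End-of-horizon comparison of one rate between arms.

    difference = rate without intervention - rate with intervention;
    improvement = difference / rate without intervention (as percent).
    """

    rate_no_intervention: float
    rate_intervention: float

    @property
    def difference(self) -> float:
        return self.rate_no_intervention - self.rate_intervention

    @property
    def improvement_percent(self) -> float:
        return 100.0 * self.difference / self.rate_no_intervention


def improvement(rate_no_intervention: float, rate_intervention: float) -> ImprovementResult:
    if rate_no_intervention <= 0:
        raise ZeroDivisionError("improvement undefined when the control rate is zero")
    return ImprovementResult(rate_no_intervention, rate_intervention)


@dataclass
class PairedResult:
    """Control and intervention runs started from the same population with
    common random numbers."""

    control: RunResult
    intervention: RunResult
    spec: Optional[InterventionSpec]
    master_seed: int
    agent_scale: float = 1.0
    horizon: int = 0

    @property
    def diabetes_averted(self) -> int:
        """Cumulative incident cases in control minus intervention (agents)."""
        return int(
            self.control.series["new_cases"].sum()
            - self.intervention.series["new_cases"].sum()
        )

    @property
    def deaths_averted_all(self) -> int:
        return int(
            self.control.series["deaths"].sum() - self.intervention.series["deaths"].sum()
        )

    @property
    def deaths_averted_diabetes(self) -> int:
        return int(
            self.control.series["diabetes_deaths"].sum()
            - self.intervention.series["diabetes_deaths"].sum()
        )


def paired_run(
    models: ModelSet,
    settings: SimulationSettings,
    dist: PopulationDistribution,
    n_agents: int,
    spec: Optional[InterventionSpec],
    master_seed: int,
    base_pop: Optional[Cohort] = None,
) -> PairedResult:
    """Run control and intervention arms from a bit-identical population.

    Both arms reuse the same named random substreams (common random
    numbers), so with a null intervention the arms are bit-identical and
    with an effective one every between-arm difference is attributable to
    the intervention.  ``base_pop`` lets several interventions share one
    control population.
    """
    if base_pop is None:
        base_pop = build_initial_population(dist, n_agents, substream(master_seed, "init"))
    control = simulate_horizon(base_pop, models, settings, None, master_seed)
    arm = simulate_horizon(base_pop, models, settings, spec, master_seed)
    return PairedResult(
        control=control,
        intervention=arm,
        spec=spec,
        master_seed=master_seed,
        agent_scale=settings.agent_scale,
        horizon=settings.horizon,
    )


def dfs_gain(
    control_pop: Cohort, intervention_pop: Cohort, horizon: int
) -> Tuple[float, int]:
    """Mean per-person gain in diabetes-free survival time (years).

    For each shared id: if diabetes onset occurs in both arms the gain is
    the onset delay (intervention minus control, positive when the
    intervention postpones onset); if in neither, zero; if only in the
    control arm at time t, the gain is censored at horizon - t; if only in
    the intervention arm at time t, the loss -(horizon - t) is recorded.
    Anyone dying before onset in either arm is excluded.  Returns
    (mean gain over included ids, number included).
    """
    if control_pop.size != intervention_pop.size or not np.array_equal(
        control_pop.ids, intervention_pop.ids
    ):
        raise ValueError("paired populations must share the same id set")
    t_c = control_pop.diabetes_onset_year
    t_i = intervention_pop.diabetes_onset_year
    dev_c = ~np.isnan(t_c)
    dev_i = ~np.isnan(t_i)
    died_before_onset = (~control_pop.alive & ~dev_c) | (~intervention_pop.alive & ~dev_i)
    include = ~died_before_onset
    n = int(include.sum())
    if n == 0:
        return 0.0, 0
    gain = np.zeros(control_pop.size)
    both = dev_c & dev_i
    gain[both] = t_i[both] - t_c[both]
    only_c = dev_c & ~dev_i
    gain[only_c] = horizon - t_c[only_c]
    only_i = dev_i & ~dev_c
    gain[only_i] = -(horizon - t_i[only_i])
    return float(gain[include].mean()), n


@dataclass(frozen=True)
class CEResult:
    """Cost-effectiveness accounting of one paired comparison.

    Monetary fields are in thousands of dollars; the identities
    ``aversion_savings == diabetes_averted_persons * per_case_benefit / 1000``
    and ``total_savings == aversion_savings - intervention_cost`` hold
    exactly by construction.
    """

    diabetes_averted_persons: float
    deaths_averted_all_persons: float
    deaths_averted_diabetes_persons: float
    mean_dfs_gain_years: float
    dfs_n: int
    intervention_cost_thousands: float
    per_case_benefit: float

    @property
    def aversion_savings_thousands(self) -> float:
        return self.diabetes_averted_persons * self.per_case_benefit / 1000.0

    @property
    def total_savings_thousands(self) -> float:
        return self.aversion_savings_thousands - self.intervention_cost_thousands


def ce_from_accounting(
    diabetes_averted_persons: float,
    intervention_cost_thousands: float,
    per_case_benefit: float = DEFAULT_PER_CASE_BENEFIT,
    deaths_averted_all: float = 0.0,
    deaths_averted_diabetes: float = 0.0,
    mean_dfs_gain_years: float = 0.0,
    dfs_n: int = 0,
) -> CEResult:
    """Build a CEResult directly from counts and costs (no simulation)."""
    return CEResult(
        diabetes_averted_persons=diabetes_averted_persons,
        deaths_averted_all_persons=deaths_averted_all,
        deaths_averted_diabetes_persons=deaths_averted_diabetes,
        mean_dfs_gain_years=mean_dfs_gain_years,
        dfs_n=dfs_n,
        intervention_cost_thousands=intervention_cost_thousands,
        per_case_benefit=per_case_benefit,
    )


def cost_effectiveness(
    paired: PairedResult,
    spec: Optional[InterventionSpec] = None,
    per_case_benefit: float = DEFAULT_PER_CASE_BENEFIT,
    participants: Optional[int] = None,
) -> CEResult:
    """Cost-effectiveness of one paired run, rescaled to persons."""
    if per_case_benefit <= 0:
        raise ValueError("per-case benefit must be positive")
    spec = spec if spec is not None else paired.spec
    if spec is None:
        raise ValueError("an intervention spec is required for cost accounting")
    if participants is None:
        participants = paired.intervention.participants
    scale = paired.agent_scale
    cost = total_intervention_cost(participants, spec, agent_scale=scale)
    gain, n = dfs_gain(paired.control.cohort, paired.intervention.cohort, paired.horizon)
    return CEResult(
        diabetes_averted_persons=paired.diabetes_averted * scale,
        deaths_averted_all_persons=paired.deaths_averted_all * scale,
        deaths_averted_diabetes_persons=paired.deaths_averted_diabetes * scale,
        mean_dfs_gain_years=gain,
        dfs_n=n,
        intervention_cost_thousands=cost / 1000.0,
        per_case_benefit=per_case_benefit,
    )


def discounted_savings(
    paired: PairedResult,
    spec: Optional[InterventionSpec] = None,
    per_case_benefit: float = DEFAULT_PER_CASE_BENEFIT,
    rate: float = 0.0,
) -> Tuple[float, float, float]:
    """Sensitivity variant of the accounting with annual discounting.

    Averted cases are credited in the year they occur and discounted at
    ``rate`` back to the start year; the one-time program cost is not
    discounted.  Returns (aversion savings, cost, total savings) in
    thousands of dollars; ``rate=0`` reproduces the undiscounted default.
    """
    spec = spec if spec is not None else paired.spec
    if spec is None:
        raise ValueError("an intervention spec is required for cost accounting")
    averted_by_year = (
        paired.control.series["new_cases"].to_numpy()
        - paired.intervention.series["new_cases"].to_numpy()
    )
    disc = (1.0 + rate) ** -np.arange(averted_by_year.size, dtype=float)
    aversion = (
        float((averted_by_year * disc).sum())
        * paired.agent_scale
        * per_case_benefit
        / 1000.0
    )
    cost = total_intervention_cost(
        paired.intervention.participants, spec, agent_scale=paired.agent_scale
    ) / 1000.0
    return aversion, cost, aversion - cost


def optimal_age_band(
    results: Sequence[Tuple[Tuple[int, int], CEResult]]
) -> Tuple[Tuple[int, int], CEResult]:
    """The age band with maximum total savings among the candidates."""
    if not results:
        raise ValueError("no candidate bands supplied")
    return max(results, key=lambda item: item[1].total_savings_thousands)
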