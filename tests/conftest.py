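import numpy as np
import pytest

from prediasim.population import Cohort
from prediasim.progression import (
    BmiDriftModel,
    DiabeticMortalityModel,
    LifeTable,
    ModelSet,
    SimulationSettings,
    TransitionMatrixSet,
)
from prediasim.synthetic import make_default_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Default synthetic scenario at a size fast enough for unit tests."""
    return make_default_scenario(seed=7, n_agents=8_000, horizon=10)


def make_cohort(n, age=40, gender=0, bmi=27.0, state=2, seed=0):
    """Homogeneous alive cohort helper."""
    rng = np.random.default_rng(seed)
    state_arr = np.full(n, state, dtype=np.int8)
    diabetic = state_arr == 3
    onset = np.full(n, np.nan)
    onset[diabetic] = -1.0
    return Cohort(
        ids=np.arange(n, dtype=np.int64),
        age=np.full(n, age, dtype=np.int64),
        gender=np.full(n, gender, dtype=np.int8),
        bmi=np.full(n, float(bmi)),
        glycemic=state_arr,
        alive=np.ones(n, dtype=bool),
        diabetes_onset_year=onset,
        death_year=np.full(n, np.nan),
        ever_diabetic=diabetic,
    )


def frozen_models(P, q=0.0):
    """Models with no BMI drift and a flat life table: dynamics reduce to
    the glycemic Markov chain alone (diabetic hazard also zero)."""
    lt = LifeTable(np.full((91, 2), float(q)))
    dm = DiabeticMortalityModel(beta_age=0.0, beta_male=0.0, beta_bmi=0.0, h0=0.0)
    drift = BmiDriftModel(mean_change=0.0, p_change=1.0, sigma=0.0)
    return ModelSet(lt, dm, drift, TransitionMatrixSet.from_single(np.asarray(P)))


def frozen_settings(horizon):
    return SimulationSettings(horizon=horizon, entry_schedule=None)
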