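import numpy as np
import pytest

from prediasim.population import Cohort
from prediasim.progression import (
    BmiDriftModel,
    DiabeticMortalityModel,
    LifeTable,
    MissingStratumError,
    ModelSet,
    SimulationSettings,
    TransitionMatrixSet,
    annual_death_probability,
    apply_mortality,
    glycemic_transition,
    read_bmi_drift,
    read_diabetic_mortality,
    read_life_table,
    read_tpms,
    simulate_horizon,
    update_age_bmi,
    write_bmi_drift,
    write_diabetic_mortality,
    write_life_table,
    write_tpms,
)
from prediasim.rng import substream
from prediasim.state_core import GlycemicState, Individual

from tests.conftest import frozen_models, frozen_settings, make_cohort

IDENTITY = np.eye(3)


def person(age=50, gender=0, bmi=27.0, glycemic=1, **kw):
    return Individual(id=0, age=age, gender=gender, bmi=bmi, glycemic=glycemic, **kw)


class TestAnnualDeathProbability:
    def test_zero_hazard_life_table(self):
        lt = LifeTable(np.zeros((91, 2)))
        dm = DiabeticMortalityModel(0.0, 0.0, 0.0, h0=0.5)
        assert annual_death_probability(person(), lt, dm) == 0.0

    def test_diabetic_closed_form(self):
        lt = LifeTable(np.zeros((91, 2)))
        dm = DiabeticMortalityModel(0.0, 0.0, 0.0, h0=0.02, c=0.0)
        p = annual_death_probability(person(glycemic=3), lt, dm)
        assert p == pytest.approx(1 - np.exp(-0.02), abs=1e-12)

    def test_large_constant_drives_probability_to_one(self):
        lt = LifeTable(np.zeros((91, 2)))
        dm = DiabeticMortalityModel(0.0, 0.0, 0.0, h0=0.02, c=50.0)
        assert annual_death_probability(person(glycemic=3), lt, dm) == pytest.approx(1.0)

    def test_life_table_last_value_reused_beyond_110(self):
        q = np.zeros((91, 2))
        q[-1, :] = 0.4
        lt = LifeTable(q)
        assert lt.lookup(115, 0) == 0.4

    def test_age_below_table_rejected(self):
        lt = LifeTable(np.zeros((91, 2)))
        with pytest.raises(ValueError):
            lt.lookup(19, 0)


class TestApplyMortality:
    def test_all_zero_probabilities_no_deaths(self):
        pop = make_cohort(500)
        deaths, dmd = apply_mortality(
            pop, LifeTable(np.zeros((91, 2))),
            DiabeticMortalityModel(0, 0, 0, h0=0.0), 0, substream(0, "mortality", 0),
        )
        assert deaths == 0 and dmd == 0 and pop.n_alive == 500

    def test_certain_death_kills_everyone(self):
        pop = make_cohort(200)
        deaths, _ = apply_mortality(
            pop, LifeTable(np.ones((91, 2))),
            DiabeticMortalityModel(0, 0, 0, h0=0.0), 4, substream(0, "mortality", 0),
        )
        assert deaths == 200 and pop.n_alive == 0
        assert np.all(pop.death_year == 4)

    def test_homogeneous_probability_binomial(self):
        pop = make_cohort(10_000)
        deaths, _ = apply_mortality(
            pop, LifeTable(np.full((91, 2), 0.1)),
            DiabeticMortalityModel(0, 0, 0, h0=0.0), 0, substream(3, "mortality", 0),
        )
        sigma = np.sqrt(10_000 * 0.1 * 0.9)
        assert abs(deaths - 1_000) <= 3 * sigma

    def test_diabetic_deaths_counted_separately(self):
        pop = make_cohort(100, state=3)
        deaths, dmd = apply_mortality(
            pop, LifeTable(np.zeros((91, 2))),
            DiabeticMortalityModel(0, 0, 0, h0=50.0), 0, substream(0, "mortality", 0),
        )
        assert deaths == dmd == 100


class TestUpdateAgeBmi:
    def test_deterministic_composition(self):
        drift = BmiDriftModel(mean_change=0.2, p_change=1.0, sigma=0.0)
        ind = person(age=37, bmi=30.0)
        update_age_bmi(ind, drift, np.random.default_rng(0))
        assert ind.age == 38
        assert ind.bmi == pytest.approx(30.2, abs=1e-12)

    def test_age_always_increments(self):
        drift = BmiDriftModel(mean_change=0.0, p_change=1.0, sigma=0.0)
        for seed in range(5):
            ind = person(age=37)
            update_age_bmi(ind, drift, np.random.default_rng(seed))
            assert ind.age == 38

    def test_unconditional_mean_change_matches_trend(self):
        # change prob 0.5 with conditional mean 0.4 => E[change] = 0.2
        from prediasim.progression import _update_age_bmi_cohort

        drift = BmiDriftModel(mean_change=0.2, p_change=0.5, sigma=0.5)
        pop = make_cohort(100_000, bmi=30.0)
        _update_age_bmi_cohort(pop, drift, substream(1, "age_bmi", 0), bmi_floor=15.0)
        per_draw_var = 0.5 * (0.4**2 + 0.5**2) - 0.2**2
        se = np.sqrt(per_draw_var / 100_000)
        assert abs((pop.bmi - 30.0).mean() - 0.2) <= 3 * se

    def test_bmi_floored(self):
        drift = BmiDriftModel(mean_change=-5.0, p_change=1.0, sigma=0.0)
        ind = person(bmi=16.0)
        update_age_bmi(ind, drift, np.random.default_rng(0), bmi_floor=15.0)
        assert ind.bmi == 15.0


class TestGlycemicTransition:
    def test_point_mass_row_stays(self):
        P = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        tpms = TransitionMatrixSet.from_single(P)
        ind = person(glycemic=1)
        glycemic_transition(ind, tpms, np.random.default_rng(0))
        assert ind.glycemic == GlycemicState.NO_DIABETES

    def test_diabetes_absorbing(self):
        P = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 1]], dtype=float)
        tpms = TransitionMatrixSet.from_single(P)
        ind = person(glycemic=3)
        glycemic_transition(ind, tpms, np.random.default_rng(0))
        assert ind.glycemic == GlycemicState.DIABETES

    def test_onset_bookkeeping(self):
        P = np.array([[0, 0, 1], [0, 0, 1], [0, 0, 1]], dtype=float)
        ind = person(glycemic=2)
        glycemic_transition(ind, TransitionMatrixSet.from_single(P),
                            np.random.default_rng(0), year=6)
        assert ind.ever_diabetic and ind.diabetes_onset_year == 6

    def test_multinomial_frequencies(self):
        from prediasim.progression import _glycemic_transition_cohort

        row = np.array([0.2, 0.5, 0.3])
        P = np.vstack([row, row, [0, 0, 1]])
        pop = make_cohort(100_000, state=1)
        _glycemic_transition_cohort(
            pop, TransitionMatrixSet.from_single(P), substream(5, "glycemic", 0), 0
        )
        for k, p in enumerate(row, start=1):
            frac = (pop.glycemic == k).mean()
            assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / 100_000)

    def test_missing_stratum_identified(self):
        tensor = np.full((17, 2, 3, 3, 3), np.nan)
        tpms = TransitionMatrixSet(tensor)
        with pytest.raises(MissingStratumError, match="age group 6.*male|male.*age group 6"):
            glycemic_transition(person(age=50, gender=0), tpms, np.random.default_rng(0))


class TestSimulateHorizon:
    def test_zero_horizon_no_op(self):
        pop = make_cohort(50)
        res = simulate_horizon(pop, frozen_models(IDENTITY), frozen_settings(0))
        assert res.series.empty
        assert np.array_equal(res.cohort.bmi, pop.bmi)

    def test_frozen_dynamics(self):
        pop = make_cohort(1_000, state=2)
        res = simulate_horizon(pop, frozen_models(IDENTITY), frozen_settings(10), None, 3)
        assert (res.series["new_cases"] == 0).all()
        assert (res.series["deaths"] == 0).all()
        assert (res.series["incidence_per100"] == 0).all()
        assert res.series["n_alive_end"].nunique() == 1

    def test_seed_determinism(self, small_scenario):
        a = small_scenario.run(master_seed=13)
        b = small_scenario.run(master_seed=13)
        assert a.series.equals(b.series)
        assert np.array_equal(a.cohort.bmi, b.cohort.bmi)
        c = small_scenario.run(master_seed=14)
        assert not a.series.equals(c.series)

    def test_population_conservation_every_year(self, small_scenario):
        res = small_scenario.run(master_seed=2)
        s = res.series
        assert (
            s["n_alive_end"] == s["n_alive_start"] - s["deaths"] + s["entrants"]
        ).all()
        assert (s["new_cases"] <= s["at_risk"]).all()
        assert (s[["deaths", "new_cases", "entrants", "n_alive_end"]] >= 0).all().all()

    def test_two_step_frequencies_match_matrix_power(self):
        # frozen covariates: the cohort-level chain must obey P^2
        P = np.array([[0.7, 0.25, 0.05], [0.15, 0.7, 0.15], [0, 0, 1]])
        n = 40_000
        pop = make_cohort(n, age=40, state=1)
        res = simulate_horizon(pop, frozen_models(P), frozen_settings(2), None, 9)
        expected = np.linalg.matrix_power(P, 2)[0]
        for k in (1, 2, 3):
            frac = (res.cohort.glycemic == k).mean()
            p = expected[k - 1]
            assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestTpmValidation:
    def test_rows_must_sum_to_one(self):
        P = np.array([[0.5, 0.4, 0.2], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="sum to 1"):
            TransitionMatrixSet.from_single(P).validate()

    def test_diabetes_row_must_be_absorbing(self):
        P = np.array([[1, 0, 0], [0, 1, 0], [0.1, 0, 0.9]])
        with pytest.raises(ValueError, match="DIABETES"):
            TransitionMatrixSet.from_single(P).validate()


class TestCsvRoundTrips:
    def test_life_table(self, tmp_path, small_scenario):
        lt = small_scenario.models.life_table
        write_life_table(lt, tmp_path / "lt.csv")
        assert np.array_equal(read_life_table(tmp_path / "lt.csv").q, lt.q)

    def test_diabetic_mortality(self, tmp_path, small_scenario):
        dm = small_scenario.models.diabetic_mortality
        write_diabetic_mortality(dm, tmp_path / "dm.csv")
        back = read_diabetic_mortality(tmp_path / "dm.csv")
        assert back == dm

    def test_bmi_drift(self, tmp_path, small_scenario):
        drift = small_scenario.models.bmi_drift
        write_bmi_drift(drift, tmp_path / "drift.csv")
        back = read_bmi_drift(tmp_path / "drift.csv")
        assert np.array_equal(back.mean_change, drift.mean_change)
        assert np.array_equal(back.sigma, drift.sigma)

    def test_tpms(self, tmp_path, small_scenario):
        tpms = small_scenario.models.tpms
        write_tpms(tpms, tmp_path / "tpms.csv")
        assert np.array_equal(read_tpms(tmp_path / "tpms.csv").tensor, tpms.tensor)
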