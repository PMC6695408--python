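import dataclasses

import numpy as np
import pandas as pd
import pytest

from prediasim.datasets import published_rate_improvements, published_short_term_ce
from prediasim.interventions import PRESETS, get_preset
from prediasim.outcomes import (
    ce_from_accounting,
    cost_effectiveness,
    dfs_gain,
    diabetes_mortality_rate,
    improvement,
    incidence_rate,
    discounted_savings,
    optimal_age_band,
    paired_run,
    prevalence_rate,
)
from prediasim.population import Cohort


def cohort_from_onsets(onsets, alive=None, death_years=None):
    """Paired-arm cohort helper: onset None=never, -1=pre-baseline."""
    n = len(onsets)
    alive = [True] * n if alive is None else alive
    death_years = [None] * n if death_years is None else death_years
    onset_arr = np.array([np.nan if o is None else float(o) for o in onsets])
    ever = ~np.isnan(onset_arr)
    return Cohort(
        ids=np.arange(n, dtype=np.int64),
        age=np.full(n, 50, dtype=np.int64),
        gender=np.zeros(n, dtype=np.int8),
        bmi=np.full(n, 28.0),
        glycemic=np.where(ever, 3, 2).astype(np.int8),
        alive=np.array(alive, dtype=bool),
        diabetes_onset_year=onset_arr,
        death_year=np.array(
            [np.nan if d is None else float(d) for d in death_years]
        ),
        ever_diabetic=ever,
    )


class TestRates:
    def test_incidence_printed_definition(self):
        assert incidence_rate(5, 1_000, 200) == pytest.approx(0.625)

    def test_zero_new_cases(self):
        assert incidence_rate(0, 1_000, 10) == 0.0

    def test_zero_at_risk_denominator_undefined(self):
        with pytest.raises(ZeroDivisionError):
            incidence_rate(1, 200, 200)

    def test_prevalence_and_mortality(self):
        assert prevalence_rate(90, 1_000) == 9.0
        assert diabetes_mortality_rate(3, 1_500) == 0.2


class TestImprovement:
    def test_formula(self):
        r = improvement(1.0, 0.97)
        assert r.difference == pytest.approx(0.03)
        assert r.improvement_percent == pytest.approx(3.0)

    def test_no_change_zero_improvement(self):
        assert improvement(0.8, 0.8).improvement_percent == 0.0

    def test_zero_control_rate_undefined(self):
        with pytest.raises(ZeroDivisionError):
            improvement(0.0, 0.0)

    def test_published_pairs_invert_consistently(self):
        # difference / (improvement/100) recovers the control rate; feeding
        # it back through the formula must reproduce the printed improvement
        df = published_rate_improvements()
        row = df.query("measure=='incidence' and intervention=='dpp' and years==15").iloc[0]
        rate_ni = row.difference / (row.improvement_percent / 100.0)
        assert rate_ni == pytest.approx(1.003, abs=0.01)
        r = improvement(rate_ni, rate_ni - row.difference)
        assert r.improvement_percent == pytest.approx(row.improvement_percent, rel=1e-9)


class TestDfsGain:
    def test_censoring_and_exclusion_rules(self):
        H = 10
        control = cohort_from_onsets(
            [5, None, 6, None, None, -1],
            alive=[True, True, True, True, False, True],
            death_years=[None, None, None, None, 2, None],
        )
        interv = cohort_from_onsets([8, None, None, 7, None, -1])
        gain, n = dfs_gain(control, interv, H)
        # +3 (delayed), 0 (neither), +4 (control-only, censored at H),
        # -3 (intervention-only loss), excluded (died before onset), 0 (both prevalent)
        assert n == 5
        assert gain == pytest.approx((3 + 0 + 4 - 3 + 0) / 5)

    def test_mismatched_ids_rejected(self):
        a = cohort_from_onsets([None, None])
        b = cohort_from_onsets([None])
        with pytest.raises(ValueError, match="id"):
            dfs_gain(a, b, 5)


class TestCostAccounting:
    def test_published_totals_reproduced_exactly(self):
        for row in published_short_term_ce().itertuples(index=False):
            ce = ce_from_accounting(
                diabetes_averted_persons=row.diabetes_averted_thousands * 1_000,
                intervention_cost_thousands=row.intervention_cost_thousands,
            )
            assert ce.aversion_savings_thousands == pytest.approx(
                row.aversion_savings_thousands, abs=1e-6
            )
            assert ce.total_savings_thousands == pytest.approx(
                row.total_savings_thousands, abs=1e-6
            )

    def test_example_cells(self):
        help_pd = ce_from_accounting(927_600, 41_007_400)
        assert help_pd.total_savings_thousands == pytest.approx(38_024_120)
        dpp = ce_from_accounting(258_780, 31_074_700)
        assert dpp.total_savings_thousands == pytest.approx(-9_026_644)

    def test_identity_holds_by_construction(self):
        ce = ce_from_accounting(123.0, 456.0, per_case_benefit=1_000.0)
        assert ce.total_savings_thousands == ce.aversion_savings_thousands - 456.0

    def test_optimal_band_maximizes_total_savings(self):
        table = published_short_term_ce().query("intervention=='help-pd'")
        cands = [
            ((int(r.age_lo), int(r.age_hi)),
             ce_from_accounting(r.diabetes_averted_thousands * 1_000,
                                r.intervention_cost_thousands))
            for r in table.itertuples(index=False)
        ]
        band, _ = optimal_age_band(cands)
        assert band == (25, 65)


class TestPairedRuns:
    def test_null_intervention_arms_bit_identical(self, small_scenario):
        sc = small_scenario
        null = dataclasses.replace(PRESETS["help-pd"], achievement_rate=0.0)
        pr = paired_run(sc.models, sc.settings, sc.dist, 4_000, null, master_seed=5)
        assert pr.control.series.equals(pr.intervention.series)
        assert np.array_equal(pr.control.cohort.bmi, pr.intervention.cohort.bmi)
        gain, _ = dfs_gain(pr.control.cohort, pr.intervention.cohort, sc.settings.horizon)
        assert gain == 0.0
        assert pr.diabetes_averted == 0

    def test_same_master_seed_reproduces_pair(self, small_scenario):
        sc = small_scenario
        spec = PRESETS["dpp"]
        a = paired_run(sc.models, sc.settings, sc.dist, 3_000, spec, 8)
        b = paired_run(sc.models, sc.settings, sc.dist, 3_000, spec, 8)
        assert a.control.series.equals(b.control.series)
        assert a.intervention.series.equals(b.intervention.series)

    def test_widening_age_band_monotone_in_participants_and_cost(self, small_scenario):
        sc = small_scenario
        prev_participants, prev_cost = -1, -1.0
        for lo in (55, 45, 35, 25):
            spec = get_preset("help-pd", lo, 65)
            pr = paired_run(sc.models, sc.settings, sc.dist, 4_000, spec, 3)
            ce = cost_effectiveness(pr)
            assert pr.intervention.participants >= prev_participants
            assert ce.intervention_cost_thousands >= prev_cost
            prev_participants = pr.intervention.participants
            prev_cost = ce.intervention_cost_thousands

    def test_cost_effectiveness_rescales_to_persons(self, small_scenario):
        sc = small_scenario
        settings = dataclasses.replace(sc.settings, agent_scale=2_000.0)
        spec = PRESETS["help-pd"]
        pr = paired_run(sc.models, settings, sc.dist, 3_000, spec, 2)
        ce = cost_effectiveness(pr)
        expected_cost = pr.intervention.participants * spec.per_person_cost * 2_000 / 1_000
        assert ce.intervention_cost_thousands == pytest.approx(expected_cost)
        assert ce.diabetes_averted_persons == pr.diabetes_averted * 2_000


def test_zero_discount_rate_reproduces_undiscounted_accounting(small_scenario):
    sc = small_scenario
    spec = PRESETS["help-pd"]
    pr = paired_run(sc.models, sc.settings, sc.dist, 4_000, spec, 4)
    ce = cost_effectiveness(pr)
    aversion, cost, total = discounted_savings(pr, rate=0.0)
    assert aversion == pytest.approx(ce.aversion_savings_thousands)
    assert total == pytest.approx(ce.total_savings_thousands)
    aversion3, _, _ = discounted_savings(pr, rate=0.03)
    if ce.aversion_savings_thousands > 0:
        assert aversion3 < aversion


def test_frozen_dynamics_prevalence_follows_markov_trajectory():
    """With frozen covariates the cohort prevalence must track v0 P^t."""
    from prediasim.progression import simulate_horizon
    from tests.conftest import frozen_models, frozen_settings, make_cohort

    P = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0, 0, 1]])
    n = 20_000
    pop = make_cohort(n, age=40, state=1)
    res = simulate_horizon(pop, frozen_models(P), frozen_settings(5), None, 17)
    v = np.array([1.0, 0.0, 0.0])
    for t in range(5):
        v = v @ P
        prev = res.series["prevalence_per100"].iloc[t] / 100.0
        sigma = np.sqrt(v[2] * (1 - v[2]) / n)
        assert abs(prev - v[2]) <= 3 * sigma
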