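"""Published reference figures for the three lifestyle programs.

Small published result tables from the U.S. modeling study the package's
accounting mirrors, kept here as *inputs* for consistency checks: the
10-year cost-effectiveness figures by target age band, and the 5/10/15-year
rate differences and improvement percentages relative to no intervention.
All monetary columns are thousands of dollars; averted counts are
thousands of persons.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_short_term_ce", "published_rate_improvements"]

_CE_ROWS = [
    # intervention, age_lo, age_hi, averted_k, deaths_averted_k, dfs_gain_yr,
    # cost_k$, aversion_k$, total_k$
    ("dpp", 55, 65, 258.78, 18.24, 0.03, 31_074_700, 22_048_056, -9_026_644),
    ("dpp-ymca", 55, 65, 150.35, 4.96, 0.02, 7_677_100, 12_809_820, 5_132_720),
    ("help-pd", 55, 65, 226.00, 22.80, 0.03, 10_039_300, 19_255_200, 9_215_900),
    ("dpp", 45, 65, 489.06, 44.08, 0.06, 62_174_800, 41_667_912, -20_506_888),
    ("dpp-ymca", 45, 65, 296.67, 26.35, 0.03, 15_361_400, 25_276_284, 9_914_884),
    ("help-pd", 45, 65, 509.60, 58.00, 0.06, 20_088_000, 43_417_920, 23_329_920),
    ("dpp", 35, 65, 652.84, 77.14, 0.07, 92_405_900, 55_621_968, -36_783_932),
    ("dpp-ymca", 35, 65, 394.32, 44.95, 0.05, 22_829_300, 33_596_064, 10_766_764),
    ("help-pd", 35, 65, 764.00, 107.60, 0.08, 29_853_700, 65_092_800, 35_239_100),
    ("dpp", 25, 65, 915.80, 83.98, 0.11, 126_929_900, 78_026_160, -48_903_740),
    ("dpp-ymca", 25, 65, 553.35, 62.31, 0.06, 31_358_600, 47_145_420, 15_786_820),
    ("help-pd", 25, 65, 927.60, 130.40, 0.11, 41_007_400, 79_031_520, 38_024_120),
]


def published_short_term_ce() -> pd.DataFrame:
    """Published 10-year cost-effectiveness figures by intervention and
    target age band."""
    return pd.DataFrame(
        _CE_ROWS,
        columns=[
            "intervention",
            "age_lo",
            "age_hi",
            "diabetes_averted_thousands",
            "deaths_averted_thousands",
            "dfs_gain_years",
            "intervention_cost_thousands",
            "aversion_savings_thousands",
            "total_savings_thousands",
        ],
    )


_RATE_ROWS = [
    # measure, intervention, years, difference (per 100), improvement (%)
    ("incidence", "dpp", 5, 0.06, 6.25),
    ("incidence", "dpp", 10, 0.03, 2.96),
    ("incidence", "dpp", 15, 0.03, 2.99),
    ("incidence", "dpp-ymca", 5, 0.03, 3.39),
    ("incidence", "dpp-ymca", 10, 0.02, 1.91),
    ("incidence", "dpp-ymca", 15, 0.02, 2.16),
    ("incidence", "help-pd", 5, 0.06, 6.79),
    ("incidence", "help-pd", 10, 0.04, 3.38),
    ("incidence", "help-pd", 15, 0.04, 3.28),
    ("prevalence", "dpp", 5, 0.18, 1.55),
    ("prevalence", "dpp", 10, 0.28, 2.06),
    ("prevalence", "dpp", 15, 0.33, 2.20),
    ("prevalence", "dpp-ymca", 5, 0.12, 1.00),
    ("prevalence", "dpp-ymca", 10, 0.20, 1.32),
    ("prevalence", "dpp-ymca", 15, 0.20, 1.32),
    ("prevalence", "help-pd", 5, 0.20, 1.68),
    ("prevalence", "help-pd", 10, 0.31, 2.27),
    ("prevalence", "help-pd", 15, 0.35, 2.44),
    ("mortality", "dpp", 5, 0.01, 1.41),
    ("mortality", "dpp", 10, 0.02, 2.29),
    ("mortality", "dpp", 15, 0.03, 4.65),
    ("mortality", "dpp-ymca", 5, 0.00, 0.53),
    ("mortality", "dpp-ymca", 10, 0.01, 0.98),
    ("mortality", "dpp-ymca", 15, 0.01, 2.92),
    ("mortality", "help-pd", 5, 0.01, 1.62),
    ("mortality", "help-pd", 10, 0.02, 3.39),
    ("mortality", "help-pd", 15, 0.03, 5.23),
]


def published_rate_improvements() -> pd.DataFrame:
    """Published rate differences and improvement percentages (per 100 and
    percent) of the three programs versus no intervention."""
    return pd.DataFrame(
        _RATE_ROWS,
        columns=["measure", "intervention", "years", "difference", "improvement_percent"],
    )
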