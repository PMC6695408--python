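"""Estimation of stratified glycemic transition matrices from longitudinal
panel data, and calibration of the diabetic-mortality constant.

The estimator is the maximum-likelihood count proportion: for each
(age group, gender, BMI category) stratum and each origin state, observed
state pairs one visit interval apart are tallied and each row is the
proportion of destinations.  Visit spacings within a configurable slack of
the nominal interval (default +-25%) count as one interval.  Sparse strata
are pooled hierarchically — BMI split dropped first, then gender, then
adjacent age bands collapsed — and sub-annual intervals are annualized by
matrix power (eigen method for fractional powers, with projection of rows
back to the probability simplex; linear rescaling as a fallback when the
matrix has no admissible real power).  The diabetes row is forced absorbing
before the set is returned, so estimated reversion out of diabetes is
renormalized away rather than simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.linalg

from .population import Cohort
from .progression import DiabeticMortalityModel, TransitionMatrixSet
from .state_core import (
    N_AGE_GROUPS,
    Gender,
    GlycemicState,
    age_group_of,
    bmi_category_of,
)

__all__ = [
    "PanelRecord",
    "CalibrationTarget",
    "EmptyStratumError",
    "estimate_tpms",
    "smooth_tpms",
    "calibrate_mortality_constant",
    "expected_diabetic_mortality_rate",
    "panel_to_frame",
    "read_panel",
    "write_panel",
    "annualize_matrix",
]


class EmptyStratumError(ValueError):
    """No transition pairs available for a stratum even after pooling."""


@dataclass(frozen=True)
class PanelRecord:
    """One visit of one subject in a longitudinal glycemic panel."""

    subject_id: int
    visit_month: float
    age: float
    gender: Gender
    bmi: float
    glycemic: GlycemicState


@dataclass(frozen=True)
class CalibrationTarget:
    """Observed annual diabetic mortality rate (per 100) to calibrate to."""

    rate_per100: float
    tolerance: float = 1e-3  # relative

    def __post_init__(self) -> None:
        if not 0.0 < self.rate_per100 < 100.0:
            raise ValueError("target rate must lie in (0, 100) per 100")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


_PANEL_COLUMNS = ["subject_id", "visit_month", "age", "gender", "bmi", "glycemic_state"]


def panel_to_frame(panel: Union[pd.DataFrame, Iterable[PanelRecord]]) -> pd.DataFrame:
    if isinstance(panel, pd.DataFrame):
        missing = set(_PANEL_COLUMNS) - set(panel.columns)
        if missing:
            raise ValueError(f"panel frame missing columns {sorted(missing)}")
        df = panel.loc[:, _PANEL_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [
                (r.subject_id, r.visit_month, r.age, int(Gender.parse(r.gender)),
                 r.bmi, int(GlycemicState.parse(r.glycemic)))
                for r in panel
            ],
            columns=_PANEL_COLUMNS,
        )
    df["gender"] = [int(Gender.parse(g)) for g in df["gender"]]
    df["glycemic_state"] = [int(GlycemicState.parse(s)) for s in df["glycemic_state"]]
    df = df.sort_values(["subject_id", "visit_month"], kind="mergesort").reset_index(drop=True)
    spacing_ok = df.groupby("subject_id")["visit_month"].diff().dropna()
    if (spacing_ok <= 0).any():
        raise ValueError("visit times must be strictly increasing within each subject")
    return df


def write_panel(panel, path) -> None:
    df = panel_to_frame(panel).copy()
    df["gender"] = [Gender(g).name.lower() for g in df["gender"]]
    df["glycemic_state"] = [GlycemicState(s).name.lower() for s in df["glycemic_state"]]
    df.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != _PANEL_COLUMNS:
        raise ValueError(f"{path}: expected columns {_PANEL_COLUMNS}")
    return panel_to_frame(df)


# ---------------------------------------------------------------------------
# Annualization
# ---------------------------------------------------------------------------


def _project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    k = np.arange(1, v.size + 1)
    rho = np.nonzero(u - css / k > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def annualize_matrix(P: np.ndarray, steps: float) -> np.ndarray:
    """Raise a row-stochastic matrix to the power ``steps`` (= 12/interval).

    Integer powers use exact matrix multiplication; fractional powers use
    the eigen method followed by row-wise projection to the simplex.  When
    the fractional power is not an admissible stochastic matrix (complex or
    badly negative), falls back to the linear generator rescaling
    ``I + steps (P - I)`` with a warning.
    """
    P = np.asarray(P, dtype=np.float64)
    if abs(steps - round(steps)) < 1e-12:
        return np.linalg.matrix_power(P, int(round(steps)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Q = scipy.linalg.fractional_matrix_power(P, steps)
    if np.iscomplexobj(Q) and np.abs(Q.imag).max() > 1e-8:
        warnings.warn(
            "transition matrix has no real fractional power; "
            "falling back to linear rescaling of the generator",
            RuntimeWarning,
        )
        Q = np.eye(P.shape[0]) + steps * (P - np.eye(P.shape[0]))
    Q = np.real(Q)
    return np.vstack([_project_to_simplex(row) for row in Q])


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _pooled_row_counts(
    counts: np.ndarray, ag: int, g: int, b: int, i: int
) -> Tuple[np.ndarray, str]:
    """Hierarchical pooling for one origin-state row of one stratum.

    Order: own cell -> pool BMI categories -> pool gender -> widen the age
    window one band at a time.  Returns (counts over destinations, pooling
    level label).
    """
    own = counts[ag, g, b, i]
    if own.sum() > 0:
        return own, "none"
    by_bmi = counts[ag, g, :, i].sum(axis=0)
    if by_bmi.sum() > 0:
        return by_bmi, "bmi"
    by_gender = counts[ag, :, :, i].sum(axis=(0, 1))
    if by_gender.sum() > 0:
        return by_gender, "gender"
    for w in range(1, N_AGE_GROUPS):
        lo, hi = max(0, ag - w), min(N_AGE_GROUPS, ag + w + 1)
        pooled = counts[lo:hi, :, :, i].sum(axis=(0, 1, 2))
        if pooled.sum() > 0:
            return pooled, f"age+-{w}"
    return np.zeros(3), "exhausted"


def estimate_tpms(
    panel: Union[pd.DataFrame, Iterable[PanelRecord]],
    interval_months: float = 12.0,
    stratify: Sequence[str] = ("age_group", "gender", "bmi_cat"),
    spacing_slack: float = 0.25,
    log=None,
) -> TransitionMatrixSet:
    """Estimate the stratified one-year transition matrices from a panel.

    ``interval_months`` is the nominal visit spacing used to pair
    observations; if it differs from 12 the interval-level matrices are
    annualized by matrix power.  ``stratify`` lists the covariates kept in
    the stratification; dropped covariates are pooled over up front.
    ``log``, if given, receives one message per pooled stratum row.
    """
    df = panel_to_frame(panel)
    lo, hi = interval_months * (1 - spacing_slack), interval_months * (1 + spacing_slack)

    nxt = df.shift(-1)
    same = df["subject_id"].to_numpy() == nxt["subject_id"].to_numpy()
    gap = nxt["visit_month"].to_numpy() - df["visit_month"].to_numpy()
    use = same & (gap >= lo) & (gap <= hi)
    if not use.any():
        raise EmptyStratumError("panel contains no transition pairs at the requested interval")

    ag = age_group_of(np.maximum(df["age"].to_numpy()[use], 20.0))
    g = df["gender"].to_numpy()[use]
    b = bmi_category_of(df["bmi"].to_numpy()[use])
    frm = df["glycemic_state"].to_numpy()[use] - 1
    to = nxt["glycemic_state"].to_numpy()[use].astype(np.int64) - 1

    counts = np.zeros(TransitionMatrixSet._SHAPE)
    np.add.at(counts, (ag, g, b, frm, to), 1.0)

    if "bmi_cat" not in stratify:
        counts = np.broadcast_to(counts.sum(axis=2, keepdims=True), counts.shape).copy()
    if "gender" not in stratify:
        counts = np.broadcast_to(counts.sum(axis=1, keepdims=True), counts.shape).copy()
    if "age_group" not in stratify:
        counts = np.broadcast_to(counts.sum(axis=0, keepdims=True), counts.shape).copy()

    tensor = np.empty(TransitionMatrixSet._SHAPE)
    used_counts = np.zeros(TransitionMatrixSet._SHAPE)
    empty: List[tuple] = []
    for iag in range(N_AGE_GROUPS):
        for ig in range(2):
            for ib in range(3):
                P = np.zeros((3, 3))
                for i in range(2):  # diabetes row forced absorbing below
                    row, level = _pooled_row_counts(counts, iag, ig, ib, i)
                    if row.sum() == 0:
                        empty.append((iag, ig, ib, i))
                        continue
                    if level != "none" and log is not None:
                        log(
                            f"stratum (age group {iag}, {Gender(ig).name.lower()}, "
                            f"bmi cat {ib}) row {i}: pooled at level {level!r}"
                        )
                    used_counts[iag, ig, ib, i] = row
                    P[i] = row / row.sum()
                P[2] = (0.0, 0.0, 1.0)
                tensor[iag, ig, ib] = P
    if empty:
        raise EmptyStratumError(
            f"no transition pairs even after full pooling for strata/rows: {empty[:10]}"
        )

    steps = 12.0 / interval_months
    if abs(steps - 1.0) > 1e-12:
        for iag in range(N_AGE_GROUPS):
            for ig in range(2):
                for ib in range(3):
                    tensor[iag, ig, ib] = annualize_matrix(tensor[iag, ig, ib], steps)

    tpms = TransitionMatrixSet(tensor, counts=used_counts)
    tpms.force_absorbing()
    # renormalize defensively after annualization/projection
    sums = tpms.tensor.sum(axis=4, keepdims=True)
    tpms.tensor /= sums
    tpms.validate()
    return tpms


def smooth_tpms(tpms: TransitionMatrixSet, pseudo_count: float) -> TransitionMatrixSet:
    """Additive (Dirichlet) smoothing of every row, then renormalization.

    Operates on the transition counts when the set carries them (the
    estimator attaches the pooled counts it used), otherwise on the row
    probabilities treated as a unit-mass pseudo-sample.  ``pseudo_count``
    of 0 is the identity; the diabetes row stays absorbing.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be >= 0")
    out = tpms.copy()
    if pseudo_count == 0:
        return out
    base = out.counts if out.counts is not None else out.tensor
    mask = out.defined()
    smoothed = (base + pseudo_count) / (
        base.sum(axis=4, keepdims=True) + 3.0 * pseudo_count
    )
    out.tensor[mask] = smoothed[mask]
    out.force_absorbing()
    out.tensor /= out.tensor.sum(axis=4, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Mortality calibration
# ---------------------------------------------------------------------------


def expected_diabetic_mortality_rate(
    snapshot: Cohort, dm: DiabeticMortalityModel, c: float
) -> float:
    """Expected annual diabetic mortality (per 100) of a cohort snapshot.

    Deterministic: the mean of each alive diabetic's annual death
    probability under constant ``c`` — no Monte Carlo noise, so bisection
    on ``c`` is exact.
    """
    m = snapshot.alive & snapshot.ever_diabetic
    if not m.any():
        raise ValueError("snapshot contains no alive diabetic individuals")
    p = dm.annual_probability(snapshot.age[m], snapshot.gender[m], snapshot.bmi[m], c=c)
    return float(100.0 * p.mean())


def calibrate_mortality_constant(
    snapshot: Cohort,
    dm: DiabeticMortalityModel,
    target: CalibrationTarget,
    seed: int = 0,
    c_bounds: Tuple[float, float] = (-10.0, 10.0),
    max_iter: int = 50,
) -> Tuple[float, float]:
    """Bisect the log-hazard shift ``c`` to hit the target mortality rate.

    The annual probability 1 - exp(-h0 e^{beta'x + c}) is strictly
    increasing in ``c``, so the expected cohort rate is monotone and
    bisection converges.  Returns ``(c, achieved rate per 100)``; raises if
    the target lies outside the rates reachable on ``c_bounds``.  ``seed``
    is accepted for interface symmetry; the expected-value rate used here
    is deterministic.
    """
    lo, hi = c_bounds
    r_lo = expected_diabetic_mortality_rate(snapshot, dm, lo)
    r_hi = expected_diabetic_mortality_rate(snapshot, dm, hi)
    if not r_lo <= target.rate_per100 <= r_hi:
        raise ValueError(
            f"target rate {target.rate_per100} per 100 unreachable on c in "
            f"[{lo}, {hi}]: bracket rates [{r_lo:.6g}, {r_hi:.6g}]"
        )
    c = 0.5 * (lo + hi)
    rate = expected_diabetic_mortality_rate(snapshot, dm, c)
    for _ in range(max_iter):
        if abs(rate - target.rate_per100) <= target.tolerance * target.rate_per100:
            break
        if rate < target.rate_per100:
            lo = c
        else:
            hi = c
        c = 0.5 * (lo + hi)
        rate = expected_diabetic_mortality_rate(snapshot, dm, c)
    return c, rate
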