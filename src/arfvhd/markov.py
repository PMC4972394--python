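"""Discrete-time Markov cohort engine.

Each (birth year, sex) cohort enters at its live-birth count and is
propagated in one-year cycles through four states:

* ``arf_free``        — never had acute rheumatic fever
* ``post_arf_no_vhd`` — had ARF, no valvular disease
* ``arf_vhd``         — ARF-related valvular heart disease
* ``dead``            — absorbing

Within a cycle from year t to t+1 (age a = t - birth year at the start):

1. mortality — ``arf_free`` and ``post_arf_no_vhd`` die with the period
   probability q(a, t, sex); ``arf_vhd`` dies with the hazard-adjusted
   probability ``1 - (1 - q)**hr`` once a >= the excess-mortality start
   age (20 by default), plain q before;
2. incidence — a fraction lambda(a+1, t+1) of the surviving ``arf_free``
   experience ARF (one episode per person), of whom ``vhd_fraction``
   enter ``arf_vhd`` immediately and the rest ``post_arf_no_vhd``.

Counts are real-valued expectations, not integers. "Alive in 2013"
means survivors through the 2012 mortality cycle (mortality data end in
2012), i.e. the state recorded at calendar year 2013.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .demography import SEXES, BirthSeries, LifeTable
from .scenarios import IncidenceScenario, incidence

STATE_COLUMNS = ("arf_free", "post_arf_no_vhd", "arf_vhd", "dead")


@dataclass(frozen=True)
class DiseaseParams:
    """Disease-progression parameters of the cohort model.

    vhd_fraction
        Fraction of ARF patients developing VHD (0.50 in sub-scenarios
        'a', 0.40 in 'b').
    hazard_ratio
        Mortality hazard ratio of ARF-VHD patients vs the general
        population; 1.5 is the conservative literature-based choice.
    excess_mortality_start_age
        Age (completed years) from which the hazard ratio applies.
    final_year
        Cross-section year of the analysis; states are reported through
        the start of this year.
    """

    vhd_fraction: float = 0.50
    hazard_ratio: float = 1.5
    excess_mortality_start_age: int = 20
    final_year: int = 2013

    def __post_init__(self) -> None:
        if not 0.0 <= self.vhd_fraction <= 1.0:
            raise ValueError(f"vhd_fraction out of [0,1]: {self.vhd_fraction}")
        if self.hazard_ratio <= 0:
            raise ValueError(f"hazard_ratio must be > 0: {self.hazard_ratio}")


def hazard_adjust(q: float, hr: float) -> float:
    """Apply a hazard ratio to an annual death probability.

    Under a constant within-year hazard h = -ln(1-q), scaling the hazard
    by ``hr`` gives 1 - (1-q)**hr. Stays in [0, 1] for any hr > 0,
    unlike naive multiplication of q.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q out of [0,1]: {q}")
    if hr <= 0:
        raise ValueError(f"hr must be > 0: {hr}")
    if q == 1.0:
        return 1.0
    return -math.expm1(hr * math.log1p(-q))


@dataclass(frozen=True)
class StepResult:
    state: tuple[float, float, float, float]
    new_arf_cases: float


def step_cohort(
    state: tuple[float, float, float, float],
    q: float,
    incidence_next: float,
    params: DiseaseParams,
    age: int,
) -> StepResult:
    """One annual cycle: mortality at the current age, then incidence at age+1."""
    arf_free, post_arf, arf_vhd, dead = state
    if age >= params.excess_mortality_start_age:
        q_vhd = hazard_adjust(q, params.hazard_ratio)
    else:
        q_vhd = q
    deaths = (arf_free + post_arf) * q + arf_vhd * q_vhd
    arf_free *= 1.0 - q
    post_arf *= 1.0 - q
    arf_vhd *= 1.0 - q_vhd
    dead += deaths

    new_cases = arf_free * incidence_next
    arf_free -= new_cases
    arf_vhd += new_cases * params.vhd_fraction
    post_arf += new_cases * (1.0 - params.vhd_fraction)
    return StepResult((arf_free, post_arf, arf_vhd, dead), new_cases)


class CohortStateTable:
    """State counts per (birth year, sex, calendar year).

    Wraps a tidy DataFrame with columns ``birth_year, sex,
    calendar_year, arf_free, post_arf_no_vhd, arf_vhd, dead,
    new_arf_cases``; ``new_arf_cases`` records the ARF episodes arising
    in the cycle ending at that calendar year.
    """

    def __init__(self, df: pd.DataFrame, births: BirthSeries, final_year: int):
        self.df = df
        self.births = births
        self.final_year = final_year

    def final_states(self) -> pd.DataFrame:
        """States at the start of the final (cross-section) year."""
        return self.df[self.df.calendar_year == self.final_year]

    def conservation_error(self) -> float:
        """Max relative deviation of state sums from cohort entry counts."""
        totals = self.df[list(STATE_COLUMNS)].sum(axis=1)
        entry = pd.Series(
            [self.births.births(by, s) for by, s in zip(self.df.birth_year, self.df.sex)],
            index=self.df.index,
        )
        return float(((totals - entry).abs() / entry.where(entry > 0, 1.0)).max())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def run_model(
    births: BirthSeries,
    table: LifeTable,
    scenario: IncidenceScenario,
    params: DiseaseParams = DiseaseParams(),
) -> CohortStateTable:
    """Propagate every (birth year, sex) cohort from birth through the
    final cross-section year."""
    records: list[dict] = []
    for birth_year in births.years:
        for sex in SEXES:
            b = births.births(birth_year, sex)
            state = (float(b), 0.0, 0.0, 0.0)
            records.append(_record(birth_year, sex, birth_year, state, 0.0))
            for t in range(birth_year, params.final_year):
                age = t - birth_year
                step = step_cohort(
                    state,
                    table.q(age, t, sex),
                    incidence(scenario, age + 1, t + 1),
                    params,
                    age,
                )
                state = step.state
                records.append(
                    _record(birth_year, sex, t + 1, state, step.new_arf_cases)
                )
    df = pd.DataFrame.from_records(records)
    return CohortStateTable(df, births, params.final_year)


def count_arf_cases(result: CohortStateTable, by: str | None = None):
    """Number of patients ever developing ARF.

    ``by`` is None (scalar total), ``"sex"``, ``"birth_year"``, or
    ``"both"`` (a Series indexed accordingly).
    """
    df = result.df
    if by is None:
        return float(df.new_arf_cases.sum())
    keys = {"sex": ["sex"], "birth_year": ["birth_year"], "both": ["birth_year", "sex"]}[by]
    return df.groupby(keys).new_arf_cases.sum()


def _record(birth_year, sex, calendar_year, state, new_cases) -> dict:
    rec = {
        "birth_year": birth_year,
        "sex": sex,
        "calendar_year": calendar_year,
        "new_arf_cases": new_cases,
    }
    rec.update(dict(zip(STATE_COLUMNS, state)))
    return rec
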