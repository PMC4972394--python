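"""Synthetic demography with mid-century French structure.

Stands in for the official birth registries and period life tables the
analysis was designed around, so the full pipeline runs and is testable
without any external download. Mortality follows a Gompertz-Makeham
hazard with multiplicative period improvement and a sex differential:

    mu(x)      = makeham_a + gompertz_b * exp(gompertz_c * x)   for x >= 1
    q(x, t, s) = 1 - exp(-mu(x) * m(t) * g(s))
    m(t)       = (1 - annual_improvement) ** (t - 1940)
    g(male)    = 1,  g(female) = female_hazard_multiplier

Age 0 uses a separate infant-mortality schedule: a hazard equivalent to
``infant_q0`` in 1940, declining with the same period factor and sex
multiplier. Births are constant per year with a male/female sex ratio
of 1.05. The surface is deterministic given its parameters; parameters
are plausible configuration, not calibrated truth claims about France.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .demography import (
    FIRST_BIRTH_YEAR,
    LAST_BIRTH_YEAR,
    SEXES,
    BirthSeries,
    LifeTable,
    write_births,
    write_life_table,
)
from .scenarios import VHD_FRACTIONS, default_scenarios, dump_scenario

import pandas as pd


@dataclass(frozen=True)
class SyntheticDemographyParams:
    """Parameters of the synthetic demographic surface.

    births_per_year
        Total live births per calendar year (both sexes), ~800k for
        mid-century France.
    sex_ratio_at_birth
        Male/female ratio, 1.05.
    makeham_a
        Age-independent baseline hazard (per year).
    gompertz_b, gompertz_c
        Scale and log-slope of the senescent hazard component.
    infant_q0
        Age-0 annual death probability in 1940 (males), declining over
        time with ``annual_improvement``.
    annual_improvement
        Proportional hazard decline per calendar year.
    female_hazard_multiplier
        Female/male hazard ratio (< 1: female advantage).
    seed
        Reserved for optional stochastic extensions; the default
        surface is fully deterministic.
    """

    births_per_year: int = 800_000
    sex_ratio_at_birth: float = 1.05
    makeham_a: float = 5e-4
    gompertz_b: float = 1e-4
    gompertz_c: float = 0.095
    infant_q0: float = 0.05
    annual_improvement: float = 0.01
    female_hazard_multiplier: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.births_per_year <= 0:
            raise ValueError("births_per_year must be positive")
        if min(self.makeham_a, self.gompertz_b, self.gompertz_c) <= 0:
            raise ValueError("hazard parameters must be > 0")
        if not 0.0 <= self.infant_q0 <= 1.0:
            raise ValueError("infant_q0 must be a probability")
        if not 0.0 <= self.annual_improvement < 1.0:
            raise ValueError("annual_improvement must be in [0, 1)")
        if self.female_hazard_multiplier <= 0:
            raise ValueError("female_hazard_multiplier must be > 0")


def _sex_factor(params: SyntheticDemographyParams, sex: str) -> float:
    return 1.0 if sex == "male" else params.female_hazard_multiplier


def _period_factor(params: SyntheticDemographyParams, year: int) -> float:
    return (1.0 - params.annual_improvement) ** (year - 1940)


def synthetic_q(
    params: SyntheticDemographyParams, age: int, year: int, sex: str
) -> float:
    """Closed-form q(age, year, sex) of the synthetic surface."""
    m = _period_factor(params, year)
    g = _sex_factor(params, sex)
    if age == 0:
        h0 = -math.log1p(-params.infant_q0)
        return -math.expm1(-h0 * m * g)
    mu = params.makeham_a + params.gompertz_b * math.exp(params.gompertz_c * age)
    return -math.expm1(-mu * m * g)


def make_life_table(
    params: SyntheticDemographyParams,
    years: range = range(FIRST_BIRTH_YEAR, 2013),
    max_age: int = 110,
) -> LifeTable:
    """Full synthetic period life table over ``years`` and ages 0..max_age."""
    if max_age < 75:
        raise ValueError("max_age must cover the oldest cohort (>= 75)")
    q = {
        (age, year, sex): synthetic_q(params, age, year, sex)
        for year in years
        for sex in SEXES
        for age in range(max_age + 1)
    }
    return LifeTable(q)


def make_births(
    params: SyntheticDemographyParams,
    years: range = range(FIRST_BIRTH_YEAR, LAST_BIRTH_YEAR + 1),
) -> BirthSeries:
    """Constant annual births split male/female by the sex ratio."""
    ratio = params.sex_ratio_at_birth
    male = round(params.births_per_year * ratio / (1.0 + ratio))
    female = round(params.births_per_year / (1.0 + ratio))
    counts = {}
    for year in years:
        counts[(year, "male")] = float(male)
        counts[(year, "female")] = float(female)
    return BirthSeries(counts)


def make_infant_series(
    params: SyntheticDemographyParams, years: range = range(1940, 1946)
) -> dict[tuple[int, str], float]:
    """Age-0 q for the backfill years, from the synthetic surface."""
    return {
        (year, sex): synthetic_q(params, 0, year, sex)
        for year in years
        for sex in SEXES
    }


def make_fixture_bundle(
    out_dir: str | Path,
    params: SyntheticDemographyParams = SyntheticDemographyParams(),
) -> Path:
    """Write the complete input bundle a real analysis would start from.

    ``births.csv`` (1940-1960), ``lifetable.csv`` (1946-2012, mirroring
    the availability of detailed official tables), ``infant.csv``
    (age-0 mortality 1940-1945), and the three default scenario YAMLs
    with both VHD-fraction sub-scenarios. Deterministic given params:
    regenerating produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_births(make_births(params), out / "births.csv")
    write_life_table(
        make_life_table(params, years=range(1946, 2013)), out / "lifetable.csv"
    )
    infant = make_infant_series(params)
    pd.DataFrame(
        [
            {"year": y, "sex": s, "q0": repr(q0)}
            for (y, s), q0 in sorted(infant.items())
        ]
    ).to_csv(out / "infant.csv", index=False)
    for scenario in default_scenarios():
        for letter, fraction in sorted(VHD_FRACTIONS.items()):
            dump_scenario(
                scenario,
                out / f"{scenario.name}{letter}.yaml",
                vhd_fraction=fraction,
            )
    return out


def life_expectancy_at_birth(
    table: LifeTable, year: int, sex: str, max_age: int | None = None
) -> float:
    """Period life expectancy e0 with the half-year correction."""
    max_age = table.max_age if max_age is None else max_age
    surv = 1.0
    e0 = 0.5
    for age in range(max_age + 1):
        surv *= 1.0 - table.q(age, year, sex)
        e0 += surv
        if surv < 1e-12:
            break
    return e0
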