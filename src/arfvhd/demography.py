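"""Demographic inputs: birth series and period life tables.

The cohort model consumes two demographic surfaces: live births by
calendar year and sex (cohort entry counts, 1940-1960), and a period
life table giving the annual probability of death q(age, year, sex).
Official French life tables are detailed only from 1946 onward, so the
war years 1941-1945 are backfilled under the convention that
age-specific mortality after age 1 was steady between 1941 and 1946;
infant (age-0) mortality for those years comes from a separate infant
deaths series when available.

Files are plain CSV, UTF-8, header required, sex coded ``male``/``female``:

* ``births.csv``    — ``year,sex,births``
* ``lifetable.csv`` — ``year,sex,age,qx``
* ``infant.csv``    — ``year,sex,q0`` (optional, for the backfill years)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: Birth-cohort span of the study population.
FIRST_BIRTH_YEAR = 1940
LAST_BIRTH_YEAR = 1960


class ValidationError(ValueError):
    """Raised when a demographic input violates its contract."""


@dataclass(frozen=True)
class BirthSeries:
    """Live births by (calendar year, sex).

    Complete over 1940-1960 for both sexes; counts are non-negative.
    """

    counts: dict[tuple[int, str], float]

    def __post_init__(self) -> None:
        for (year, sex), n in self.counts.items():
            if sex not in SEXES:
                raise ValidationError(f"unknown sex code {sex!r}")
            if n < 0:
                raise ValidationError(f"negative births for ({year}, {sex}): {n}")
        for year in range(FIRST_BIRTH_YEAR, LAST_BIRTH_YEAR + 1):
            for sex in SEXES:
                if (year, sex) not in self.counts:
                    raise ValidationError(f"missing births for {year} ({sex})")

    @classmethod
    def single_cohort(cls, year: int, n: float, sex: str = "male") -> "BirthSeries":
        """A degenerate series with ``n`` births of one sex in one year
        and zero elsewhere — handy for worked examples and oracles."""
        counts = {
            (y, s): 0.0
            for y in range(FIRST_BIRTH_YEAR, LAST_BIRTH_YEAR + 1)
            for s in SEXES
        }
        counts[(year, sex)] = float(n)
        return cls(counts)

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.counts})

    def births(self, year: int, sex: str) -> float:
        return self.counts[(year, sex)]

    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class LifeTable:
    """Period life table: annual death probability q(age, year, sex).

    Ages beyond ``max_age`` reuse the ``max_age`` value, so old-age
    lookups never fail for cohorts ageing past the table's top row.
    """

    q_values: dict[tuple[int, int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (age, year, sex), qx in self.q_values.items():
            if sex not in SEXES:
                raise ValidationError(f"unknown sex code {sex!r}")
            if age < 0:
                raise ValidationError(f"negative age {age}")
            if not 0.0 <= qx <= 1.0:
                raise ValidationError(
                    f"qx out of [0,1] for (age={age}, year={year}, {sex}): {qx}"
                )

    @property
    def years(self) -> list[int]:
        return sorted({y for _, y, _ in self.q_values})

    @property
    def max_age(self) -> int:
        return max(a for a, _, _ in self.q_values)

    def q(self, age: int, year: int, sex: str) -> float:
        """Annual death probability, clamping age to the table maximum."""
        if age < 0:
            raise ValidationError(f"negative age {age}")
        age = min(age, self.max_age)
        try:
            return self.q_values[(age, year, sex)]
        except KeyError:
            raise ValidationError(
                f"life table has no cell for (age={age}, year={year}, sex={sex})"
            ) from None

    def copy(self) -> "LifeTable":
        return LifeTable(dict(self.q_values))


def read_births(path: str | Path) -> BirthSeries:
    """Read ``year,sex,births`` CSV into a validated :class:`BirthSeries`."""
    df = _read_csv(path, ["year", "sex", "births"])
    dup = df.duplicated(subset=["year", "sex"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(f"duplicate births row for ({row.year}, {row.sex})")
    counts = {
        (int(r.year), str(r.sex)): float(r.births) for r in df.itertuples(index=False)
    }
    return BirthSeries(counts)


def read_life_table(path: str | Path) -> LifeTable:
    """Read ``year,sex,age,qx`` CSV into a validated :class:`LifeTable`."""
    df = _read_csv(path, ["year", "sex", "age", "qx"])
    dup = df.duplicated(subset=["year", "sex", "age"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate life-table row for (year={row.year}, {row.sex}, age={row.age})"
        )
    q = {
        (int(r.age), int(r.year), str(r.sex)): float(r.qx)
        for r in df.itertuples(index=False)
    }
    return LifeTable(q)


def read_infant_table(path: str | Path) -> dict[tuple[int, str], float]:
    """Read the optional ``year,sex,q0`` infant-mortality CSV."""
    df = _read_csv(path, ["year", "sex", "q0"])
    out: dict[tuple[int, str], float] = {}
    for r in df.itertuples(index=False):
        key = (int(r.year), str(r.sex))
        if key in out:
            raise ValidationError(f"duplicate infant row for {key}")
        q0 = float(r.q0)
        if not 0.0 <= q0 <= 1.0:
            raise ValidationError(f"infant q0 out of [0,1] for {key}: {q0}")
        out[key] = q0
    return out


def write_births(series: BirthSeries, path: str | Path) -> None:
    rows = [
        {"year": y, "sex": s, "births": int(round(n))}
        for (y, s), n in sorted(series.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_life_table(table: LifeTable, path: str | Path) -> None:
    rows = [
        {"year": y, "sex": s, "age": a, "qx": repr(q)}
        for (a, y, s), q in sorted(table.q_values.items(), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0]))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def backfill_life_table(
    table: LifeTable,
    first_available_year: int = 1946,
    infant: dict[tuple[int, str], float] | None = None,
    first_year: int = FIRST_BIRTH_YEAR,
) -> LifeTable:
    """Extend a life table back to ``first_year`` (1940 by default).

    For years before ``first_available_year``, mortality at ages >= 1 is
    copied from ``first_available_year`` (the steady-war-mortality
    convention). Age-0 values come from the ``infant`` series; if none is
    supplied at all, the ``first_available_year`` age-0 value is copied
    and a warning is logged. A supplied-but-incomplete infant series is
    an error.
    """
    out = table.copy()
    ages = sorted({a for a, y, _ in table.q_values if y == first_available_year})
    if not ages:
        raise ValidationError(f"life table has no rows for {first_available_year}")
    if infant is None:
        logger.warning(
            "no infant mortality series supplied; copying age-0 qx from %d "
            "back to %d-%d",
            first_available_year,
            first_year,
            first_available_year - 1,
        )
    for year in range(first_year, first_available_year):
        for sex in SEXES:
            for age in ages:
                if age == 0:
                    if infant is not None:
                        if (year, sex) not in infant:
                            raise ValidationError(
                                f"infant series missing q0 for ({year}, {sex})"
                            )
                        q0 = infant[(year, sex)]
                    else:
                        q0 = table.q(0, first_available_year, sex)
                    out.q_values[(0, year, sex)] = q0
                else:
                    out.q_values[(age, year, sex)] = table.q(
                        age, first_available_year, sex
                    )
    return out


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != columns:
        raise ValidationError(
            f"{path.name}: expected header {','.join(columns)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        raise ValidationError(f"{path.name}: no rows")
    return df
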