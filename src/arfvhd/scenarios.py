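"""Acute-rheumatic-fever incidence surface.

The annual probability of a first ARF episode factorises as

    lambda(a, t) = r_t / 100000 * s(a)

where ``r_t`` is the *reference incidence rate* (the plateau rate at
ages 5-15, per 100,000 per year) for calendar year ``t``, and ``s(a)``
is a fixed age shape: zero up to age 3, linear ramp to 1 at age 5, a
plateau of 1 through age 15, linear decline to zero at age 25, zero
thereafter. Incidence is identical for both sexes.

Reference-rate time series are piecewise-linear in calendar year between
user-supplied breakpoints and zero outside their span. Three default
historical scenarios are provided as documented approximations of
mid-century European surveillance (Denmark-like decline; upper and lower
bounds of early-1950s England), since the source curves are not
tabulated anywhere machine-readable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

#: (age, multiplier) vertices of the age shape s(a).
AGE_SHAPE_BREAKPOINTS: tuple[tuple[float, float], ...] = (
    (3.0, 0.0),
    (5.0, 1.0),
    (15.0, 1.0),
    (25.0, 0.0),
)


def age_shape(age: float) -> float:
    """Age multiplier s(a) in [0, 1]; exact 0 outside (3, 25)."""
    if age < 0:
        raise ValueError(f"negative age {age}")
    xs = [a for a, _ in AGE_SHAPE_BREAKPOINTS]
    ys = [v for _, v in AGE_SHAPE_BREAKPOINTS]
    return float(np.interp(age, xs, ys, left=0.0, right=0.0))


@dataclass(frozen=True)
class IncidenceScenario:
    """Piecewise-linear reference-rate curve r_t (per 100,000 per year)."""

    name: str
    breakpoints: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("scenario needs at least one breakpoint")
        if any(rate < 0 for _, rate in self.breakpoints):
            raise ValueError("reference rates must be >= 0")
        years = [y for y, _ in self.breakpoints]
        if years != sorted(years):
            raise ValueError("breakpoints must be sorted by year")


def reference_rate(scenario: IncidenceScenario, year: float) -> float:
    """r_t per 100,000: linear between breakpoints, 0 outside their span."""
    years = [y for y, _ in scenario.breakpoints]
    rates = [r for _, r in scenario.breakpoints]
    if year < years[0] or year > years[-1]:
        return 0.0
    return float(np.interp(year, years, rates))


def incidence(scenario: IncidenceScenario, age: int, year: int) -> float:
    """Annual first-ARF probability lambda(a, t); sex-symmetric."""
    return reference_rate(scenario, year) / 100_000.0 * age_shape(age)


def default_scenarios() -> list[IncidenceScenario]:
    """The three core reference-rate scenarios (documented approximations).

    1. 100/100k in 1940 declining linearly to 0 by 1986 (Denmark-like).
    2. 62.5/100k plateau through 1950 (England upper bound), 0 from 1965.
    3. Same shape as 2 at the England lower bound, 37.5/100k.
    """
    return [
        IncidenceScenario("scenario1", ((1940, 100.0), (1986, 0.0))),
        IncidenceScenario(
            "scenario2", ((1940, 62.5), (1950, 62.5), (1965, 0.0))
        ),
        IncidenceScenario(
            "scenario3", ((1940, 37.5), (1950, 37.5), (1965, 0.0))
        ),
    ]


#: Sub-scenario letter -> fraction of ARF patients developing VHD.
VHD_FRACTIONS: dict[str, float] = {"a": 0.50, "b": 0.40}


def load_scenario(path: str | Path) -> tuple[IncidenceScenario, float | None]:
    """Load a scenario YAML: ``name``, ``breakpoints``, optional ``vhd_fraction``."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    scenario = IncidenceScenario(
        name=str(spec["name"]),
        breakpoints=tuple((int(y), float(r)) for y, r in spec["breakpoints"]),
    )
    frac = spec.get("vhd_fraction")
    return scenario, (float(frac) if frac is not None else None)


def dump_scenario(
    scenario: IncidenceScenario, path: str | Path, vhd_fraction: float | None = None
) -> None:
    spec: dict = {
        "name": scenario.name,
        "breakpoints": [[int(y), float(r)] for y, r in scenario.breakpoints],
    }
    if vhd_fraction is not None:
        spec["vhd_fraction"] = vhd_fraction
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
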