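"""Conditional probability of ARF-related VHD and its sensitivity grid.

The headline quantity is

    P(ARF-VHD | VHD and benfluorex intake)
        = P(ARF-VHD) / P(VHD | benfluorex intake)

valid when benfluorex intake is independent of ARF history and patients
with ARF-VHD cannot additionally develop drug-induced VHD. The
numerator is the 2013 prevalence of ARF-related VHD among survivors of
the 1940-1960 birth cohort, taken from the Markov engine; the
denominator is the echo-based VHD probability in benfluorex-treated
patients (16%, varied 7-22% in sensitivity analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .demography import BirthSeries, LifeTable
from .markov import CohortStateTable, DiseaseParams, run_model
from .scenarios import VHD_FRACTIONS, IncidenceScenario


@dataclass(frozen=True)
class BenfluorexParams:
    """P(VHD | benfluorex intake) point estimate and sensitivity range."""

    p_vhd_given_benfluorex: float = 0.16
    sensitivity_range: tuple[float, float] = (0.07, 0.22)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_vhd_given_benfluorex <= 1.0:
            raise ValueError("p_vhd_given_benfluorex must be in (0, 1]")
        lo, hi = self.sensitivity_range
        if not lo <= hi:
            raise ValueError("sensitivity range bounds out of order")


def prevalence_final_year(
    result: CohortStateTable,
    sex: str | None = None,
    birth_year: int | None = None,
) -> float:
    """P(ARF-related VHD) among cohort members alive in the final year.

    ``sex`` None means both sexes pooled; ``birth_year`` None pools all
    birth years.
    """
    df = result.final_states()
    if sex is not None:
        df = df[df.sex == sex]
    if birth_year is not None:
        df = df[df.birth_year == birth_year]
    alive = float((df.arf_free + df.post_arf_no_vhd + df.arf_vhd).sum())
    if alive == 0:
        raise ValueError(
            f"no survivors in stratum (sex={sex}, birth_year={birth_year})"
        )
    return float(df.arf_vhd.sum()) / alive


def conditional_probability(p_arf_vhd: float, p_benfluorex: float) -> float:
    """P(ARF-VHD | VHD and exposure) = P(ARF-VHD) / P(VHD | exposure)."""
    if p_benfluorex == 0:
        raise ValueError("P(VHD | benfluorex) must be > 0")
    ratio = p_arf_vhd / p_benfluorex
    if ratio > 1.0:
        warnings.warn(
            f"conditional probability {ratio:.4g} exceeds 1; "
            "numerator is not consistent with the denominator",
            stacklevel=2,
        )
    return ratio


def scenario_grid(
    births: BirthSeries,
    table: LifeTable,
    scenarios: list[IncidenceScenario],
    benfluorex: BenfluorexParams = BenfluorexParams(),
    vhd_fractions: dict[str, float] = VHD_FRACTIONS,
    base_params: DiseaseParams = DiseaseParams(),
) -> pd.DataFrame:
    """Full sensitivity grid: scenarios x VHD fractions x sexes x p values.

    One Markov run per (incidence scenario, VHD fraction); rows report
    the conditional probability in percent (full precision) for p at the
    point estimate and both sensitivity bounds, for sexes all/male/female.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    lo, hi = benfluorex.sensitivity_range
    p_values = [benfluorex.p_vhd_given_benfluorex, lo, hi]
    rows = []
    for scenario in scenarios:
        for letter, fraction in sorted(vhd_fractions.items()):
            params = DiseaseParams(
                vhd_fraction=fraction,
                hazard_ratio=base_params.hazard_ratio,
                excess_mortality_start_age=base_params.excess_mortality_start_age,
                final_year=base_params.final_year,
            )
            result = run_model(births, table, scenario, params)
            for sex_label in ("all", "male", "female"):
                sex = None if sex_label == "all" else sex_label
                prev = prevalence_final_year(result, sex=sex)
                for p in p_values:
                    rows.append(
                        {
                            "scenario": f"{scenario.name}{letter}",
                            "sex": sex_label,
                            "p_benfluorex": p,
                            "probability_percent": 100.0
                            * conditional_probability(prev, p),
                        }
                    )
    return pd.DataFrame(rows)


def by_birth_year(
    results: dict[str, CohortStateTable],
    benfluorex: BenfluorexParams = BenfluorexParams(),
) -> pd.DataFrame:
    """Per-birth-year conditional probability at the point-estimate p.

    ``results`` maps scenario labels to completed Markov runs covering
    birth years 1940-1960.
    """
    p = benfluorex.p_vhd_given_benfluorex
    rows = []
    for label, result in results.items():
        for birth_year in result.births.years:
            prev = prevalence_final_year(result, birth_year=birth_year)
            rows.append(
                {
                    "scenario": label,
                    "birth_year": birth_year,
                    "probability_percent": 100.0 * conditional_probability(prev, p),
                }
            )
    return pd.DataFrame(rows)


def anchored_cell(
    anchor_percent: float,
    p_target: float,
    p_anchor: float = 0.16,
    numerator_scale: float = 1.0,
) -> float:
    """Sensitivity cell derived from a published point estimate.

    Given a conditional probability ``anchor_percent`` (in percent)
    computed at ``p_anchor``, recover the implied ARF-VHD prevalence and
    re-evaluate at ``p_target``, optionally rescaling the numerator
    (e.g. by the VHD-fraction ratio 0.40/0.50, exact by the engine's
    linearity in the VHD fraction). Returns percent at full precision.
    """
    prevalence = (anchor_percent / 100.0) * p_anchor
    return 100.0 * conditional_probability(prevalence * numerator_scale, p_target)


def format_table(grid: pd.DataFrame, benfluorex: BenfluorexParams = BenfluorexParams()) -> pd.DataFrame:
    """Presentation table: point estimate with the (high-p, low-p) band.

    One row per (scenario, sex): ``point (low; high)`` percent strings,
    half-even rounded to 2 decimals, band ordered (value at the upper p
    bound, value at the lower p bound) so it reads (low, high).
    """
    lo, hi = benfluorex.sensitivity_range
    p0 = benfluorex.p_vhd_given_benfluorex
    out = []
    for (scenario, sex), g in grid.groupby(["scenario", "sex"], sort=False):
        vals = {round(r.p_benfluorex, 6): r.probability_percent for r in g.itertuples()}
        out.append(
            {
                "scenario": scenario,
                "sex": sex,
                "formatted": f"{_r2(vals[p0])} ({_r2(vals[hi])};{_r2(vals[lo])})",
            }
        )
    return pd.DataFrame(out)


def _r2(x: float) -> str:
    # round-half-even via float formatting
    return f"{round(x, 2):.2f}"
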