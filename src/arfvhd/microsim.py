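"""Individual-level Monte-Carlo oracle for the cohort model.

Samples whole life courses (birth, annual death/ARF events, ARF-VHD,
and a final-year benfluorex-VHD assignment) with exactly the same event
order as the deterministic Markov engine: mortality at the current age,
then ARF incidence evaluated at the new age. It serves two purposes:

* an independent check that the engine's expected state counts are the
  mean of the individual-level process, and
* an end-to-end validation of the conditional-probability formula
  P(ARF-VHD | VHD and exposure) = P(ARF-VHD) / P(VHD | exposure) under
  the independence assumptions (benfluorex-VHD assigned independently
  of ARF history, never on top of ARF-VHD).

Exposure and drug-induced VHD are assigned once, at the final-year
cross-section, matching a 2013 screening snapshot. Randomness comes
from per-cohort, per-purpose generator streams; uniforms are drawn as
(individual x year) matrices in row-major order, so enlarging n appends
individuals without reshuffling the life courses of earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import SEXES, BirthSeries, LifeTable
from .markov import DiseaseParams, hazard_adjust
from .scenarios import IncidenceScenario, incidence

ARF_FREE, POST_ARF, ARF_VHD, DEAD = 0, 1, 2, 3
_STATE_NAMES = {
    ARF_FREE: "arf_free",
    POST_ARF: "post_arf_no_vhd",
    ARF_VHD: "arf_vhd",
    DEAD: "dead",
}
# purpose ids for independent random streams
_P_DEATH, _P_ARF, _P_VHD, _P_EXPOSURE, _P_BENF = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class MicrosimConfig:
    n_individuals: int
    seed: int
    births: BirthSeries
    life_table: LifeTable
    scenario: IncidenceScenario
    params: DiseaseParams = field(default_factory=DiseaseParams)
    p_exposure: float = 1.0
    p_vhd_given_benfluorex: float = 0.16

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("p_exposure", "p_vhd_given_benfluorex"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {p}")


@dataclass
class MicrosimResult:
    """Final-year cross-section of the simulated population."""

    n: int
    state_counts: dict[str, int]
    counts_by_cohort: pd.DataFrame
    allocation: BirthSeries
    prevalence: float              # P(ARF-VHD | alive)
    prevalence_se: float
    p_arf_vhd_given_vhd_exposed: float
    p_arf_vhd_given_vhd_exposed_se: float
    n_alive: int
    n_vhd_exposed: int

    def state_fractions(self) -> dict[str, float]:
        return {k: v / self.n for k, v in self.state_counts.items()}


def allocate_individuals(births: BirthSeries, n: int) -> dict[tuple[int, str], int]:
    """Deterministic largest-remainder allocation of n individuals
    across (birth year, sex) cells, proportional to births."""
    keys = sorted(births.counts)
    total = births.total()
    quotas = {k: n * births.counts[k] / total for k in keys}
    alloc = {k: int(math.floor(quotas[k])) for k in keys}
    short = n - sum(alloc.values())
    for k in sorted(keys, key=lambda k: quotas[k] - alloc[k], reverse=True)[:short]:
        alloc[k] += 1
    return alloc


def microsimulate(config: MicrosimConfig) -> MicrosimResult:
    params = config.params
    alloc = allocate_individuals(config.births, config.n_individuals)
    cohorts = sorted(alloc)

    cohort_rows = []
    arf_vhd_alive = 0
    alive_total = 0
    exposed_arf_vhd = 0
    exposed_any_vhd = 0
    state_counts = {name: 0 for name in _STATE_NAMES.values()}

    for cohort_id, (birth_year, sex) in enumerate(cohorts):
        n_c = alloc[(birth_year, sex)]
        if n_c == 0:
            continue
        n_years = params.final_year - birth_year
        u_death = _stream(config.seed, cohort_id, _P_DEATH).random((n_c, n_years))
        u_arf = _stream(config.seed, cohort_id, _P_ARF).random((n_c, n_years))
        u_vhd = _stream(config.seed, cohort_id, _P_VHD).random((n_c, n_years))

        state = np.full(n_c, ARF_FREE, dtype=np.int8)
        for k, t in enumerate(range(birth_year, params.final_year)):
            age = t - birth_year
            q = config.life_table.q(age, t, sex)
            if age >= params.excess_mortality_start_age:
                q_vhd = hazard_adjust(q, params.hazard_ratio)
            else:
                q_vhd = q
            dies = ((state == ARF_FREE) | (state == POST_ARF)) & (u_death[:, k] < q)
            dies |= (state == ARF_VHD) & (u_death[:, k] < q_vhd)
            state[dies] = DEAD
            lam = incidence(config.scenario, age + 1, t + 1)
            if lam > 0.0:
                new_arf = (state == ARF_FREE) & (u_arf[:, k] < lam)
                to_vhd = new_arf & (u_vhd[:, k] < params.vhd_fraction)
                state[new_arf] = POST_ARF
                state[to_vhd] = ARF_VHD

        exposed = (
            _stream(config.seed, cohort_id, _P_EXPOSURE).random(n_c)
            < config.p_exposure
        )
        # drug-induced VHD never assigned on top of ARF-VHD
        benf_vhd = (
            exposed
            & (state != DEAD)
            & (state != ARF_VHD)
            & (
                _stream(config.seed, cohort_id, _P_BENF).random(n_c)
                < config.p_vhd_given_benfluorex
            )
        )

        alive = state != DEAD
        alive_total += int(alive.sum())
        arf_vhd_alive += int((state == ARF_VHD).sum())
        exposed_arf_vhd += int((exposed & (state == ARF_VHD)).sum())
        exposed_any_vhd += int((exposed & alive & ((state == ARF_VHD) | benf_vhd)).sum())
        row = {"birth_year": birth_year, "sex": sex, "n": n_c}
        for code, name in _STATE_NAMES.items():
            c = int((state == code).sum())
            row[name] = c
            state_counts[name] += c
        cohort_rows.append(row)

    prevalence = arf_vhd_alive / alive_total if alive_total else float("nan")
    prev_se = (
        math.sqrt(prevalence * (1 - prevalence) / alive_total) if alive_total else float("nan")
    )
    if exposed_any_vhd:
        p_cond = exposed_arf_vhd / exposed_any_vhd
        p_cond_se = math.sqrt(p_cond * (1 - p_cond) / exposed_any_vhd)
    else:
        p_cond, p_cond_se = float("nan"), float("nan")

    return MicrosimResult(
        n=config.n_individuals,
        state_counts=state_counts,
        counts_by_cohort=pd.DataFrame(cohort_rows),
        allocation=BirthSeries({k: float(v) for k, v in alloc.items()}),
        prevalence=prevalence,
        prevalence_se=prev_se,
        p_arf_vhd_given_vhd_exposed=p_cond,
        p_arf_vhd_given_vhd_exposed_se=p_cond_se,
        n_alive=alive_total,
        n_vhd_exposed=exposed_any_vhd,
    )


def _stream(seed: int, cohort_id: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, cohort_id, purpose]))
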