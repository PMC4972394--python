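"""Markov cohort engine: hazard adjustment, cycle update, full runs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import arfvhd as av
from arfvhd.markov import step_cohort

# Age multipliers at integer ages 4..24, written out independently of the
# scenarios module: ramp midpoint, 11 plateau years, declining tail.
S_BY_AGE = {4: 0.5}
S_BY_AGE.update({a: 1.0 for a in range(5, 16)})
S_BY_AGE.update({15 + k: 1.0 - 0.1 * k for k in range(1, 10)})


def lifetime_arf_probability(rate_per_100k: float) -> float:
    """Direct-product oracle: P(ever ARF) for an immortal cohort under a
    flat reference rate."""
    p_escape = 1.0
    for a in range(4, 25):
        p_escape *= 1.0 - rate_per_100k / 100_000.0 * S_BY_AGE[a]
    return 1.0 - p_escape


class TestHazardAdjust:
    def test_zero_mortality_stays_zero(self):
        assert av.hazard_adjust(0.0, 1.5) == 0.0

    def test_identity_at_unit_hazard_ratio(self):
        assert av.hazard_adjust(0.3, 1.0) == pytest.approx(0.3, rel=1e-15)

    def test_closed_form_at_hr_1_5(self):
        # 1 - 0.99^1.5, cross-checked by scaling the constant hazard -ln(0.99)
        expected = 1.0 - 0.99**1.5
        assert av.hazard_adjust(0.01, 1.5) == pytest.approx(expected, rel=1e-14)
        hazard_route = -math.expm1(-1.5 * -math.log(0.99))
        assert av.hazard_adjust(0.01, 1.5) == pytest.approx(hazard_route, rel=1e-14)

    def test_certain_death_stays_certain(self):
        assert av.hazard_adjust(1.0, 1.5) == 1.0

    @given(
        st.floats(min_value=0, max_value=1, allow_nan=False),
        st.floats(min_value=0.01, max_value=10, allow_nan=False),
    )
    @settings(derandomize=True)
    def test_stays_a_probability(self, q, hr):
        adj = av.hazard_adjust(q, hr)
        assert 0.0 <= adj <= 1.0
        if hr >= 1.0:
            assert adj >= q - 1e-15
        else:
            assert adj <= q + 1e-15


class TestStepCohort:
    def test_hand_arithmetic_of_update(self):
        params = av.DiseaseParams(vhd_fraction=0.5)
        step = step_cohort((1000.0, 0.0, 0.0, 0.0), q=0.0, incidence_next=0.01,
                           params=params, age=10)
        assert step.state == pytest.approx((990.0, 5.0, 5.0, 0.0))
        assert step.new_arf_cases == pytest.approx(10.0)

    def test_null_step_leaves_state_unchanged(self):
        params = av.DiseaseParams()
        state = (800.0, 60.0, 40.0, 100.0)
        step = step_cohort(state, q=0.0, incidence_next=0.0, params=params, age=30)
        assert step.state == pytest.approx(state)
        assert step.new_arf_cases == 0.0

    def test_all_dead_is_absorbing(self):
        params = av.DiseaseParams()
        step = step_cohort((0.0, 0.0, 0.0, 1000.0), q=0.5, incidence_next=0.1,
                           params=params, age=30)
        assert step.state == pytest.approx((0.0, 0.0, 0.0, 1000.0))

    def test_excess_mortality_only_from_start_age(self):
        params = av.DiseaseParams(hazard_ratio=1.5, excess_mortality_start_age=20)
        young = step_cohort((0.0, 0.0, 100.0, 0.0), 0.01, 0.0, params, age=19)
        old = step_cohort((0.0, 0.0, 100.0, 0.0), 0.01, 0.0, params, age=20)
        assert young.state[2] == pytest.approx(100.0 * 0.99)
        assert old.state[2] == pytest.approx(100.0 * 0.99**1.5)

    @given(
        st.floats(min_value=0, max_value=1, allow_nan=False),
        st.floats(min_value=0, max_value=0.05, allow_nan=False),
        st.integers(min_value=0, max_value=80),
    )
    @settings(derandomize=True)
    def test_conservation_and_nonnegativity(self, q, lam, age):
        params = av.DiseaseParams()
        state = (700.0, 200.0, 50.0, 50.0)
        step = step_cohort(state, q, lam, params, age)
        assert all(x >= 0 for x in step.state)
        assert sum(step.state) == pytest.approx(sum(state), rel=1e-12)


@pytest.fixture(scope="module")
def flat_scenario():
    return av.IncidenceScenario("flat10", ((1930, 10.0), (2020, 10.0)))


@pytest.fixture(scope="module")
def immortal_run(zero_mortality_table, flat_scenario):
    births = av.BirthSeries.single_cohort(1950, 1000)
    return av.run_model(births, zero_mortality_table, flat_scenario,
                        av.DiseaseParams(vhd_fraction=0.5))


class TestRunModel:
    def test_null_scenario_never_produces_vhd(self, births, life_table):
        null = av.IncidenceScenario("null", ((1940, 0.0), (1986, 0.0)))
        result = av.run_model(births, life_table, null)
        assert (result.df.arf_vhd == 0).all()
        assert av.count_arf_cases(result) == 0.0

    def test_single_immortal_cohort_matches_product_oracle(self, immortal_run):
        expected = 1000.0 * lifetime_arf_probability(10.0)
        assert av.count_arf_cases(immortal_run) == pytest.approx(expected, rel=1e-9)
        vhd_2013 = immortal_run.final_states().arf_vhd.sum()
        assert vhd_2013 == pytest.approx(expected / 2.0, rel=1e-9)

    def test_conservation_on_synthetic_demography(self, births, life_table):
        result = av.run_model(births, life_table, av.default_scenarios()[0])
        assert result.conservation_error() < 1e-6

    def test_dead_counts_never_decrease(self, births, life_table):
        result = av.run_model(births, life_table, av.default_scenarios()[0])
        for _, g in result.df.groupby(["birth_year", "sex"]):
            dead = g.sort_values("calendar_year").dead.values
            assert (np.diff(dead) >= -1e-9).all()

    def test_vhd_never_alters_totals_at_unit_hazard_ratio(self, births, life_table):
        sc = av.default_scenarios()[0]
        with_vhd = av.run_model(
            births, life_table, sc, av.DiseaseParams(vhd_fraction=0.5, hazard_ratio=1.0)
        )
        without = av.run_model(
            births, life_table, sc, av.DiseaseParams(vhd_fraction=0.0, hazard_ratio=1.0)
        )
        a = with_vhd.final_states()
        b = without.final_states()
        alive_a = (a.arf_free + a.post_arf_no_vhd + a.arf_vhd).sum()
        alive_b = (b.arf_free + b.post_arf_no_vhd + b.arf_vhd).sum()
        assert alive_a == pytest.approx(alive_b, rel=1e-12)

    def test_exact_linearity_in_vhd_fraction(self, births, life_table):
        sc = av.default_scenarios()[1]
        res_a = av.run_model(births, life_table, sc, av.DiseaseParams(vhd_fraction=0.5))
        res_b = av.run_model(births, life_table, sc, av.DiseaseParams(vhd_fraction=0.4))
        vhd_a = res_a.final_states().arf_vhd.sum()
        vhd_b = res_b.final_states().arf_vhd.sum()
        assert vhd_b / vhd_a == pytest.approx(0.8, rel=1e-12)

    def test_near_linearity_in_reference_rate(self, zero_mortality_table):
        births = av.BirthSeries.single_cohort(1950, 1000)
        base = av.IncidenceScenario("r25", ((1930, 25.0), (2020, 25.0)))
        quadruple = av.IncidenceScenario("r100", ((1930, 100.0), (2020, 100.0)))
        c1 = av.count_arf_cases(av.run_model(births, zero_mortality_table, base))
        c4 = av.count_arf_cases(av.run_model(births, zero_mortality_table, quadruple))
        assert c4 / c1 == pytest.approx(4.0, rel=0.01)
        assert c4 / c1 < 4.0  # depletion makes it sublinear

    def test_missing_life_table_cell_names_the_cell(self, flat_scenario):
        births = av.BirthSeries.single_cohort(1950, 1000)
        table = av.LifeTable({(0, 1950, "male"): 0.0})
        with pytest.raises(av.ValidationError, match=r"age=0, year=1940, sex=male"):
            av.run_model(births, table, flat_scenario)


class TestCountArfCases:
    def test_sex_strata_sum_to_total(self, births, life_table):
        result = av.run_model(births, life_table, av.default_scenarios()[2])
        by_sex = av.count_arf_cases(result, by="sex")
        assert by_sex.sum() == pytest.approx(av.count_arf_cases(result), rel=1e-12)
        assert set(by_sex.index) == {"male", "female"}

    def test_birth_year_strata_sum_to_total(self, births, life_table):
        result = av.run_model(births, life_table, av.default_scenarios()[2])
        by_year = av.count_arf_cases(result, by="birth_year")
        assert by_year.sum() == pytest.approx(av.count_arf_cases(result), rel=1e-12)
        assert list(by_year.index) == list(range(1940, 1961))
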