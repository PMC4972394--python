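import pytest

import arfvhd as av

SEXES = ("male", "female")


@pytest.fixture(scope="session")
def demo_params():
    return av.SyntheticDemographyParams()


@pytest.fixture(scope="session")
def life_table(demo_params):
    return av.make_life_table(demo_params)


@pytest.fixture(scope="session")
def births(demo_params):
    return av.make_births(demo_params)


@pytest.fixture(scope="session")
def zero_mortality_table():
    """Immortal population: isolates incidence dynamics from survival."""
    return av.LifeTable(
        {
            (age, year, sex): 0.0
            for age in range(111)
            for year in range(1940, 2013)
            for sex in SEXES
        }
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, demo_params):
    out = tmp_path_factory.mktemp("bundle")
    return av.make_fixture_bundle(out, demo_params)
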