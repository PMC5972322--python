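import pytest
from hypothesis import settings

import cordfit as cf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return cf.load_morphometry_table()


@pytest.fixture(scope="session")
def thoracic_pop(table):
    """The stated study simulation: 200 draws per level, restricted to T2-T12."""
    pop = cf.simulate_population(table, cf.SimulationConfig(n_per_segment=200, seed=20))
    return pop.restrict(cf.ANALYSIS_SEGMENTS)


@pytest.fixture(scope="session")
def small_pop(table):
    """A light thoracic sample for optimizer and pipeline tests."""
    pop = cf.simulate_population(
        table, cf.SimulationConfig(n_per_segment=40, seed=11, segments=cf.ANALYSIS_SEGMENTS)
    )
    return pop


@pytest.fixture(scope="session")
def configured_catalog(table, thoracic_pop):
    return cf.build_configured_catalog(table, population=thoracic_pop)
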