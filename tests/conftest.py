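import numpy as np
import pytest

from pgsace.synthetic_data import (
    SimulationConfig,
    make_power_scenario,
    null_scenario,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort with real effects, shared across read-only tests."""
    cfg = SimulationConfig(n=4000, or_matrix=((1.10,) * 6,) * 8)
    return simulate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no PGS->ACE and no ACE->outcome effects."""
    return simulate_cohort(null_scenario(n=4000), seed=202)


@pytest.fixture(scope="session")
def h2a_cohort():
    """Large cohort under the mediation power scenario (known paths)."""
    return simulate_cohort(make_power_scenario("h2a", n=20000), seed=303)
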