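import numpy as np
import pytest

from turtur.demographic_models import DemographicScenario, build_scenario, table1_draw


@pytest.fixture
def rng():
    return np.random.default_rng(20161107)


@pytest.fixture(scope="session")
def constant_demography():
    """Constant-size history, diploid Ne = 10,000."""
    return DemographicScenario(scenario_id=1, epochs=((0.0, 10_000.0),))


@pytest.fixture(scope="session")
def scenario4_demography():
    """The winning two-change history at the reported posterior means."""
    return build_scenario(table1_draw())
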