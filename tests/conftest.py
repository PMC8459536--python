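import numpy as np
import pytest

from haplocross import SimulationConfig, simulate_study, table2_fixture


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture(scope="session")
def study_records():
    """One deterministic synthetic study dataset (49 parental + 16 backcross)."""
    return simulate_study(SimulationConfig(seed=1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
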