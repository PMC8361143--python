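import numpy as np
import pytest

from lipidmrm import SimulationConfig, default_classes


@pytest.fixture(scope="session")
def classes():
    return default_classes()


@pytest.fixture(scope="session")
def config():
    """Default study configuration: 6 replicates, 10% noise, default grid."""
    return SimulationConfig(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
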