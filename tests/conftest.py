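import numpy as np
import pytest

from chromstate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=60, plad_count=8)


@pytest.fixture(scope="session")
def small_genome(small_config):
    """Genes, segmentation and PLADs for one fixed-seed toy genome."""
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
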