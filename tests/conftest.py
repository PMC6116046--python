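import numpy as np
import pytest

from neosex import SimulationConfig, simulate_gene_set


@pytest.fixture(scope="session")
def default_genes():
    """A moderate simulated gene set under package defaults."""
    cfg = SimulationConfig(n_genes=60, codons_per_gene=300, seed=101)
    return cfg, simulate_gene_set(cfg)


@pytest.fixture(scope="session")
def clean_config():
    """Defaults with corruption switched off."""
    return SimulationConfig(n_genes=12, codons_per_gene=200, seed=7).with_corruption(0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
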