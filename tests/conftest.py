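import numpy as np
import pytest

from rdriver.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted cohort shared by fast tests (60 samples, 30 genes)."""
    cfg = SimulationConfig(
        n_samples=60,
        n_genes=30,
        n_alleles=8,
        n_drivers=2,
        genes_per_driver=6,
        allele_frequency=(0.1, 0.3),
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
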