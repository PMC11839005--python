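import numpy as np
import pandas as pd
import pytest

from plasmanet import SimulationConfig, simulate_dataset
from plasmanet.synthetic import gene_annotation, protein_gene_map


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples=300, n_genes=12, n_tissues=3, snps_per_gene=10,
        n_modules=4, module_size=4, rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(genotypes, expression, proteins, truth, factors) bundle."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_config) -> pd.DataFrame:
    return gene_annotation(small_config)


@pytest.fixture(scope="session")
def small_p2g(small_config) -> dict:
    return protein_gene_map(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
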