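import numpy as np
import pytest

from gevm.preprocessing import CountMatrix, filter_genes, gene_stats
from gevm.simulator import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_homogeneous():
    """A small NB dataset with known (alpha, beta) and no heterogeneity."""
    config = SimConfig(
        n_genes=4_000, n_cells=400, master_mean=10.0, alpha=0.15, beta=1.2, prct=0.0, seed=7
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_homogeneous_stats(small_homogeneous):
    return gene_stats(filter_genes(small_homogeneous.counts))


def make_counts(values, normalized=False):
    values = np.asarray(values)
    return CountMatrix(
        values=values,
        gene_ids=np.array([f"g{i}" for i in range(values.shape[0])], dtype=object),
        cell_ids=np.array([f"c{j}" for j in range(values.shape[1])], dtype=object),
        normalized=normalized,
    )
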