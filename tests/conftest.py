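import numpy as np
import pytest

from gbnea import DirectedNetwork, ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_network_pair():
    """Hand-sized network pair over genes a..e with known statistics."""
    genes = ("a", "b", "c", "d", "e")
    net_c = DirectedNetwork(genes, {("a", "b"): 2.0, ("a", "c"): -3.0,
                                    ("b", "c"): 1.0})
    net_n = DirectedNetwork(genes, {("a", "b"): 2.0, ("d", "c"): 0.5})
    return net_c, net_n


def make_dataset(rng, n_genes=8, n_per_group=10, noise=1.0,
                 labels=("C", "N")):
    """Unstructured two-group expression dataset (pure noise)."""
    n = 2 * n_per_group
    values = 5.0 + noise * rng.standard_normal((n_genes, n))
    gene_ids = tuple(f"g{i}" for i in range(n_genes))
    sample_ids = tuple(f"s{i}" for i in range(n))
    phenotype = (labels[0],) * n_per_group + (labels[1],) * n_per_group
    return ExpressionDataset(values, gene_ids, sample_ids, phenotype)


@pytest.fixture
def noise_dataset(rng):
    return make_dataset(rng)
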