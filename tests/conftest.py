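import numpy as np
import pytest

from gcnlmf import (
    GeneNetwork,
    LabeledGeneSet,
    PlantedScenario,
    generate_labels,
    generate_network,
    sample_negatives,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_network(rng, n=8, density=0.4):
    """Small random symmetric weighted network for round-trip/algebra tests."""
    upper = np.triu(rng.random((n, n)) < density, k=1)
    W = np.round(rng.uniform(0.1, 1.0, (n, n)), 6)
    A = np.where(upper, W, 0.0)
    A = A + A.T
    genes = [f"GENE{i}" for i in range(n)]
    return GeneNetwork(genes, A)


@pytest.fixture
def small_scenario():
    """A compact planted-module instance with a strong topological signal."""
    return PlantedScenario(
        n_genes=100,
        module_size=20,
        p_in=0.6,
        p_out=0.04,
        n_positives_labeled=20,
        label_noise=0.0,
        seed=5,
    )


@pytest.fixture
def small_benchmark(small_scenario):
    """(network, labels-with-negatives, truth) for the small scenario."""
    network, truth = generate_network(small_scenario)
    labels = generate_labels(truth, network, small_scenario)
    negatives = sample_negatives(set(network.genes), labels.positives, 50, seed=9)
    labels = LabeledGeneSet(labels.positives, negatives, source="small benchmark")
    return network, labels, truth
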