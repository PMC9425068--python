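"""Planted-module synthetic networks.

A planted partition (two-parameter stochastic block model): one module of
``module_size`` genes whose internal pairs are edged with probability
``p_in``, all other pairs with the background probability ``p_out``.  The
module stands in for a disease gene module — real disease genes interact
with each other more densely than with the background proteome — and the
module member set is the ground truth for benchmarking.  Edges are
unweighted (weight 1.0): the prioritization signal under study is purely
topological.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GeneNetwork, LabeledGeneSet

__all__ = [
    "PlantedScenario",
    "generate_network",
    "generate_labels",
    "reference_scenario",
]


@dataclass
class PlantedScenario:
    """Parameters of one planted-module benchmark instance."""

    n_genes: int = 500
    module_size: int = 40
    p_in: float = 0.30
    p_out: float = 0.02
    n_positives_labeled: int = 40
    label_noise: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if not (1 <= self.module_size <= self.n_genes):
            raise ValueError("module_size must lie in [1, n_genes]")
        for name in ("p_in", "p_out", "label_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.n_positives_labeled < 1:
            raise ValueError("n_positives_labeled must be >= 1")
        if self.label_noise == 0 and self.n_positives_labeled > self.module_size:
            raise ValueError(
                "n_positives_labeled cannot exceed module_size at label_noise=0"
            )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(scenario: PlantedScenario) -> tuple[GeneNetwork, set[str]]:
    """Sample one planted-module network; returns (network, truth set).

    Deterministic under ``scenario.seed``.  The module members are a seeded
    random subset of the gene universe.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_genes
    genes = _gene_names(n)
    members = rng.choice(n, size=scenario.module_size, replace=False)
    in_module = np.zeros(n, dtype=bool)
    in_module[members] = True
    P = np.full((n, n), scenario.p_out)
    P[np.ix_(in_module, in_module)] = scenario.p_in
    U = rng.random((n, n))
    upper = np.triu(U < P, k=1)
    A = (upper | upper.T).astype(float)
    truth = {genes[i] for i in np.nonzero(in_module)[0]}
    return GeneNetwork(genes, A), truth


def generate_labels(
    truth: set[str], network: GeneNetwork, scenario: PlantedScenario
) -> LabeledGeneSet:
    """Draw the labeled positive set from the planted module.

    ``floor(label_noise * n_positives_labeled)`` positives are mislabeled —
    drawn from outside the module — and the rest from inside.  Negatives are
    left empty; sample them with
    :func:`gcnlmf.evaluation.sample_negatives`.
    """
    rng = np.random.default_rng([scenario.seed, 1])
    n_out = int(np.floor(scenario.label_noise * scenario.n_positives_labeled))
    n_in = scenario.n_positives_labeled - n_out
    inside = sorted(truth)
    outside = sorted(set(network.genes) - truth)
    if n_in > len(inside) or n_out > len(outside):
        raise ValueError(
            f"cannot draw {n_in} module + {n_out} background positives from "
            f"{len(inside)} module and {len(outside)} background genes"
        )
    positives = set(rng.choice(inside, size=n_in, replace=False))
    positives |= set(rng.choice(outside, size=n_out, replace=False))
    return LabeledGeneSet(
        positives=positives,
        negatives=set(),
        source=f"planted-module simulation seed={scenario.seed}",
    )


def reference_scenario() -> PlantedScenario:
    """The pinned benchmark scenario.

    500 genes with a 40-gene module (p_in=0.30 vs background p_out=0.02),
    40 labeled positives with no label noise, seed 42 — sized to echo a
    41-positive disease gene study design.
    """
    return PlantedScenario(
        n_genes=500,
        module_size=40,
        p_in=0.30,
        p_out=0.02,
        n_positives_labeled=40,
        label_noise=0.0,
        seed=42,
    )
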