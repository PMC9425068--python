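"""Pinned planted-module benchmarks.

These wrap the full pipeline — scenario generation, negative sampling,
stratified 10-fold cross-validation — into the three standard checks used
throughout the package: the reference benchmark, its no-signal (null)
control, and the GCN-initialization ablation.
"""

from __future__ import annotations

import numpy as np

from .evaluation import CVResult, cross_validate, sample_negatives
from .model import GCNLMF
from .network import LabeledGeneSet
from .simulate import PlantedScenario, generate_labels, generate_network, reference_scenario

__all__ = ["benchmark_scenario", "reference_benchmark", "null_benchmark", "ablation_benchmark"]


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def benchmark_scenario(
    scenario: PlantedScenario,
    seed: int,
    estimator: GCNLMF | None = None,
    n_negatives: int = 200,
    k: int = 10,
) -> CVResult:
    """Generate a scenario, sample negatives, and cross-validate.

    ``seed`` drives negative sampling and fold assignment (the network and
    positive labels are pinned by ``scenario.seed``).
    """
    neg_seed, fold_seed = _derive_seeds(seed, 2)
    network, truth = generate_network(scenario)
    labels = generate_labels(truth, network, scenario)
    negatives = sample_negatives(
        set(network.genes), labels.positives, n_negatives, neg_seed
    )
    labels = LabeledGeneSet(labels.positives, negatives, source=labels.source)
    return cross_validate(network, labels, estimator=estimator, k=k, seed=fold_seed)


def reference_benchmark(seed: int = 42, estimator: GCNLMF | None = None) -> CVResult:
    """10-fold CV on the pinned reference scenario with 200 sampled negatives."""
    return benchmark_scenario(reference_scenario(), seed=seed, estimator=estimator)


def null_benchmark(n_seeds: int = 20, base_seed: int = 0) -> list[float]:
    """Mean CV AUC per seed with the module signal removed (p_in = p_out).

    With no planted signal the labels are arbitrary, so the mean AUC over
    seeds should sit near 0.5.
    """
    ref = reference_scenario()
    aucs = []
    for s in range(n_seeds):
        scenario = PlantedScenario(
            n_genes=ref.n_genes,
            module_size=ref.module_size,
            p_in=ref.p_out,
            p_out=ref.p_out,
            n_positives_labeled=ref.n_positives_labeled,
            label_noise=ref.label_noise,
            seed=base_seed + s,
        )
        aucs.append(benchmark_scenario(scenario, seed=base_seed + s).mean_auc)
    return aucs


def ablation_benchmark(n_seeds: int = 10, base_seed: int = 0) -> tuple[float, float]:
    """Mean CV AUC under GCN vs random latent-factor initialization.

    Both arms share the pinned reference network; the ``n_seeds`` replicates
    vary negative sampling, fold assignment, and the factorization's init
    seed.  Returns (mean_auc_gcn_init, mean_auc_random_init).
    """
    scenario = reference_scenario()
    means = {}
    for y_init in ("gcn", "random"):
        aucs = [
            benchmark_scenario(
                scenario,
                seed=base_seed + s,
                estimator=GCNLMF(y_init=y_init, init_seed=base_seed + s),
            ).mean_auc
            for s in range(n_seeds)
        ]
        means[y_init] = float(np.mean(aucs))
    return means["gcn"], means["random"]
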