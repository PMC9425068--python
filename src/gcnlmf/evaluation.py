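"""Negative sampling, stratified k-fold cross-validation, AUC and AUPR.

The protocol mirrors a standard disease-gene benchmark: a known positive
set, a uniformly sampled negative set (default 200 genes), and 10-fold
stratified cross-validation of the ranking, scored by ROC AUC (midrank /
Mann-Whitney form) and AUPR (step-wise average precision with ties broken
against the positive class).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .logmf import LogisticMF
from .model import GCNLMF, labels_to_arrays
from .network import GeneNetwork, LabeledGeneSet

__all__ = [
    "CVResult",
    "sample_negatives",
    "kfold_split",
    "compute_auc",
    "compute_aupr",
    "cross_validate",
    "score_file_eval",
]


@dataclass
class CVResult:
    """Per-fold AUC/AUPR with their mean and population standard deviation."""

    fold_auc: list[float]
    fold_aupr: list[float]
    mean_auc: float = field(init=False)
    sd_auc: float = field(init=False)
    mean_aupr: float = field(init=False)
    sd_aupr: float = field(init=False)
    seed: int = 0

    def __post_init__(self) -> None:
        auc = np.asarray(self.fold_auc, dtype=float)
        aupr = np.asarray(self.fold_aupr, dtype=float)
        if auc.shape != aupr.shape or auc.ndim != 1 or auc.size == 0:
            raise ValueError("fold metric lists must be equal-length, non-empty")
        if np.any((auc < 0) | (auc > 1)) or np.any((aupr < 0) | (aupr > 1)):
            raise ValueError("AUC/AUPR values must lie in [0, 1]")
        self.mean_auc = float(auc.mean())
        self.sd_auc = float(auc.std(ddof=0))
        self.mean_aupr = float(aupr.mean())
        self.sd_aupr = float(aupr.std(ddof=0))

    @property
    def k(self) -> int:
        return len(self.fold_auc)


def sample_negatives(universe, positives, n: int, seed: int) -> set[str]:
    """Uniform sample of n presumed-negative genes from universe \\ positives."""
    pool = sorted({g.upper() for g in universe} - {g.upper() for g in positives})
    if n > len(pool):
        raise ValueError(
            f"requested {n} negatives but only {len(pool)} genes available"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=n, replace=False))


def kfold_split(
    labels: LabeledGeneSet, k: int = 10, seed: int = 0
) -> list[tuple[LabeledGeneSet, LabeledGeneSet]]:
    """Stratified k-fold partition of the labeled genes.

    Positives and negatives are each split into k near-equal chunks so every
    test fold contains both classes; train is the complement.  Deterministic
    under ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(labels.positives):
        raise ValueError(
            f"k={k} exceeds the {len(labels.positives)} available positives"
        )
    if not labels.negatives:
        raise ValueError("labels must include negatives before splitting")
    genes = sorted(labels.positives) + sorted(labels.negatives)
    y = np.array([1] * len(labels.positives) + [0] * len(labels.negatives))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(genes)), y):
        def _subset(idx):
            return LabeledGeneSet(
                positives={genes[i] for i in idx if y[i] == 1},
                negatives={genes[i] for i in idx if y[i] == 0},
                source=labels.source,
            )
        folds.append((_subset(train_idx), _subset(test_idx)))
    return folds


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int)


def compute_auc(scores, labels) -> float:
    """ROC AUC as the normalized Mann-Whitney statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # midranks
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def compute_aupr(scores, labels) -> float:
    """Average precision: mean precision at each positive's rank.

    Scores are sorted descending with ties broken against the positive class
    (negatives first within a tie group), so tied scores never flatter the
    ranking.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("at least one positive is required to compute AUPR")
    order = np.lexsort((labels, -scores))  # desc score, negatives before positives
    hits = labels[order]
    cum_pos = np.cumsum(hits)
    ranks = np.arange(1, labels.size + 1)
    precision_at_pos = cum_pos[hits == 1] / ranks[hits == 1]
    return float(precision_at_pos.mean())


def cross_validate(
    network: GeneNetwork,
    labels: LabeledGeneSet,
    estimator: GCNLMF | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of the full GCN + LogisticMF pipeline.

    Embeddings are computed once on the full network (the network carries no
    label information); per fold, test genes are masked out of training,
    their latent rows stay at the embedding initialization, and the fitted
    model scores them.
    """
    estimator = GCNLMF() if estimator is None else clone(estimator)
    encoder = estimator._make_encoder().fit(network)
    embeddings = encoder.embeddings_
    fold_auc, fold_aupr = [], []
    for train, test in kfold_split(labels, k=k, seed=seed):
        r, mask = labels_to_arrays(network.genes, train)
        mf: LogisticMF = estimator._make_mf().fit(embeddings, r, mask)
        test_genes = sorted(test.positives) + sorted(test.negatives)
        idx = [network.index_of(g) for g in test_genes]
        scores = mf.predict_proba(idx)
        y_true = np.array([1] * len(test.positives) + [0] * len(test.negatives))
        fold_auc.append(compute_auc(scores, y_true))
        fold_aupr.append(compute_aupr(scores, y_true))
    return CVResult(fold_auc=fold_auc, fold_aupr=fold_aupr, seed=seed)


def score_file_eval(score_csv, labels: LabeledGeneSet) -> tuple[float, float]:
    """AUC/AUPR for an external gene,score CSV (e.g. a baseline method).

    The file must cover every labeled gene; an optional ``gene,score``
    header row is tolerated.
    """
    scores_by_gene: dict[str, float] = {}
    with open(score_csv) as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            try:
                value = float(row[1])
            except ValueError:
                continue  # header row
            scores_by_gene[row[0].strip().upper()] = value
    genes = sorted(labels.positives) + sorted(labels.negatives)
    missing = [g for g in genes if g not in scores_by_gene]
    if missing:
        raise ValueError(f"labeled genes missing from score file: {missing}")
    scores = np.array([scores_by_gene[g] for g in genes])
    y_true = np.array([1] * len(labels.positives) + [0] * len(labels.negatives))
    return compute_auc(scores, y_true), compute_aupr(scores, y_true)
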