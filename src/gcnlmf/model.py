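"""The fused GCN + logistic matrix factorization estimator."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .gcn import GCNEncoder
from .logmf import LogisticMF, rank_genes
from .network import GeneNetwork, LabeledGeneSet

__all__ = ["GCNLMF", "labels_to_arrays"]


def labels_to_arrays(
    genes, labels: LabeledGeneSet
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a labeled gene set into (r, mask) vectors over ``genes``.

    Positives get r=1, negatives r=0; both are masked in.  Any labeled gene
    missing from ``genes`` raises, naming the gene.
    """
    index = {g.upper(): i for i, g in enumerate(genes)}
    r = np.zeros(len(index))
    mask = np.zeros(len(index), dtype=bool)
    for group, value in ((labels.positives, 1.0), (labels.negatives, 0.0)):
        for g in group:
            if g not in index:
                raise KeyError(f"labeled gene {g!r} not in network")
            r[index[g]] = value
            mask[index[g]] = True
    return r, mask


class GCNLMF(BaseEstimator):
    """Gene prioritization: GCN feature propagation + LogisticMF.

    The encoder propagates node features over the degree-normalized
    interaction network; the factorization initializes gene latent factors
    from those embeddings and fine-tunes the labeled rows by alternating
    gradient ascent.  ``predict_proba`` scores every network gene.

    Parameters mirror :class:`~gcnlmf.gcn.GCNEncoder` (``gcn_*``) and
    :class:`~gcnlmf.logmf.LogisticMF` (the rest).
    """

    def __init__(
        self,
        gcn_layer_dims=(64, 32),
        gcn_activation="relu",
        gcn_input_features="onehot",
        gcn_weight_seed=17,
        n_factors=32,
        a=2.0,
        epsilon=1.0,
        lam=0.5,
        weighting="linear",
        iterations=3000,
        learning_rate=0.05,
        y_init="gcn",
        adagrad_floor=1e-8,
        init_seed=0,
    ):
        self.gcn_layer_dims = gcn_layer_dims
        self.gcn_activation = gcn_activation
        self.gcn_input_features = gcn_input_features
        self.gcn_weight_seed = gcn_weight_seed
        self.n_factors = n_factors
        self.a = a
        self.epsilon = epsilon
        self.lam = lam
        self.weighting = weighting
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.y_init = y_init
        self.adagrad_floor = adagrad_floor
        self.init_seed = init_seed

    def _make_encoder(self) -> GCNEncoder:
        return GCNEncoder(
            layer_dims=self.gcn_layer_dims,
            activation=self.gcn_activation,
            input_features=self.gcn_input_features,
            weight_seed=self.gcn_weight_seed,
        )

    def _make_mf(self) -> LogisticMF:
        return LogisticMF(
            n_factors=self.n_factors,
            a=self.a,
            epsilon=self.epsilon,
            lam=self.lam,
            weighting=self.weighting,
            iterations=self.iterations,
            learning_rate=self.learning_rate,
            y_init=self.y_init,
            adagrad_floor=self.adagrad_floor,
            init_seed=self.init_seed,
        )

    def fit(self, network, y, mask=None):
        """Fit on a network and labels.

        Parameters
        ----------
        network : GeneNetwork or square adjacency ndarray
        y : LabeledGeneSet or array-like of shape (N,)
            Observed association values r; with a LabeledGeneSet the r/mask
            vectors are derived (positives 1, negatives 0, rest masked out).
        mask : boolean array-like, optional
            Only used with an array ``y``.
        """
        if isinstance(network, GeneNetwork):
            genes = list(network.genes)
        else:
            genes = [f"G{i}" for i in range(np.asarray(network).shape[0])]
        if isinstance(y, LabeledGeneSet):
            if not y.positives or not y.negatives:
                raise ValueError(
                    "both positive and negative sets must be non-empty for fitting"
                )
            r, mask = labels_to_arrays(genes, y)
        else:
            r = np.asarray(y, dtype=float)
        self.encoder_ = self._make_encoder().fit(network)
        self.mf_ = self._make_mf().fit(self.encoder_.embeddings_, r, mask)
        self.genes_ = genes
        return self

    def predict_proba(self, genes=None) -> np.ndarray:
        """Association probability for every gene (or a named/indexed subset)."""
        check_is_fitted(self, "mf_")
        if genes is None:
            return self.mf_.predict_proba()
        idx = [
            g if isinstance(g, (int, np.integer)) else self.genes_.index(g.upper())
            for g in genes
        ]
        return self.mf_.predict_proba(idx)

    def decision_function(self, genes=None) -> np.ndarray:
        check_is_fitted(self, "mf_")
        if genes is None:
            return self.mf_.decision_function()
        idx = [
            g if isinstance(g, (int, np.integer)) else self.genes_.index(g.upper())
            for g in genes
        ]
        return self.mf_.decision_function(idx)

    def rank_genes(self, exclude=()) -> list[tuple[str, float]]:
        """All genes minus ``exclude``, sorted by descending probability."""
        check_is_fitted(self, "mf_")
        return rank_genes(self.mf_, self.genes_, exclude)
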