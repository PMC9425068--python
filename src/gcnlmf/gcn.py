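"""Graph-convolutional feature propagation over a gene network.

Each gene receives a feature vector by repeatedly smoothing node features
over the degree-normalized, self-looped adjacency

    Ā = A + I,      Â = D^(-1/2) Ā D^(-1/2),      H' = σ(Â H W).

The layer weights W are not trained: there is no supervised objective at
this stage, so each W is a fixed, seeded orthonormal-column projection and
the encoder acts as deterministic neighborhood aggregation.  The resulting
embeddings feed the logistic matrix factorization, which initializes its
gene latent factors from them and fine-tunes the labeled rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .network import GeneNetwork

__all__ = [
    "GCNConfig",
    "GeneEmbeddings",
    "GCNEncoder",
    "add_self_loops",
    "normalize_adjacency",
    "gcn_layer",
    "extract_features",
]

_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "sigmoid": expit,
    "identity": lambda x: x,
}


def add_self_loops(A: np.ndarray) -> np.ndarray:
    """Return Ā = A + I so each node's own features survive aggregation."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    return A + np.eye(A.shape[0])


def normalize_adjacency(A_bar: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization Â = D^(-1/2) Ā D^(-1/2).

    D is the diagonal of (weighted) row sums of Ā.  After self-loops every
    degree is strictly positive; Â is symmetric with spectral radius ≤ 1.
    """
    A_bar = np.asarray(A_bar, dtype=float)
    if A_bar.ndim != 2 or A_bar.shape[0] != A_bar.shape[1]:
        raise ValueError(f"matrix must be square, got shape {A_bar.shape}")
    d = A_bar.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("zero row sum: normalize after adding self-loops")
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_bar * np.outer(d_inv_sqrt, d_inv_sqrt)


def gcn_layer(
    H: np.ndarray, A_hat: np.ndarray, W: np.ndarray, activation: str = "identity"
) -> np.ndarray:
    """One propagation step σ(Â · H · W)."""
    H, A_hat, W = (np.asarray(m, dtype=float) for m in (H, A_hat, W))
    if A_hat.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: Â {A_hat.shape}, H {H.shape}, W {W.shape}"
        )
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    return _ACTIVATIONS[activation](A_hat @ H @ W)


@dataclass
class GCNConfig:
    """Encoder configuration in full layer-dimension form.

    ``layer_dims`` lists (F^0, F^1, ..., F^k) including the input width; with
    one-hot inputs F^0 must equal the network size N.
    """

    layer_dims: list[int]
    activation: str = "relu"
    weight_seed: int = 17
    input_features: str = "onehot"

    def __post_init__(self) -> None:
        self.layer_dims = [int(d) for d in self.layer_dims]
        if len(self.layer_dims) < 1 or any(d < 1 for d in self.layer_dims):
            raise ValueError("layer_dims needs >= 1 entries, all >= 1")


@dataclass
class GeneEmbeddings:
    """Per-gene feature vectors, rows aligned with ``genes``."""

    genes: list[str]
    H: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape[0] != len(self.genes):
            raise ValueError("embedding rows must align with genes")
        if not np.all(np.isfinite(self.H)):
            raise ValueError("non-finite embedding entries")


def _orthonormal(rng: np.random.Generator, f_in: int, f_out: int) -> np.ndarray:
    """Seeded orthonormal projection (columns if f_in >= f_out, else rows)."""
    G = rng.standard_normal((f_in, f_out))
    if f_in >= f_out:
        Q, _ = np.linalg.qr(G)
        return Q
    Q, _ = np.linalg.qr(G.T)
    return Q.T


class GCNEncoder(TransformerMixin, BaseEstimator):
    """Deterministic graph-convolutional encoder (untrained, seeded weights).

    Parameters
    ----------
    layer_dims : tuple of int, default (64, 32)
        Output width of each propagation layer (the input width F^0 is set
        by ``input_features``: N for one-hot, 1 for degree).  An empty tuple
        returns the raw input features.
    activation : {"relu", "sigmoid", "identity"}, default "relu"
        Nonlinearity of all layers except the last.
    output_activation : {"relu", "sigmoid", "identity"}, default "identity"
        Nonlinearity of the final layer.
    input_features : {"onehot", "degree"}, default "onehot"
    weight_seed : int, default 17
        Seed of the orthonormal weight draw.
    weights : list of ndarray or None
        Explicit layer weights (test hook); bypasses the seeded draw.

    Attributes
    ----------
    A_hat_ : ndarray of shape (N, N)
        Normalized self-looped adjacency.
    weights_ : list of ndarray
        Layer weight matrices actually used.
    embeddings_ : ndarray of shape (N, F^k)
    genes_ : list of str or None
    """

    def __init__(
        self,
        layer_dims=(64, 32),
        activation="relu",
        output_activation="identity",
        input_features="onehot",
        weight_seed=17,
        weights=None,
    ):
        self.layer_dims = layer_dims
        self.activation = activation
        self.output_activation = output_activation
        self.input_features = input_features
        self.weight_seed = weight_seed
        self.weights = weights

    def _adjacency(self, X) -> tuple[np.ndarray, list[str] | None]:
        if isinstance(X, GeneNetwork):
            return X.adjacency, list(X.genes)
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("X must be a GeneNetwork or square adjacency matrix")
        return A, None

    def _input_matrix(self, A: np.ndarray) -> np.ndarray:
        if self.input_features == "onehot":
            return np.eye(A.shape[0])
        if self.input_features == "degree":
            return A.sum(axis=1, keepdims=True)
        raise ValueError(f"unknown input_features {self.input_features!r}")

    def fit(self, X, y=None):
        """Compute Â and propagate input features through the seeded layers."""
        A, genes = self._adjacency(X)
        for name in (self.activation, self.output_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")
        dims = [int(d) for d in self.layer_dims]
        if any(d < 1 for d in dims):
            raise ValueError("layer output widths must be >= 1")
        H = self._input_matrix(A)
        self.A_hat_ = normalize_adjacency(add_self_loops(A))
        if self.weights is not None:
            weights = [np.asarray(W, dtype=float) for W in self.weights]
            if [W.shape[1] for W in weights] != dims:
                raise ValueError("explicit weights do not match layer_dims")
        else:
            rng = np.random.default_rng(self.weight_seed)
            weights, f_in = [], H.shape[1]
            for f_out in dims:
                weights.append(_orthonormal(rng, f_in, f_out))
                f_in = f_out
        for i, W in enumerate(weights):
            act = self.output_activation if i == len(weights) - 1 else self.activation
            H = gcn_layer(H, self.A_hat_, W, act)
        self.weights_ = weights
        self.embeddings_ = H
        self.genes_ = genes
        self.n_features_in_ = A.shape[0]
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return embeddings; with X given, re-propagate X under fitted weights."""
        check_is_fitted(self, "embeddings_")
        if X is None:
            return self.embeddings_
        A, _ = self._adjacency(X)
        H = self._input_matrix(A)
        A_hat = normalize_adjacency(add_self_loops(A))
        for i, W in enumerate(self.weights_):
            act = (
                self.output_activation
                if i == len(self.weights_) - 1
                else self.activation
            )
            H = gcn_layer(H, A_hat, W, act)
        return H


def extract_features(network: GeneNetwork, config: GCNConfig) -> GeneEmbeddings:
    """Run the encoder under a full-layer-dimension config.

    With one-hot inputs ``config.layer_dims[0]`` must equal the network size.
    """
    expected_f0 = network.n_genes if config.input_features == "onehot" else 1
    if config.layer_dims[0] != expected_f0:
        raise ValueError(
            f"layer_dims[0]={config.layer_dims[0]} does not match input "
            f"feature width {expected_f0} for {config.input_features!r} inputs"
        )
    enc = GCNEncoder(
        layer_dims=tuple(config.layer_dims[1:]),
        activation=config.activation,
        input_features=config.input_features,
        weight_seed=config.weight_seed,
    ).fit(network)
    return GeneEmbeddings(list(network.genes), enc.embeddings_)
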