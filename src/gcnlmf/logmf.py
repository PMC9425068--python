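"""Logistic matrix factorization with confidence-weighted binary labels.

A single disease u and N genes.  The probability that gene i is associated
with the disease is

    p_i = sigma(z_i),    z_i = x_u . y_i + beta_u + beta_i,

with disease factors x_u, gene factors y_i (rows of Y), and biases.  The
observed association vector r (1 for known disease genes, 0 for sampled
negatives) enters a weighted Bernoulli log-likelihood in which positives are
up-weighted by w_i = a * r_i (or, optionally, the logarithmic confidence
mapping a * log(1 + r_i / epsilon)):

    log L = sum_i  w_i * z_i - (1 + w_i) * log(1 + exp(z_i))

Gaussian priors on the latent factors contribute an L2 penalty
-(lam/2)(|x_u|^2 + sum_i |y_i|^2); biases are unregularized.  The posterior
is maximized by alternating gradient ascent with AdaGrad per-coordinate
steps: the disease side (x_u, beta_u) is updated with the gene side fixed,
then the gene side (Y, beta) with the disease side fixed.

Genes outside the labeled training set are masked: they contribute nothing
to the posterior or its gradients, so their latent rows stay frozen at
initialization.  Under GCN initialization this is the fusion mechanism —
an unlabeled gene is scored by the trained x_u against its propagated
network embedding.
"""

from __future__ import annotations

import json

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AssociationData",
    "LogisticMF",
    "association_probability",
    "confidence",
    "log_posterior",
    "grad_x_u",
    "grad_y_i",
    "grad_beta_u",
    "grad_beta_i",
    "rank_genes",
    "save_model",
    "load_model",
]

# Largest double below 1; probabilities are clipped into the open interval.
_ONE_MINUS = np.nextafter(1.0, 0.0)
_TINY = np.finfo(float).tiny


def _sigmoid_open(z):
    """sigma(z) clipped into (0, 1) so saturated scores stay proper probabilities."""
    return np.clip(expit(z), _TINY, _ONE_MINUS)


def association_probability(x_u, y_i, beta_u=0.0, beta_i=0.0) -> float:
    """sigma(x_u . y_i + beta_u + beta_i), strictly inside (0, 1)."""
    z = float(np.dot(np.ravel(x_u), np.ravel(y_i)) + beta_u + beta_i)
    return float(_sigmoid_open(z))


def confidence(r_ui, a, epsilon):
    """Confidence mapping c = 1 + a * log(1 + r_ui / epsilon) (natural log)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    r = np.asarray(r_ui, dtype=float)
    if np.any(r < 0):
        raise ValueError("r_ui must be non-negative")
    out = 1.0 + a * np.log1p(r / epsilon)
    return float(out) if np.isscalar(r_ui) else out


class AssociationData:
    """Observed association vector r with a training mask.

    ``r`` holds r_ui >= 0 per gene (binary here); ``mask`` marks the genes
    that participate in fitting.  Masked-out genes contribute nothing to the
    posterior or gradients.
    """

    def __init__(self, r, mask=None):
        self.r = np.asarray(r, dtype=float)
        if self.r.ndim != 1:
            raise ValueError("r must be a 1-D vector")
        if np.any(self.r < 0):
            raise ValueError("r entries must be non-negative")
        if mask is None:
            mask = np.ones(self.r.shape[0], dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != self.r.shape:
            raise ValueError("mask must match r in length")

    def __len__(self) -> int:
        return self.r.shape[0]


def _weights(r: np.ndarray, a: float, epsilon: float, weighting: str) -> np.ndarray:
    if weighting == "linear":
        return a * r
    if weighting == "log":
        return a * np.log1p(r / epsilon)
    raise ValueError(f"unknown weighting {weighting!r}")


def _check_shapes(data: AssociationData, Y: np.ndarray, beta: np.ndarray) -> None:
    n = len(data)
    if Y.shape[0] != n or beta.shape[0] != n:
        raise ValueError(
            f"shape mismatch: {n} genes in data, Y has {Y.shape[0]} rows, "
            f"beta has {beta.shape[0]} entries"
        )


def log_posterior(
    data: AssociationData,
    x_u,
    Y,
    beta_u,
    beta,
    a=2.0,
    lam=0.5,
    epsilon=1.0,
    weighting="linear",
) -> float:
    """Penalized log-posterior of the weighted Bernoulli model.

    Masked-out genes are excluded from both the data term and the
    sum-of-squares penalty on Y rows.
    """
    x_u = np.asarray(x_u, dtype=float)
    Y = np.asarray(Y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    _check_shapes(data, Y, beta)
    m = data.mask
    z = Y[m] @ x_u + beta_u + beta[m]
    w = _weights(data.r[m], a, epsilon, weighting)
    ll = w * z - (1.0 + w) * np.logaddexp(0.0, z)
    penalty = 0.5 * lam * (x_u @ x_u) + 0.5 * lam * float((Y[m] ** 2).sum())
    return float(ll.sum() - penalty)


def _coef(data, x_u, Y, beta_u, beta, a, epsilon, weighting) -> np.ndarray:
    """Per-gene data-term factor w_i - (1 + w_i) sigma(z_i), zero where masked."""
    z = Y @ x_u + beta_u + beta
    w = _weights(data.r, a, epsilon, weighting)
    c = w - (1.0 + w) * expit(z)
    c[~data.mask] = 0.0
    return c


def grad_x_u(data, x_u, Y, beta_u, beta, a=2.0, lam=0.5, epsilon=1.0, weighting="linear"):
    """d log-posterior / d x_u (gene side fixed)."""
    x_u, Y, beta = (np.asarray(v, dtype=float) for v in (x_u, Y, beta))
    _check_shapes(data, Y, beta)
    c = _coef(data, x_u, Y, beta_u, beta, a, epsilon, weighting)
    return c @ Y - lam * x_u


def grad_beta_u(data, x_u, Y, beta_u, beta, a=2.0, lam=0.5, epsilon=1.0, weighting="linear"):
    """d log-posterior / d beta_u; the bias carries no penalty term."""
    x_u, Y, beta = (np.asarray(v, dtype=float) for v in (x_u, Y, beta))
    _check_shapes(data, Y, beta)
    return float(_coef(data, x_u, Y, beta_u, beta, a, epsilon, weighting).sum())


def _grad_Y(data, x_u, Y, beta_u, beta, a, lam, epsilon, weighting):
    c = _coef(data, x_u, Y, beta_u, beta, a, epsilon, weighting)
    g = np.outer(c, x_u)
    g[data.mask] -= lam * Y[data.mask]
    return g


def grad_y_i(data, x_u, Y, beta_u, beta, i, a=2.0, lam=0.5, epsilon=1.0, weighting="linear"):
    """d log-posterior / d y_i (zero for masked-out genes)."""
    x_u, Y, beta = (np.asarray(v, dtype=float) for v in (x_u, Y, beta))
    _check_shapes(data, Y, beta)
    return _grad_Y(data, x_u, Y, beta_u, beta, a, lam, epsilon, weighting)[i]


def grad_beta_i(data, x_u, Y, beta_u, beta, i, a=2.0, lam=0.5, epsilon=1.0, weighting="linear"):
    """d log-posterior / d beta_i (zero for masked-out genes)."""
    x_u, Y, beta = (np.asarray(v, dtype=float) for v in (x_u, Y, beta))
    _check_shapes(data, Y, beta)
    return float(_coef(data, x_u, Y, beta_u, beta, a, epsilon, weighting)[i])


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


class LogisticMF(BaseEstimator):
    """Single-disease logistic matrix factorization estimator.

    Parameters
    ----------
    n_factors : int, default 32
        Latent dimension f.
    a : float, default 2.0
        Positive-example confidence weight.
    epsilon : float, default 1.0
        Confidence scale; only consulted under ``weighting="log"``.
    lam : float, default 0.5
        L2 penalty on x_u and the trained rows of Y (biases are free).
    weighting : {"linear", "log"}, default "linear"
        Positive weight w_i = a*r_i or a*log1p(r_i/epsilon).
    iterations : int, default 3000
        Full alternating passes; the default is sized so the posterior
        trace has flattened on problems of a few hundred genes.
    learning_rate : float, default 0.05
        AdaGrad base step.
    y_init : {"gcn", "random"}, default "gcn"
        Initialize Y from the (column-standardized) first f embedding
        columns, or from seeded Gaussian noise (plain LMF ablation).
    adagrad_floor : float, default 1e-8
        Additive floor inside the AdaGrad denominator.
    init_seed : int, default 0

    Attributes
    ----------
    x_u_ : ndarray of shape (f,)
    Y_ : ndarray of shape (N, f)
    beta_u_ : float
    beta_ : ndarray of shape (N,)
    posterior_trace_ : ndarray of shape (iterations + 1,)
        Log-posterior at initialization and after every alternating pass.
    """

    def __init__(
        self,
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

    def _validate(self):
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.a < 0 or self.lam < 0:
            raise ValueError("a and lam must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.y_init not in ("gcn", "random"):
            raise ValueError(f"unknown y_init {self.y_init!r}")

    def fit(self, X, y, mask=None):
        """Fit by alternating AdaGrad ascent on the penalized posterior.

        Parameters
        ----------
        X : ndarray of shape (N, d) or None
            Gene embeddings; required when ``y_init="gcn"`` (d >= n_factors).
        y : array-like of shape (N,)
            Observed association values r (binary 0/1 here).
        mask : boolean array-like of shape (N,), optional
            Genes participating in training; defaults to all.
        """
        self._validate()
        data = y if isinstance(y, AssociationData) else AssociationData(y, mask)
        n = len(data)
        f = int(self.n_factors)
        rng = np.random.default_rng(self.init_seed)
        if self.y_init == "gcn":
            if X is None:
                raise ValueError('y_init="gcn" requires embeddings X')
            X = np.asarray(X, dtype=float)
            if X.shape[0] != n:
                raise ValueError("embedding rows must match number of genes")
            if X.shape[1] < f:
                raise ValueError(
                    f"embeddings provide {X.shape[1]} columns < n_factors={f}"
                )
            Y = _standardize_columns(X[:, :f]).copy()
        else:
            Y = 0.1 * rng.standard_normal((n, f))
        x_u = 1e-3 * rng.standard_normal(f)
        beta_u = 0.0
        beta = np.zeros(n)

        hyper = dict(
            a=self.a, lam=self.lam, epsilon=self.epsilon, weighting=self.weighting
        )
        lr, floor = self.learning_rate, self.adagrad_floor
        G_x = np.zeros(f)
        G_bu = 0.0
        G_Y = np.zeros((n, f))
        G_b = np.zeros(n)
        trace = [log_posterior(data, x_u, Y, beta_u, beta, **hyper)]
        for it in range(1, int(self.iterations) + 1):
            # disease side, gene side fixed
            gx = grad_x_u(data, x_u, Y, beta_u, beta, **hyper)
            gbu = grad_beta_u(data, x_u, Y, beta_u, beta, **hyper)
            G_x += gx**2
            x_u = x_u + lr * gx / (np.sqrt(G_x) + floor)
            G_bu += gbu**2
            beta_u = beta_u + lr * gbu / (np.sqrt(G_bu) + floor)
            # gene side, disease side fixed
            gY = _grad_Y(data, x_u, Y, beta_u, beta, **hyper)
            gb = _coef(data, x_u, Y, beta_u, beta, self.a, self.epsilon, self.weighting)
            G_Y += gY**2
            Y = Y + lr * gY / (np.sqrt(G_Y) + floor)
            G_b += gb**2
            beta = beta + lr * gb / (np.sqrt(G_b) + floor)
            lp = log_posterior(data, x_u, Y, beta_u, beta, **hyper)
            if not np.isfinite(lp):
                raise RuntimeError(f"non-finite posterior at iteration {it}")
            trace.append(lp)

        self.x_u_ = x_u
        self.Y_ = Y
        self.beta_u_ = float(beta_u)
        self.beta_ = beta
        self.posterior_trace_ = np.asarray(trace)
        self.n_genes_ = n
        self.n_iter_ = int(self.iterations)
        return self

    def decision_function(self, indices=None) -> np.ndarray:
        """Linear scores z_i = x_u . y_i + beta_u + beta_i."""
        check_is_fitted(self, "x_u_")
        z = self.Y_ @ self.x_u_ + self.beta_u_ + self.beta_
        if indices is None:
            return z
        return z[np.asarray(indices, dtype=int)]

    def predict_proba(self, indices=None) -> np.ndarray:
        """Per-gene association probabilities, strictly inside (0, 1)."""
        return _sigmoid_open(self.decision_function(indices))


def rank_genes(model: LogisticMF, genes, exclude=()) -> list[tuple[str, float]]:
    """All genes minus ``exclude``, sorted by descending probability.

    Ties are broken by lexicographic gene symbol so rankings are stable.
    """
    check_is_fitted(model, "x_u_")
    genes = list(genes)
    if len(genes) != model.n_genes_:
        raise ValueError("gene list does not match fitted model size")
    excluded = {g.upper() for g in exclude}
    probs = model.predict_proba()
    pairs = [
        (g, float(p)) for g, p in zip(genes, probs) if g.upper() not in excluded
    ]
    pairs.sort(key=lambda gp: (-gp[1], gp[0]))
    return pairs


def save_model(path, genes, model: LogisticMF) -> None:
    """Serialize a fitted model (plus its gene order) to JSON.

    Floats are written with shortest-round-trip repr, so a reload is exact.
    """
    check_is_fitted(model, "x_u_")
    payload = {
        "genes": list(genes),
        "x_u": model.x_u_.tolist(),
        "Y": model.Y_.tolist(),
        "beta_u": model.beta_u_,
        "beta": model.beta_.tolist(),
        "posterior_trace": model.posterior_trace_.tolist(),
        "params": model.get_params(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> tuple[list[str], LogisticMF]:
    """Inverse of :func:`save_model`; returns (genes, fitted model)."""
    with open(path) as fh:
        payload = json.load(fh)
    model = LogisticMF(**payload["params"])
    model.x_u_ = np.asarray(payload["x_u"], dtype=float)
    model.Y_ = np.asarray(payload["Y"], dtype=float)
    model.beta_u_ = float(payload["beta_u"])
    model.beta_ = np.asarray(payload["beta"], dtype=float)
    model.posterior_trace_ = np.asarray(payload["posterior_trace"], dtype=float)
    model.n_genes_ = model.Y_.shape[0]
    model.n_iter_ = int(model.posterior_trace_.shape[0] - 1)
    return payload["genes"], model
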