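"""Gene interaction networks and labeled gene sets.

The network is held as a dense symmetric weighted adjacency matrix over an
ordered list of gene symbols.  Gene identity is the upper-cased symbol
string; no identifier mapping is performed.  Edge lists follow the common
tab-separated convention ``gene_a<TAB>gene_b[<TAB>weight]``; STRING-style
combined scores (0-1000) are supported through the ``string1000`` dialect,
which rescales weights into [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneNetwork",
    "LabeledGeneSet",
    "load_edge_list",
    "load_gene_list",
    "align_labels",
    "write_edge_list",
]


@dataclass
class GeneNetwork:
    """A symmetric, non-negatively weighted gene-gene interaction network.

    Parameters
    ----------
    genes : list of str
        Ordered, unique (upper-cased) gene symbols; row/column order of
        ``adjacency``.
    adjacency : ndarray of shape (N, N)
        Symmetric non-negative weights with a zero diagonal.  Self-loops are
        never stored here; the encoder adds them explicitly.
    """

    genes: list[str]
    adjacency: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if len(self.genes) < 1:
            raise ValueError("network must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in network")
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if A.shape[0] != len(self.genes):
            raise ValueError(
                f"adjacency size {A.shape[0]} != number of genes {len(self.genes)}"
            )
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be exactly symmetric")
        if np.any(A < 0):
            raise ValueError("adjacency entries must be non-negative")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero (no stored self-loops)")
        self.adjacency = A
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def edge_count(self) -> int:
        """Number of strictly positive entries above the diagonal."""
        return int(np.count_nonzero(np.triu(self.adjacency, k=1) > 0))

    def index_of(self, gene: str) -> int:
        return self._index[gene.upper()]

    def degrees(self) -> np.ndarray:
        """Weighted degree (row sum) of each gene."""
        return self.adjacency.sum(axis=1)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._index


@dataclass
class LabeledGeneSet:
    """Disjoint positive / negative gene symbol sets with provenance."""

    positives: set[str]
    negatives: set[str] = field(default_factory=set)
    source: str = ""

    def __post_init__(self) -> None:
        self.positives = {g.upper() for g in self.positives}
        self.negatives = {g.upper() for g in self.negatives}
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(
                f"genes labeled both positive and negative: {sorted(overlap)}"
            )

    @property
    def labeled(self) -> set[str]:
        return self.positives | self.negatives


def load_edge_list(path, score_dialect: str = "raw") -> GeneNetwork:
    """Read a whitespace/tab-separated edge list into a :class:`GeneNetwork`.

    Lines have at least two columns ``gene_a gene_b [weight]``; the weight
    defaults to 1.0.  Under the ``string1000`` dialect weights are divided by
    1000 so that STRING combined scores land in [0, 1].  Duplicate edges keep
    the maximum weight; self-edges are dropped with a warning.
    """
    if score_dialect not in ("raw", "string1000"):
        raise ValueError(f"unknown score_dialect {score_dialect!r}")
    genes: list[str] = []
    seen: dict[str, int] = {}
    edges: dict[tuple[int, int], float] = {}

    def _gene_id(symbol: str) -> int:
        if symbol not in seen:
            seen[symbol] = len(genes)
            genes.append(symbol)
        return seen[symbol]

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"line {lineno}: expected at least 2 columns")
            a, b = cols[0].upper(), cols[1].upper()
            if len(cols) >= 3:
                try:
                    w = float(cols[2])
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: non-numeric weight {cols[2]!r}"
                    ) from None
            else:
                w = 1.0
            if w < 0:
                raise ValueError(f"line {lineno}: negative weight {w}")
            if score_dialect == "string1000":
                w = w / 1000.0
            if a == b:
                warnings.warn(
                    f"line {lineno}: self-edge on {a} dropped", stacklevel=2
                )
                continue
            i, j = _gene_id(a), _gene_id(b)
            key = (min(i, j), max(i, j))
            edges[key] = max(w, edges.get(key, 0.0))
    if not edges:
        raise ValueError("no edges")
    n = len(genes)
    A = np.zeros((n, n))
    for (i, j), w in edges.items():
        A[i, j] = A[j, i] = w
    return GeneNetwork(genes, A)


def write_edge_list(network: GeneNetwork, path) -> None:
    """Write the network back to edge-list form (round-trips exactly)."""
    A = network.adjacency
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(np.triu(A, k=1))):
            fh.write(f"{network.genes[i]}\t{network.genes[j]}\t{float(A[i, j])!r}\n")


def load_gene_list(path) -> set[str]:
    """Read a plain-text gene list (one symbol per line, ``#`` comments)."""
    symbols: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            symbols.add(line.upper())
    if not symbols:
        raise ValueError("no genes in list")
    return symbols


def align_labels(
    network: GeneNetwork,
    labels: LabeledGeneSet,
    policy: str = "add_isolated",
) -> tuple[GeneNetwork, LabeledGeneSet]:
    """Reconcile labeled genes with the network's gene universe.

    Under ``add_isolated`` (the default), labeled genes absent from the
    network are appended as degree-0 nodes — they still receive a self-loop
    during encoding, so they are scorable, just uninformed by topology.
    Under ``error`` any absent labeled gene aborts, naming the gene.
    """
    if policy not in ("error", "add_isolated"):
        raise ValueError(f"unknown policy {policy!r}")
    missing = sorted(g for g in labels.labeled if g not in network)
    if not missing:
        return network, labels
    if policy == "error":
        raise ValueError(f"labeled genes absent from network: {missing}")
    warnings.warn(
        f"adding {len(missing)} labeled gene(s) absent from the network as "
        f"isolated nodes: {missing}",
        stacklevel=2,
    )
    n_old = network.n_genes
    n_new = n_old + len(missing)
    A = np.zeros((n_new, n_new))
    A[:n_old, :n_old] = network.adjacency
    return GeneNetwork(network.genes + missing, A), labels
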