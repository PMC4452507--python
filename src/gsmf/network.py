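"""Gene interaction network: shortest-path closeness kernel and spectral embedding.

The genomic side information enters the model through a single dense object,
the gene relation matrix ``C``: for genes *i*, *j* at shortest-path (hop)
distance ``d_ij`` in the interaction network,

    c_ij = a' * exp(-b' * d_ij)

with ``c_ij = 0`` for unreachable pairs (the limit as the distance grows).
``C`` is then factored through its top-``k`` eigenpairs, ``C ~ P P^T`` with
``P = Gamma Lambda^{1/2}``, and the rows of ``P`` are the gene feature
vectors. Distances are always measured in the *full* network; ``C`` is
restricted to the genes of interest (those touched by drug-gene or
disease-gene interactions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

#: Kernel defaults: scale a' and decay b' of the closeness kernel.
DEFAULT_A_PRIME = 10.0
DEFAULT_B_PRIME = 0.25


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected, unweighted gene interaction network.

    Thin wrapper around :class:`networkx.Graph` with opaque string gene IDs.
    Self-loops are dropped at construction (a gene is at distance 0 from
    itself regardless).
    """

    graph: nx.Graph = field(repr=False)

    @classmethod
    def from_edges(cls, edges) -> "GeneNetwork":
        g = nx.Graph()
        n_loops = 0
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
        if n_loops:
            logger.debug("dropped %d self-loop edge(s)", n_loops)
        return cls(graph=g)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def n_genes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.graph


@dataclass(frozen=True)
class GeneRelationMatrix:
    """Symmetric closeness matrix ``C`` over an ordered list of genes."""

    gene_ids: list[str]
    C: np.ndarray = field(repr=False)
    a_prime: float = DEFAULT_A_PRIME
    b_prime: float = DEFAULT_B_PRIME

    def __post_init__(self):
        if self.C.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("relation matrix shape does not match gene list")


@dataclass(frozen=True)
class FeatureSpace:
    """Rank-k embedding: row ``i`` of ``X`` is the feature vector of entity ``i``.

    ``eigenvalues`` (descending, all positive) are carried only by gene
    spaces produced by :func:`eigendecompose`; aggregated drug/disease
    spaces have ``eigenvalues=None``. Rows of ``X`` may be NaN for entities
    whose vector is not yet defined (no interacting genes); see
    :func:`gsmf.features.init_missing`.
    """

    ids: list[str]
    X: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("feature matrix shape does not match entity list")

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def row(self, entity_id: str) -> np.ndarray:
        return self.X[self.ids.index(entity_id)]


def shortest_path_distances(network: GeneNetwork, subset) -> np.ndarray:
    """All-pairs hop distances between ``subset`` genes through the full network.

    Returns a dense ``len(subset) x len(subset)`` float matrix; unreachable
    pairs are ``inf``. Intermediate nodes on shortest paths are not
    restricted to the subset.
    """
    subset = list(subset)
    for gene in subset:
        if gene not in network:
            raise KeyError(f"gene {gene!r} is not a node of the network")
    order = list(network.graph.nodes)
    pos = {g: i for i, g in enumerate(order)}
    idx = np.array([pos[g] for g in subset], dtype=np.intp)
    adj = nx.to_scipy_sparse_array(network.graph, nodelist=order, format="csr")
    # unweighted dijkstra == breadth-first search on the hop metric
    d_full = dijkstra(adj, unweighted=True, directed=False, indices=idx)
    return d_full[:, idx]


def gene_closeness(
    distances: np.ndarray,
    a_prime: float = DEFAULT_A_PRIME,
    b_prime: float = DEFAULT_B_PRIME,
    gene_ids=None,
) -> GeneRelationMatrix:
    """Apply the exponential kernel ``c = a' exp(-b' d)`` to a distance matrix.

    Infinite distances (unreachable pairs) map to closeness 0.
    """
    if a_prime <= 0 or b_prime <= 0:
        raise ValueError(
            f"kernel parameters must be positive (a'={a_prime}, b'={b_prime})"
        )
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.array_equal(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diagonal(distances) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    C = np.where(np.isinf(distances), 0.0, a_prime * np.exp(-b_prime * distances))
    if gene_ids is None:
        gene_ids = [str(i) for i in range(distances.shape[0])]
    return GeneRelationMatrix(gene_ids=list(gene_ids), C=C, a_prime=a_prime, b_prime=b_prime)


def eigendecompose(relation: GeneRelationMatrix, k: int) -> FeatureSpace:
    """Top-``k`` spectral embedding ``P = Gamma Lambda^{1/2}`` of the relation matrix.

    Eigenvalues are sorted descending and the top ``k`` must be strictly
    positive (the closeness kernel is not guaranteed PSD; square roots of
    negative eigenvalues are undefined, so the failure is made explicit).
    Eigenvector signs are fixed so each column's largest-magnitude entry is
    positive; downstream predictions are invariant to this choice.
    """
    C = relation.C
    n = C.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    w, v = np.linalg.eigh(C)
    w, v = w[::-1], v[:, ::-1]  # descending
    tol = n * np.finfo(float).eps * max(1.0, float(np.abs(w).max(initial=0.0)))
    n_pos = int(np.sum(w > tol))
    if n_pos < k:
        raise ValueError(
            f"relation matrix has only {n_pos} strictly positive eigenvalue(s); "
            f"cannot extract k={k} feature dimensions"
        )
    w_k, v_k = w[:k].copy(), v[:, :k].copy()
    for c in range(k):
        if v_k[np.argmax(np.abs(v_k[:, c])), c] < 0:
            v_k[:, c] = -v_k[:, c]
    P = v_k * np.sqrt(w_k)
    return FeatureSpace(ids=list(relation.gene_ids), X=P, eigenvalues=w_k)


def gene_feature_space(
    network: GeneNetwork,
    genes_of_interest,
    k: int,
    a_prime: float = DEFAULT_A_PRIME,
    b_prime: float = DEFAULT_B_PRIME,
) -> FeatureSpace:
    """Distances -> closeness -> eigendecomposition, in one call."""
    genes = list(genes_of_interest)
    d = shortest_path_distances(network, genes)
    rel = gene_closeness(d, a_prime=a_prime, b_prime=b_prime, gene_ids=genes)
    return eigendecompose(rel, k)
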