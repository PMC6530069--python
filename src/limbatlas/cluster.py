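"""PCA with Marchenko-Pastur component selection, shared-nearest-neighbor
graphs with Jaccard weights, Louvain community detection, and 2-D embedding.

Under the null of i.i.d. unit-variance entries, sample-covariance
eigenvalues of an n x p matrix concentrate inside the Marchenko-Pastur bulk
[(1 - sqrt(gamma))^2, (1 + sqrt(gamma))^2] with gamma = p/n; components
whose eigenvalue exceeds the upper edge carry signal and are retained.
Cells are then connected in an SNN graph: each cell's k-nearest-neighbor
set (Euclidean, including the cell itself) is compared with every other's
by Jaccard overlap, and edges below a prune threshold are dropped. Louvain
greedy modularity optimization (with Reichardt-Bornholdt resolution
scaling of the configuration-model null term) yields the communities; a
broad and a fine resolution are run on the same graph.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph
import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "MPBound",
    "SNNGraph",
    "ClusterLabels",
    "run_pca",
    "mp_significant",
    "build_snn_graph",
    "louvain",
    "cluster_two_tier",
    "embed_2d",
    "MarchenkoPasturPCA",
    "SNNLouvain",
]

DEFAULT_SNN_PRUNE = 1.0 / 15.0


@dataclass
class PCAResult:
    loadings: np.ndarray  # genes x components
    scores: np.ndarray  # cells x components
    eigenvalues: np.ndarray  # sample-covariance eigenvalues, non-increasing
    n_cells: int
    n_genes: int


@dataclass
class MPBound:
    gamma: float
    lambda_plus: float
    lambda_minus: float
    n_significant: int


@dataclass
class SNNGraph:
    nodes: list
    edges: np.ndarray  # rows (i, j, jaccard_weight), i < j
    k: int

    def to_igraph(self) -> igraph.Graph:
        g = igraph.Graph(n=len(self.nodes))
        if len(self.edges):
            g.add_edges([(int(i), int(j)) for i, j, _ in self.edges])
            g.es["weight"] = [float(w) for _, _, w in self.edges]
        return g


@dataclass
class ClusterLabels:
    labels_broad: np.ndarray
    labels_fine: np.ndarray
    resolution_broad: float
    resolution_fine: float
    seed: int
    n_significant: int = 0
    barcodes: list = field(default_factory=list)


def run_pca(sm, max_components: int = 50) -> PCAResult:
    """Exact PCA of a per-gene z-scored matrix.

    ``sm`` is a ScaledMatrix (genes x cells) or a bare genes x cells array.
    Cells are the observations; eigenvalues are scaled as sample-covariance
    eigenvalues (divisor n_cells - 1).
    """
    Z = sm.values if hasattr(sm, "values") else np.asarray(sm, dtype=float)
    Z = Z.toarray() if sp.issparse(Z) else np.asarray(Z, dtype=float)
    n_genes, n_cells = Z.shape
    rank = min(n_cells, n_genes)
    if max_components > rank:
        logger.warning("max_components %d clipped to %d", max_components, rank)
        max_components = rank
    X = Z.T  # cells x genes
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eig = S**2 / max(n_cells - 1, 1)
    k = max_components
    return PCAResult(
        loadings=Vt[:k].T,
        scores=U[:, :k] * S[:k],
        eigenvalues=eig[:k],
        n_cells=n_cells,
        n_genes=n_genes,
    )


def mp_significant(eigenvalues, n_cells: int, n_genes: int) -> MPBound:
    """Count eigenvalues above the Marchenko-Pastur upper edge.

    Assumes the eigenvalues come from per-feature standardized data, so the
    null noise variance is 1.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    gamma = n_genes / n_cells
    lam_plus = (1 + np.sqrt(gamma)) ** 2
    lam_minus = (1 - np.sqrt(gamma)) ** 2
    n_sig = int(np.sum(np.asarray(eigenvalues) > lam_plus))
    return MPBound(gamma, lam_plus, lam_minus, n_sig)


def _knn_sets(scores: np.ndarray, k: int) -> np.ndarray:
    """k-nearest-neighbor index sets (self included), stable tie-breaks."""
    d = cdist(scores, scores)
    # stable argsort: among tied distances the lower cell index wins,
    # making the graph reproducible on duplicated coordinates
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def build_snn_graph(scores: np.ndarray, k: int = 20,
                    prune: float = DEFAULT_SNN_PRUNE, nodes=None) -> SNNGraph:
    """Jaccard-weighted shared-nearest-neighbor graph.

    Edges with weight <= ``prune`` are dropped; weights lie in (0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    nn = _knn_sets(scores, k)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (np.ones(n * k), (rows, nn.ravel())), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()
    mask = inter.row < inter.col
    i, j, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jac = shared / (2 * k - shared)
    keep = jac > prune
    edges = np.column_stack([i[keep], j[keep], jac[keep]])
    if nodes is None:
        nodes = list(range(n))
    return SNNGraph(nodes=list(nodes), edges=edges, k=k)


def louvain(graph: SNNGraph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Louvain communities on an SNN graph, size-ranked labels from 0.

    Deterministic given ``seed``; disconnected components are handled
    independently by the algorithm.
    """
    n = len(graph.nodes)
    if n == 0:
        raise ValueError("empty graph")
    g = graph.to_igraph()
    igraph.set_random_number_generator(random.Random(seed))
    weights = g.es["weight"] if g.ecount() else None
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return _relabel_by_size(np.array(part.membership))


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel community ids by decreasing size (ties: lowest member index)."""
    ids, counts = np.unique(labels, return_counts=True)
    first = {c: int(np.argmax(labels == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def cluster_two_tier(
    sm,
    resolution_broad: float = 0.4,
    resolution_fine: float = 1.4,
    k: int = 20,
    seed: int = 0,
    snn_prune: float = DEFAULT_SNN_PRUNE,
    max_components: int = 50,
) -> ClusterLabels:
    """PCA -> MP selection -> SNN graph -> Louvain at two resolutions.

    Both tiers run on the same graph built from the MP-significant
    principal-component scores. Defaults mirror broad resolution 0.4-0.5
    and fine 1.1-1.4 with k = 20.
    """
    pca = run_pca(sm, max_components=max_components)
    mp = mp_significant(pca.eigenvalues, pca.n_cells, pca.n_genes)
    n_sig = mp.n_significant
    if n_sig == 0:
        logger.warning("no MP-significant components; falling back to top 2")
        n_sig = min(2, pca.scores.shape[1])
    scores = pca.scores[:, :n_sig]
    graph = build_snn_graph(scores, k=k, prune=snn_prune)
    lb = louvain(graph, resolution=resolution_broad, seed=seed)
    lf = louvain(graph, resolution=resolution_fine, seed=seed)
    barcodes = list(getattr(sm, "barcodes", range(scores.shape[0])))
    return ClusterLabels(
        labels_broad=lb,
        labels_fine=lf,
        resolution_broad=resolution_broad,
        resolution_fine=resolution_fine,
        seed=seed,
        n_significant=n_sig,
        barcodes=barcodes,
    )


def embed_2d(scores: np.ndarray, seed: int = 0) -> np.ndarray:
    """Neighborhood-preserving 2-D embedding (t-SNE) for visualization only.

    Deterministic given ``seed``. Downstream computation must never read
    these coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 4:
        out = np.zeros((n, 2))
        out[:, : min(2, scores.shape[1])] = scores[:, :2]
        return out
    from sklearn.manifold import TSNE

    perplexity = min(30.0, (n - 1) / 3.0)
    return TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(scores)


class MarchenkoPasturPCA(BaseEstimator, TransformerMixin):
    """PCA keeping only components above the Marchenko-Pastur edge.

    Expects X (cells x genes) standardized per gene. Fitted attributes:
    ``eigenvalues_``, ``lambda_plus_``, ``n_components_``, ``components_``.
    """

    def __init__(self, max_components: int = 50, min_components: int = 2):
        self.max_components = max_components
        self.min_components = min_components

    def fit(self, X, y=None):
        X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        pca = run_pca(X.T, max_components=self.max_components)
        mp = mp_significant(pca.eigenvalues, pca.n_cells, pca.n_genes)
        self.eigenvalues_ = pca.eigenvalues
        self.lambda_plus_ = mp.lambda_plus
        self.gamma_ = mp.gamma
        self.n_significant_ = mp.n_significant
        self.n_components_ = max(
            min(self.min_components, pca.scores.shape[1]), mp.n_significant
        )
        self.components_ = pca.loadings[:, : self.n_components_].T
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        return X @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class SNNLouvain(BaseEstimator, ClusterMixin):
    """SNN-graph Louvain clustering of PC scores (X cells x components)."""

    def __init__(self, k: int = 20, resolution: float = 1.0,
                 prune: float = DEFAULT_SNN_PRUNE, seed: int = 0):
        self.k = k
        self.resolution = resolution
        self.prune = prune
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.graph_ = build_snn_graph(X, k=self.k, prune=self.prune)
        self.labels_ = louvain(self.graph_, resolution=self.resolution, seed=self.seed)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
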