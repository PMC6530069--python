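"""Iterative signed weighted co-expression module discovery.

From an expression matrix over highly variable genes, a signed adjacency
``a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta`` (Pearson, soft power beta) is
transformed into a topological overlap matrix

    TOM_ij = (sum_{u != i,j} a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivities ``k_i = sum_{u != i} a_iu``. An average-linkage tree of
the dissimilarity 1 - TOM is cut at a fixed height; branches of at least a
minimum size become modules (size-ranked color-style labels, smaller
branches "unassigned"). Each module's eigengene is the sign-oriented first
principal component of its member genes; module membership (kME) is the
Pearson correlation of each gene with each eigengene, tested with a
two-sided Student t. Genes not significantly correlated with any module
are discarded and the whole chain is re-run on the survivors — adapting
the minimum module size so at least as many modules as in the first pass
survive — until no gene is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "CoexprParams",
    "ModuleSet",
    "signed_adjacency",
    "topological_overlap",
    "static_tree_cut",
    "module_eigengenes",
    "module_membership",
    "iterative_module_discovery",
    "module_activity",
    "activity_by_group",
    "export_module_graph",
    "CoexpressionModules",
]

UNASSIGNED = "unassigned"

# size-ranked deterministic module labels, color-style by field convention
_COLOR_NAMES = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


def _label(rank: int) -> str:
    return _COLOR_NAMES[rank] if rank < len(_COLOR_NAMES) else f"module{rank + 1}"


@dataclass
class CoexprParams:
    soft_power: float = 8.0
    cut_height: float = 0.9957
    min_module_size: int = 15
    membership_alpha: float = 0.01
    max_iterations: int = 50

    def __post_init__(self):
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.cut_height < 1:
            raise ValueError("cut_height must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleSet:
    """Final module assignment with eigengenes, membership and history."""

    assignment: pd.Series  # gene -> module label
    eigengenes: pd.DataFrame  # cells x modules
    membership: pd.DataFrame  # gene x module kME
    membership_p: pd.DataFrame  # gene x module two-sided p
    discarded: list[list[str]]  # per-iteration discarded gene lists
    iterations: list[dict]
    adjacency: pd.DataFrame | None = None  # final-iteration signed adjacency
    barcodes: list = field(default_factory=list)

    @property
    def module_labels(self) -> list[str]:
        return list(self.eigengenes.columns)

    def genes_of(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


def _as_expr(expr) -> tuple[np.ndarray, list[str], list[str]]:
    """Coerce an expression input to (dense genes x cells, gene_ids, barcodes)."""
    if hasattr(expr, "gene_ids"):
        X = expr.values
        X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        return X, list(expr.gene_ids), list(getattr(expr, "barcodes", range(X.shape[1])))
    X = expr.toarray() if sp.issparse(expr) else np.asarray(expr, dtype=float)
    return (
        X,
        [f"g{i}" for i in range(X.shape[0])],
        [str(i) for i in range(X.shape[1])],
    )


def signed_adjacency(expr, beta: float = 8.0) -> np.ndarray:
    """Signed soft-thresholded adjacency ((1 + cor) / 2) ** beta.

    ``expr`` is genes x cells with at least 3 cells and no constant genes;
    the diagonal is 1 by convention.
    """
    X, _, _ = _as_expr(expr)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    sd = X.std(axis=1)
    if (sd <= 1e-12).any():
        raise ValueError(
            f"{int((sd <= 1e-12).sum())} constant genes; remove before "
            "building the adjacency"
        )
    cor = np.corrcoef(X)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return np.clip(adj, 0.0, 1.0)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Signed topological overlap matrix of an adjacency with unit diagonal."""
    A = np.asarray(adj, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    S = A @ A  # S_ij = sum_u a_iu a_uj, includes u = i and u = j
    shared = S - 2.0 * A  # drop u = i and u = j terms (diagonal is 1)
    k = A.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - A
    numer = shared + A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 1e-12, numer / np.where(denom > 1e-12, denom, 1.0), 0.0)
    if (denom <= 1e-12).any():
        logger.warning("degenerate TOM denominators set to 0")
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def static_tree_cut(
    diss: np.ndarray, cut_height: float = 0.9957, min_module_size: int = 15
) -> np.ndarray:
    """Fixed-height cut of an average-linkage tree of a dissimilarity matrix.

    Branches below ``cut_height`` with at least ``min_module_size`` members
    become modules, labelled by decreasing size; the rest is "unassigned".
    """
    D = np.asarray(diss, dtype=float)
    Z = linkage(squareform(D, checks=False), method="average")
    branches = fcluster(Z, t=cut_height, criterion="distance")
    return _branches_to_labels(branches, min_module_size)


def _branches_to_labels(branches: np.ndarray, min_module_size: int) -> np.ndarray:
    ids, counts = np.unique(branches, return_counts=True)
    keep = ids[counts >= min_module_size]
    if keep.size == 0:
        logger.warning("no branch reaches min size %d; all unassigned", min_module_size)
    sizes = dict(zip(ids.tolist(), counts.tolist()))
    first = {b: int(np.argmax(branches == b)) for b in ids}
    ranked = sorted(keep.tolist(), key=lambda b: (-sizes[b], first[b]))
    name = {b: _label(r) for r, b in enumerate(ranked)}
    return np.array(
        [name.get(b, UNASSIGNED) for b in branches], dtype=object
    )


def module_eigengenes(expr, assignment) -> pd.DataFrame:
    """Sign-oriented, unit-variance first PC of each module's genes.

    Member genes are standardized across cells before the decomposition;
    the eigengene's sign is chosen so its correlation with the module's
    mean (standardized) expression profile is non-negative. A single-gene
    module's eigengene is the standardized gene itself; a constant module
    yields a zero eigengene (flagged in the log).
    """
    X, gene_ids, barcodes = _as_expr(expr)
    assignment = _as_assignment(assignment, gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    cols = {}
    for module in _module_order(assignment):
        rows = [idx[g] for g in assignment.index[assignment == module]]
        sub = X[rows]
        mu, sd = sub.mean(axis=1, keepdims=True), sub.std(axis=1, keepdims=True)
        nonconst = sd.ravel() > 1e-12
        if not nonconst.any():
            logger.warning("module %s is constant; zero eigengene", module)
            cols[module] = np.zeros(X.shape[1])
            continue
        Z = (sub[nonconst] - mu[nonconst]) / sd[nonconst]
        U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
        eig = U[:, 0]
        mean_profile = Z.mean(axis=0)
        if np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        sd_e = eig.std()
        cols[module] = eig / sd_e if sd_e > 0 else eig
    return pd.DataFrame(cols, index=pd.Index(barcodes, name="barcode"))


def _as_assignment(assignment, gene_ids) -> pd.Series:
    if isinstance(assignment, pd.Series):
        return assignment
    if isinstance(assignment, dict):
        return pd.Series(assignment)
    return pd.Series(np.asarray(assignment, dtype=object), index=gene_ids)


def _module_order(assignment: pd.Series) -> list[str]:
    seen = []
    for lab in assignment:
        if lab != UNASSIGNED and lab not in seen:
            seen.append(lab)
    # size-ranked label names sort naturally by their rank in _COLOR_NAMES
    rank = {name: i for i, name in enumerate(_COLOR_NAMES)}
    return sorted(seen, key=lambda m: (rank.get(m, len(_COLOR_NAMES)), m))


def module_membership(expr, eigengenes: pd.DataFrame):
    """kME (gene x module Pearson correlation) and its Student-t p-value.

    p is two-sided from t = r * sqrt((n - 2) / (1 - r^2)) with n = number
    of cells; |r| = 1 maps to p = 0 by convention.
    """
    X, gene_ids, _ = _as_expr(expr)
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 cells")
    E = eigengenes.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=0, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    es = np.sqrt((Ec**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Ec) / np.outer(np.maximum(xs, 1e-300), np.maximum(es, 1e-300))
    r = np.clip(np.nan_to_num(r), -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    kme = pd.DataFrame(r, index=pd.Index(gene_ids, name="gene"), columns=eigengenes.columns)
    pv = pd.DataFrame(p, index=kme.index, columns=kme.columns)
    return kme, pv


def _adaptive_min_size(branches: np.ndarray, target: int, initial: int) -> int:
    """Largest min size <= initial still yielding >= target modules.

    Relaxes the first-pass minimum size downward only as far as needed to
    keep at least as many modules as the first pass produced; if even a
    minimum of 2 cannot reach the target, the initial size is reused.
    """
    _, counts = np.unique(branches, return_counts=True)
    for s in range(initial, 1, -1):
        if int((counts >= s).sum()) >= target:
            return s
    return initial


def iterative_module_discovery(expr, params: CoexprParams | None = None) -> ModuleSet:
    """Repeat adjacency -> TOM -> tree cut -> eigengenes -> membership,
    discarding genes not significantly correlated with any module, until
    the retained gene set is stable.

    ``expr`` is the log-normalized expression of the highly variable genes
    (genes x cells). The first pass uses ``params.min_module_size``; later
    passes adapt the minimum size so at least as many modules as the first
    pass survive. A gene is discarded when its membership p-value exceeds
    ``params.membership_alpha`` for every module eigengene.
    """
    params = params or CoexprParams()
    X, gene_ids, barcodes = _as_expr(expr)
    sd = X.std(axis=1)
    const = sd <= 1e-12
    if const.any():
        logger.warning("dropping %d constant genes", int(const.sum()))
    retained = [g for g, c in zip(gene_ids, const) if not c]
    X = X[~const]

    history: list[dict] = []
    discarded_all: list[list[str]] = []
    n_mod_first: int | None = None
    for it in range(params.max_iterations):
        adj = signed_adjacency(X, beta=params.soft_power)
        tom = topological_overlap(adj)
        diss = 1.0 - tom
        Z = linkage(squareform(diss, checks=False), method="average")
        branches = fcluster(Z, t=params.cut_height, criterion="distance")
        if n_mod_first is None:
            min_size = params.min_module_size
        else:
            min_size = _adaptive_min_size(branches, n_mod_first, params.min_module_size)
        labels = _branches_to_labels(branches, min_size)
        assignment = pd.Series(labels, index=pd.Index(retained, name="gene"))
        n_modules = len(_module_order(assignment))
        if n_modules == 0:
            raise RuntimeError(
                f"module count dropped to 0 at iteration {it + 1}; "
                f"history: {history}"
            )
        if n_mod_first is None:
            n_mod_first = n_modules
        eig = module_eigengenes(_wrap(X, retained, barcodes), assignment)
        kme, pv = module_membership(_wrap(X, retained, barcodes), eig)
        fails = pv.min(axis=1) > params.membership_alpha
        drop = list(pv.index[fails])
        history.append(
            {
                "iteration": it + 1,
                "min_size": min_size,
                "n_modules": n_modules,
                "n_retained": len(retained),
                "n_discarded": len(drop),
            }
        )
        discarded_all.append(drop)
        if not drop:
            adj_df = pd.DataFrame(adj, index=assignment.index, columns=assignment.index)
            return ModuleSet(
                assignment=assignment,
                eigengenes=eig,
                membership=kme,
                membership_p=pv,
                discarded=discarded_all,
                iterations=history,
                adjacency=adj_df,
                barcodes=barcodes,
            )
        keep_mask = ~fails.to_numpy()
        retained = [g for g, k in zip(retained, keep_mask) if k]
        X = X[keep_mask]
        if len(retained) < 3:
            raise RuntimeError(f"fewer than 3 genes retained; history: {history}")
    raise RuntimeError(
        f"no convergence within {params.max_iterations} iterations; history: {history}"
    )


def _wrap(X, gene_ids, barcodes):
    from types import SimpleNamespace

    return SimpleNamespace(values=X, gene_ids=gene_ids, barcodes=barcodes)


def module_activity(nm, assignment) -> pd.DataFrame:
    """Per-cell mean log-normalized expression over each module's genes.

    Module genes absent from the matrix are skipped (logged); a module
    with no present genes is an error.
    """
    X, gene_ids, barcodes = _as_expr(nm)
    assignment = _as_assignment(assignment, gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    cols = {}
    for module in _module_order(assignment):
        genes = [g for g in assignment.index[assignment == module]]
        present = [idx[g] for g in genes if g in idx]
        missing = len(genes) - len(present)
        if missing:
            logger.warning("module %s: %d genes absent from matrix", module, missing)
        if not present:
            raise ValueError(f"module {module} has no genes in the matrix")
        cols[module] = X[present].mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(barcodes, name="barcode"))


def activity_by_group(act: pd.DataFrame, groups) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Mean module activity per (stage, sub-cluster) group, with dendrogram
    leaf orders of both axes for heatmap layout.

    ``groups`` is a per-cell sequence of (stage, sub_cluster) pairs aligned
    with the rows of ``act``. Groups with zero cells cannot occur by
    construction; rows and columns are ordered by average-linkage
    Euclidean clustering when there are at least 2 of them.
    """
    keys = pd.MultiIndex.from_tuples(list(groups), names=["stage", "sub_cluster"])
    tmp = act.set_index(keys)
    mat = tmp.groupby(level=["stage", "sub_cluster"], sort=True).mean()
    out = mat.T  # modules x groups (MultiIndex columns)
    row_order = _dendro_order(out.to_numpy())
    col_order = _dendro_order(out.to_numpy().T)
    return out, row_order, col_order


def _dendro_order(M: np.ndarray) -> np.ndarray:
    if M.shape[0] < 2:
        return np.arange(M.shape[0])
    return leaves_list(linkage(M, method="average", metric="euclidean"))


def export_module_graph(
    ms: ModuleSet, adj: pd.DataFrame | None = None, module: str = "",
    top_n: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of one module for graph-GUI import.

    Nodes are the ``top_n`` member genes by own-module kME, sized by kME
    rescaled to the module's min-max; edges carry the pairwise signed
    adjacency rescaled likewise, plus a visibility flag at the largest
    threshold that keeps at least one edge per node.
    """
    if module not in ms.module_labels:
        raise KeyError(f"unknown module {module!r}")
    adj = ms.adjacency if adj is None else adj
    genes = ms.genes_of(module)
    kme = ms.membership.loc[genes, module].sort_values(ascending=False, kind="stable")
    if top_n is not None:
        kme = kme.iloc[:top_n]
    genes = list(kme.index)
    lo, hi = float(kme.min()), float(kme.max())
    size = (kme - lo) / (hi - lo) if hi > lo else pd.Series(1.0, index=kme.index)
    nodes = pd.DataFrame(
        {"gene": genes, "membership": kme.to_numpy(), "size": size.to_numpy()}
    )
    A = adj.loc[genes, genes].to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    w = A[iu]
    wlo, whi = (w.min(), w.max()) if w.size else (0.0, 0.0)
    scaled = (w - wlo) / (whi - wlo) if whi > wlo else np.ones_like(w)
    edges = pd.DataFrame(
        {
            "source": [genes[i] for i in iu[0]],
            "target": [genes[j] for j in iu[1]],
            "weight": w,
            "scaled_weight": scaled,
        }
    )
    # visibility threshold: the largest weight leaving every node with at
    # least one incident visible edge = min over nodes of max incident weight
    if len(genes) > 1:
        W = A.copy()
        np.fill_diagonal(W, -np.inf)
        thresh = float(W.max(axis=1).min())
        edges["visible"] = edges["weight"] >= thresh
    else:
        edges["visible"] = pd.Series(dtype=bool)
    return nodes, edges


class CoexpressionModules(BaseEstimator):
    """Iterative signed-TOM module discovery with an sklearn surface.

    ``fit(X)`` takes log-normalized expression (cells x genes; optional
    ``gene_ids`` fit parameter). Fitted attributes: ``assignment_``,
    ``eigengenes_``, ``membership_``, ``membership_p_``, ``iterations_``,
    ``module_set_``.
    """

    def __init__(self, soft_power=8.0, cut_height=0.9957, min_module_size=15,
                 membership_alpha=0.01, max_iterations=50):
        self.soft_power = soft_power
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.membership_alpha = membership_alpha
        self.max_iterations = max_iterations

    def fit(self, X, y=None, gene_ids=None):
        X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        gene_ids = gene_ids or [f"g{i}" for i in range(X.shape[1])]
        params = CoexprParams(
            soft_power=self.soft_power,
            cut_height=self.cut_height,
            min_module_size=self.min_module_size,
            membership_alpha=self.membership_alpha,
            max_iterations=self.max_iterations,
        )
        expr = _wrap(X.T, list(gene_ids), [str(i) for i in range(X.shape[0])])
        ms = iterative_module_discovery(expr, params)
        self.module_set_ = ms
        self.assignment_ = ms.assignment
        self.eigengenes_ = ms.eigengenes
        self.membership_ = ms.membership
        self.membership_p_ = ms.membership_p
        self.iterations_ = ms.iterations
        self.n_features_in_ = X.shape[1]
        return self
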