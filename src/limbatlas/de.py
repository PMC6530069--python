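"""Negative-binomial differential expression and recursive cluster collapse.

Per gene, UMI counts are modelled as NB2 (variance = mu + mu^2 * alpha,
gene-wise alpha estimated by maximum likelihood) with a log link,
``log mu = b0 + b1 * group + b2 * covariate + log(total UMI)`` — the
log-total-UMI offset absorbs library size and the covariate slot carries
the cell-cycle nuisance score delta_G2M/S. The group effect is assessed by
a likelihood-ratio test against the model without the group indicator.
Genes enter testing only if expressed (count > 0) in at least
``min_pct_test`` of either compared population; p-values are
Bonferroni-adjusted over the tested genes (Benjamini-Hochberg available).

Marker signatures keep genes with focus-cluster expression fraction >=
``min_pct_signature``, average log fold-change > ``min_logfc`` and adjusted
p < ``max_padj``. Cluster pairs that are siblings on the centroid
dendrogram and separate by fewer than ``collapse_min_de`` signature-grade
genes (union of both directions) are merged, recursively, until stable.

The NB fitting is a small IRLS + profile-likelihood routine written for
speed of the per-gene loop; a gene whose NB fit fails falls back to a
Poisson fit, and a gene failing both is reported with p = 1. Both events
are flagged in the result table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, xlogy
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .io import CountMatrix
from .qc_norm import ScaledMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEThresholds",
    "ClusterTree",
    "nb_de_test",
    "marker_signature",
    "build_cluster_tree",
    "collapse_clusters",
    "one_vs_within_set_de",
    "NegativeBinomialDE",
]


@dataclass
class DEThresholds:
    min_pct_test: float = 0.15
    min_pct_signature: float = 0.25
    min_logfc: float = 0.5
    max_padj: float = 0.05
    collapse_min_de: int = 15
    adjust: str = "bonferroni"  # or "bh"

    def __post_init__(self):
        for f in (self.min_pct_test, self.min_pct_signature):
            if not 0 <= f <= 1:
                raise ValueError("expression fractions must lie in [0, 1]")
        if self.collapse_min_de < 1:
            raise ValueError("collapse_min_de must be >= 1")
        if self.adjust not in ("bonferroni", "bh"):
            raise ValueError("adjust must be 'bonferroni' or 'bh'")


@dataclass
class ClusterTree:
    """Average-linkage dendrogram over cluster centroids."""

    linkage_matrix: np.ndarray
    leaves: list  # cluster ids, in linkage leaf order 0..n-1

    def sibling_leaf_pairs(self) -> list[tuple]:
        """Cluster-id pairs that are joined directly as two leaves."""
        n = len(self.leaves)
        out = []
        for a, b, _, _ in self.linkage_matrix:
            if a < n and b < n:
                out.append((self.leaves[int(a)], self.leaves[int(b)]))
        return out


# ---------------------------------------------------------------------------
# NB2 GLM fitting: IRLS for the coefficients, profile ML for the dispersion
# ---------------------------------------------------------------------------

_MIN_MU, _MAX_MU = 1e-10, 1e10


def _nb_loglik(y, mu, alpha):
    mu = np.clip(mu, _MIN_MU, _MAX_MU)
    if alpha < 1e-10:
        return float(np.sum(xlogy(y, mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + xlogy(y, alpha * mu)
            - (y + r) * np.log1p(alpha * mu)
        )
    )


def _irls(y, X, offset, alpha, beta0=None, maxiter=50, tol=1e-8):
    """Newton-scoring fit of an NB2 (or Poisson, alpha=0) log-link GLM."""
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 1e-8)) - np.log(np.exp(offset).mean())
    else:
        beta = beta0.copy()
    ll_old = -np.inf
    for _ in range(maxiter):
        eta = X @ beta + offset
        mu = np.clip(np.exp(np.clip(eta, -30, 30)), _MIN_MU, _MAX_MU)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XW = X * W[:, None]
        H = XW.T @ X + 1e-10 * np.eye(p)
        beta_new = np.linalg.solve(H, XW.T @ z)
        if not np.all(np.isfinite(beta_new)):
            raise FloatingPointError("IRLS diverged")
        beta_new = np.clip(beta_new, -30, 30)
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta_new + offset, -30, 30)), alpha)
        beta = beta_new
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    mu = np.clip(np.exp(np.clip(X @ beta + offset, -30, 30)), _MIN_MU, _MAX_MU)
    return beta, mu, _nb_loglik(y, mu, alpha)


def _ml_alpha(y, mu, lo=-12.0, hi=6.0):
    """Profile-ML dispersion on the log scale with the means held fixed."""
    res = minimize_scalar(
        lambda la: -_nb_loglik(y, mu, np.exp(la)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def _fit_nb(y, X, offset, n_rounds=4):
    """Alternating IRLS / dispersion updates; returns (loglik, alpha, beta)."""
    var, mean = y.var(), y.mean()
    alpha = max((var - mean) / max(mean**2, 1e-8), 1e-4)
    beta = None
    for _ in range(n_rounds):
        beta, mu, _ = _irls(y, X, offset, alpha, beta0=beta)
        alpha_new = _ml_alpha(y, mu)
        if abs(np.log(alpha_new + 1e-12) - np.log(alpha + 1e-12)) < 1e-3:
            alpha = alpha_new
            break
        alpha = alpha_new
    beta, mu, ll = _irls(y, X, offset, alpha, beta0=beta)
    return ll, alpha, beta


def _lrt_gene(y, design_full, design_null, offset):
    """LRT p-value for the group coefficient; returns (p, flag)."""
    try:
        ll_full, _, _ = _fit_nb(y, design_full, offset)
        ll_null, _, _ = _fit_nb(y, design_null, offset)
        flag = "ok"
    except (FloatingPointError, np.linalg.LinAlgError):
        try:  # Poisson fallback
            _, _, ll_full = _irls(y, design_full, offset, 0.0)
            _, _, ll_null = _irls(y, design_null, offset, 0.0)
            flag = "poisson_fallback"
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1.0, "fit_failed"
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    return float(chi2.sf(stat, df=1)), flag


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _cells_to_idx(cm: CountMatrix, cells) -> np.ndarray:
    cells = list(cells)
    if cells and isinstance(cells[0], str):
        pos = {b: i for i, b in enumerate(cm.barcodes)}
        return np.array([pos[c] for c in cells], dtype=int)
    return np.asarray(cells, dtype=int)


def nb_de_test(
    cm: CountMatrix,
    group_a,
    group_b,
    covariate=None,
    th: DEThresholds | None = None,
    scale_factor: float = 1e4,
) -> pd.DataFrame:
    """NB likelihood-ratio differential expression, group_a vs group_b.

    ``group_a``/``group_b`` are disjoint cell sets (barcodes or column
    indices), each of size >= 3; ``covariate`` is an optional per-cell
    nuisance value (pd.Series over barcodes, or an array over all columns
    of ``cm``). Returns one row per *tested* gene with columns p_val,
    avg_logFC, pct_x, pct_rest, p_val_adj, enrichment, flag.
    """
    th = th or DEThresholds()
    ia, ib = _cells_to_idx(cm, group_a), _cells_to_idx(cm, group_b)
    if len(np.intersect1d(ia, ib)):
        raise ValueError("groups must be disjoint")
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("each group needs at least 3 cells")
    idx = np.concatenate([ia, ib])
    grp = np.concatenate([np.ones(len(ia)), np.zeros(len(ib))])

    X = sp.csc_matrix(cm.values)[:, idx]
    totals = np.asarray(X.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-UMI cells present; filter before DE")
    dense = X.toarray().astype(float)

    pct_a = (dense[:, grp == 1] > 0).mean(axis=1)
    pct_b = (dense[:, grp == 0] > 0).mean(axis=1)
    tested = (pct_a >= th.min_pct_test) | (pct_b >= th.min_pct_test)
    genes = np.flatnonzero(tested)
    if genes.size == 0:
        return _empty_de_frame()

    offset = np.log(totals)
    cov_col = None
    if covariate is not None:
        if isinstance(covariate, pd.Series):
            cov_col = covariate.loc[[cm.barcodes[i] for i in idx]].to_numpy(float)
        else:
            cov_col = np.asarray(covariate, dtype=float)[idx]
    cols = [np.ones(len(idx)), grp] + ([cov_col] if cov_col is not None else [])
    design_full = np.column_stack(cols)
    design_null = np.delete(design_full, 1, axis=1)

    lognorm = np.log1p(dense * (scale_factor / totals)[None, :])
    mean_a = lognorm[:, grp == 1].mean(axis=1)
    mean_b = lognorm[:, grp == 0].mean(axis=1)

    pvals, flags = np.ones(genes.size), []
    for out_i, g in enumerate(genes):
        pvals[out_i], flag = _lrt_gene(dense[g], design_full, design_null, offset)
        flags.append(flag)
        if flag != "ok":
            logger.debug("gene %s: %s", cm.gene_ids[g], flag)

    with np.errstate(divide="ignore"):
        enrich = np.where(pct_b[genes] > 0, pct_a[genes] / np.maximum(pct_b[genes], 1e-300), np.inf)
    return pd.DataFrame(
        {
            "p_val": pvals,
            "avg_logFC": (mean_a - mean_b)[genes],
            "pct_x": pct_a[genes],
            "pct_rest": pct_b[genes],
            "p_val_adj": _adjust(pvals, th.adjust),
            "enrichment": enrich,
            "flag": flags,
        },
        index=pd.Index([cm.gene_ids[g] for g in genes], name="gene"),
    )


def _empty_de_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "p_val": pd.Series(dtype=float),
            "avg_logFC": pd.Series(dtype=float),
            "pct_x": pd.Series(dtype=float),
            "pct_rest": pd.Series(dtype=float),
            "p_val_adj": pd.Series(dtype=float),
            "enrichment": pd.Series(dtype=float),
            "flag": pd.Series(dtype=object),
        },
        index=pd.Index([], name="gene"),
    )


def de_table_for_export(
    de: pd.DataFrame, cluster, gene_names: dict[str, str] | None = None
) -> pd.DataFrame:
    """Reshape a DEResult into the conventional marker-table column set
    (p_val, avg_logFC, pct.x, pct.rest, p_val_adj, cluster, gene, name,
    enrichment)."""
    gene_names = gene_names or {}
    return pd.DataFrame(
        {
            "p_val": de["p_val"].to_numpy(),
            "avg_logFC": de["avg_logFC"].to_numpy(),
            "pct.x": de["pct_x"].to_numpy(),
            "pct.rest": de["pct_rest"].to_numpy(),
            "p_val_adj": de["p_val_adj"].to_numpy(),
            "cluster": cluster,
            "gene": de.index.to_numpy(),
            "name": [gene_names.get(g, g) for g in de.index],
            "enrichment": de["enrichment"].to_numpy(),
        }
    )


def marker_signature(de: pd.DataFrame, th: DEThresholds | None = None) -> list[str]:
    """Signature genes: pct_x >= 25%, logFC > 0.5, adjusted p < 0.05.

    Sorted by avg_logFC descending; an empty list is a valid result.
    """
    th = th or DEThresholds()
    keep = de[
        (de["pct_x"] >= th.min_pct_signature)
        & (de["avg_logFC"] > th.min_logfc)
        & (de["p_val_adj"] < th.max_padj)
    ]
    return list(keep.sort_values("avg_logFC", ascending=False, kind="stable").index)


def _bidirectional_de_count(de: pd.DataFrame, th: DEThresholds) -> int:
    """Signature-grade genes in either direction of one symmetric contrast.

    The LRT p-value is direction-free, so the reverse contrast is the same
    table with avg_logFC negated and pct_x/pct_rest swapped.
    """
    sig = de["p_val_adj"] < th.max_padj
    fwd = sig & (de["avg_logFC"] > th.min_logfc) & (de["pct_x"] >= th.min_pct_signature)
    rev = sig & (-de["avg_logFC"] > th.min_logfc) & (de["pct_rest"] >= th.min_pct_signature)
    return int((fwd | rev).sum())


def build_cluster_tree(sm, labels, scores: np.ndarray | None = None) -> ClusterTree:
    """Average-linkage tree of cluster centroids in significant-PC space.

    ``scores`` (cells x components) may be supplied to avoid recomputing
    the PCA; otherwise it is derived from ``sm`` via Marchenko-Pastur
    selection.
    """
    labels = np.asarray(labels)
    ids = sorted(np.unique(labels).tolist())
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    if scores is None:
        scores = _significant_scores(sm)
    centroids = np.vstack([scores[labels == c].mean(axis=0) for c in ids])
    Z = linkage(centroids, method="average", metric="euclidean")
    return ClusterTree(linkage_matrix=Z, leaves=ids)


def _significant_scores(sm: ScaledMatrix) -> np.ndarray:
    from .cluster import mp_significant, run_pca

    pca = run_pca(sm)
    mp = mp_significant(pca.eigenvalues, pca.n_cells, pca.n_genes)
    n_sig = mp.n_significant if mp.n_significant > 0 else min(2, pca.scores.shape[1])
    return pca.scores[:, :n_sig]


def collapse_clusters(
    cm: CountMatrix,
    sm: ScaledMatrix,
    labels,
    covariate=None,
    th: DEThresholds | None = None,
    scores: np.ndarray | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Recursively merge under-differentiated sibling cluster pairs.

    Each round rebuilds the centroid dendrogram, tests every sibling leaf
    pair for differential expression, and simultaneously merges all pairs
    with fewer than ``collapse_min_de`` signature-grade DE genes (lowest
    label id survives). Stops when a round makes no merge; bounded by the
    initial cluster count. Returns contiguously relabelled assignments and
    a merge log.
    """
    th = th or DEThresholds()
    labels = np.asarray(labels).copy()
    if scores is None:
        scores = _significant_scores(sm)
    merge_log: list[dict] = []
    max_rounds = len(np.unique(labels))
    for rnd in range(max_rounds):
        ids = np.unique(labels)
        if len(ids) < 2:
            break
        tree = build_cluster_tree(sm, labels, scores=scores)
        merged_any = False
        merges = []
        for a, b in tree.sibling_leaf_pairs():
            de = nb_de_test(
                cm,
                np.flatnonzero(labels == a),
                np.flatnonzero(labels == b),
                covariate=covariate,
                th=th,
            )
            n_de = _bidirectional_de_count(de, th)
            if n_de < th.collapse_min_de:
                merges.append((a, b, n_de))
        for a, b, n_de in merges:
            lo, hi = min(a, b), max(a, b)
            labels[labels == hi] = lo
            merged_any = True
            merge_log.append(
                {"round": rnd, "kept": int(lo), "merged": int(hi), "n_de": n_de}
            )
            logger.info("merged cluster %s into %s (%d DE genes)", hi, lo, n_de)
        if not merged_any:
            break
    # contiguous relabelling, preserving label order
    ids = sorted(np.unique(labels).tolist())
    remap = {old: new for new, old in enumerate(ids)}
    return np.array([remap[c] for c in labels]), merge_log


def one_vs_within_set_de(
    cm: CountMatrix,
    labels,
    focus,
    background_set,
    covariate=None,
    th: DEThresholds | None = None,
) -> pd.DataFrame:
    """DE of one cluster against the pooled cells of a named cluster set.

    Used for contrasts like one interdigit sub-cluster versus the other
    two; with ``background_set`` = all other clusters it reduces to the
    standard one-vs-rest test.
    """
    if focus in background_set:
        raise ValueError("focus cluster cannot be part of the background set")
    labels = np.asarray(labels)
    bg = np.flatnonzero(np.isin(labels, list(background_set)))
    if bg.size == 0:
        raise ValueError("empty background")
    return nb_de_test(
        cm, np.flatnonzero(labels == focus), bg, covariate=covariate, th=th
    )


class NegativeBinomialDE(BaseEstimator):
    """Sklearn-style wrapper for the NB LRT test.

    ``fit(X, y)`` takes counts (cells x genes) and a binary group vector
    (1 = focus group); optional ``covariate`` and gene names are fit
    parameters. The result table is stored as ``results_``.
    """

    def __init__(self, min_pct_test=0.15, min_pct_signature=0.25,
                 min_logfc=0.5, max_padj=0.05, adjust="bonferroni"):
        self.min_pct_test = min_pct_test
        self.min_pct_signature = min_pct_signature
        self.min_logfc = min_logfc
        self.max_padj = max_padj
        self.adjust = adjust

    def _thresholds(self) -> DEThresholds:
        return DEThresholds(
            min_pct_test=self.min_pct_test,
            min_pct_signature=self.min_pct_signature,
            min_logfc=self.min_logfc,
            max_padj=self.max_padj,
            adjust=self.adjust,
        )

    def fit(self, X, y, covariate=None, gene_ids=None):
        X = sp.csr_matrix(X)
        y = np.asarray(y)
        gene_ids = gene_ids or [f"g{i}" for i in range(X.shape[1])]
        cm = CountMatrix(X.T, list(gene_ids))
        self.results_ = nb_de_test(
            cm,
            np.flatnonzero(y == 1),
            np.flatnonzero(y != 1),
            covariate=covariate,
            th=self._thresholds(),
        )
        self.signature_ = marker_signature(self.results_, self._thresholds())
        self.n_features_in_ = X.shape[1]
        return self
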