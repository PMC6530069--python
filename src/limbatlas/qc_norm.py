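"""Per-cell QC, filtering rules, log-normalization, variable-gene selection
and covariate-regression scaling.

Filtering follows three rules, all evaluated on the *unfiltered* sample in a
single pass: cells whose total UMI count exceeds ``upper_mean_mult`` times
the sample mean, falls below ``lower_median_frac`` of the sample median, or
whose mitochondrial or ribosomal UMI fraction exceeds
``organelle_frac_max``, are removed. Log-normalization maps a count c in a
cell with total t to ``log(1 + c * scale_factor / t)`` (natural log).
Variable genes are picked by binned standardized dispersion of the
back-transformed expression; scaling residualizes each gene on nuisance
covariates by OLS and z-scores the residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix, GeneClassMap

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "NormalizedMatrix",
    "ScaledMatrix",
    "compute_qc_metrics",
    "filter_cells",
    "lognormalize",
    "select_variable_genes",
    "regress_and_scale",
    "LogNormalizer",
    "VariableGeneSelector",
    "CovariateScaler",
]


@dataclass
class QCThresholds:
    """Cell-filtering thresholds.

    ``combined_organelle`` switches the 10% organelle rule from
    each-class-separately (default) to the sum of both fractions.
    """

    upper_mean_mult: float = 4.0
    lower_median_frac: float = 0.20
    organelle_frac_max: float = 0.10
    combined_organelle: bool = False

    def __post_init__(self):
        if min(self.upper_mean_mult, self.lower_median_frac, self.organelle_frac_max) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class NormalizedMatrix:
    """Log-normalized genes x cells expression."""

    values: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    scale_factor: float

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def subset_genes(self, idx) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            list(self.barcodes),
            self.scale_factor,
        )


@dataclass
class ScaledMatrix:
    """Residual z-scores (genes x cells) after covariate regression."""

    values: np.ndarray
    gene_ids: list[str]
    barcodes: list[str]
    covariates_used: list[str] = field(default_factory=list)


def compute_qc_metrics(cm: CountMatrix, classes: GeneClassMap) -> pd.DataFrame:
    """Per-cell QC table: UMI totals, genes detected, organelle fractions.

    Cells with zero UMIs get fractions 0 and ``degenerate=True``.
    """
    if cm.n_cells == 0:
        raise ValueError("empty count matrix")
    X = sp.csc_matrix(cm.values)
    umi_total = np.asarray(X.sum(axis=0)).ravel()
    genes_detected = np.diff(X.indptr)
    mito = np.asarray(X[classes.mask(cm.gene_ids, "mitochondrial")].sum(axis=0)).ravel()
    ribo = np.asarray(X[classes.mask(cm.gene_ids, "ribosomal")].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.maximum(umi_total, 1)
        mito_frac = np.where(umi_total > 0, mito / denom, 0.0)
        ribo_frac = np.where(umi_total > 0, ribo / denom, 0.0)
    return pd.DataFrame(
        {
            "umi_total": umi_total,
            "genes_detected": genes_detected,
            "mito_frac": mito_frac,
            "ribo_frac": ribo_frac,
            "degenerate": umi_total == 0,
        },
        index=pd.Index(cm.barcodes, name="barcode"),
    )


def filter_cells(qc: pd.DataFrame, th: QCThresholds) -> tuple[list[str], pd.DataFrame]:
    """Apply the UMI-extremes and organelle-fraction rules.

    The sample mean and median of the UMI totals are computed once, on the
    full unfiltered table. Returns the retained barcodes plus the table
    augmented with ``keep`` and ``rule_triggered`` columns.
    """
    qc = qc.copy()
    u = qc["umi_total"].to_numpy(dtype=float)
    mean_u, median_u = u.mean(), np.median(u)
    rules = []
    high = u > th.upper_mean_mult * mean_u
    low = u < th.lower_median_frac * median_u
    rules.append(("high_umi", high))
    rules.append(("low_umi", low))
    if th.combined_organelle:
        org = (qc["mito_frac"] + qc["ribo_frac"]).to_numpy() > th.organelle_frac_max
        rules.append(("organelle_frac", org))
    else:
        rules.append(("mito_frac", qc["mito_frac"].to_numpy() > th.organelle_frac_max))
        rules.append(("ribo_frac", qc["ribo_frac"].to_numpy() > th.organelle_frac_max))
    triggered = np.full(len(qc), "", dtype=object)
    removed = np.zeros(len(qc), dtype=bool)
    for name, mask in rules:
        newly = mask & ~removed
        triggered[newly] = name
        # a cell failing several rules logs the first in rule order, but is
        # removed either way
        removed |= mask
    qc["keep"] = ~removed
    qc["rule_triggered"] = triggered
    for bc, rule in zip(qc.index[removed], triggered[removed]):
        logger.info("cell %s removed by rule %s", bc, rule)
    if removed.all():
        raise ValueError("all cells removed by QC filtering")
    return list(qc.index[~removed]), qc


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Per-cell total-count scaling to ``scale_factor`` followed by log1p."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cm.cell_totals()
    if (totals == 0).any():
        raise ValueError("cells with zero UMIs must be filtered before normalization")
    X = sp.csc_matrix(cm.values, dtype=float)
    X = X.multiply(scale_factor / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return NormalizedMatrix(X, list(cm.gene_ids), list(cm.barcodes), scale_factor)


def select_variable_genes(
    nm: NormalizedMatrix, dispersion_cutoff: float = 0.5, n_bins: int = 20
) -> list[str]:
    """Highly variable genes by binned standardized dispersion.

    Per gene the mean and the dispersion (variance / mean) of the
    back-transformed expression ``expm1(x)`` are computed; genes are binned
    into ``n_bins`` equal-frequency bins by mean, the dispersion is z-scored
    within each bin, and genes with standardized dispersion strictly above
    ``dispersion_cutoff`` are returned (input order preserved).
    """
    if len(nm.barcodes) < 2:
        raise ValueError("need at least 2 cells")
    X = np.expm1(nm.dense())
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    n_genes = len(mean)
    if n_genes < n_bins:
        logger.warning("fewer genes (%d) than bins (%d); reducing", n_genes, n_bins)
        n_bins = max(1, n_genes)
    bins = pd.qcut(pd.Series(mean).rank(method="first"), n_bins, labels=False)
    z = np.zeros(n_genes)
    for b in range(n_bins):
        in_bin = bins.to_numpy() == b
        d = disp[in_bin]
        sd = d.std(ddof=1) if in_bin.sum() > 1 else 0.0
        z[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0
    selected = z > dispersion_cutoff
    return [g for g, s in zip(nm.gene_ids, selected) if s]


def _residualize(Y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of every row of Y (genes x cells) on the design."""
    beta, _, rank, _ = np.linalg.lstsq(design, Y.T, rcond=None)
    if rank < design.shape[1]:
        logger.warning("rank-deficient covariate design (rank %d of %d); "
                       "pseudo-inverse solution used", rank, design.shape[1])
    return (Y.T - design @ beta).T


def regress_and_scale(nm: NormalizedMatrix, covariates: pd.DataFrame | None) -> ScaledMatrix:
    """Residualize each gene on intercept + covariates, then z-score.

    Covariates are a per-cell numeric table aligned with ``nm.barcodes``
    (or None for centering/scaling only). Constant genes map to all-zero
    rows.
    """
    Y = nm.dense()
    n_cells = Y.shape[1]
    cols: list[str] = []
    design = np.ones((n_cells, 1))
    if covariates is not None and covariates.shape[1] > 0:
        if covariates.isna().any().any():
            raise ValueError("covariates contain missing values")
        cov = covariates.loc[list(nm.barcodes)] if not covariates.index.equals(
            pd.Index(nm.barcodes)
        ) else covariates
        cols = list(cov.columns)
        design = np.hstack([design, cov.to_numpy(dtype=float)])
    resid = _residualize(Y, design)
    sd = resid.std(axis=1, ddof=0)
    nonconst = sd > 1e-12
    Z = np.zeros_like(resid)
    Z[nonconst] = resid[nonconst] / sd[nonconst, None]
    return ScaledMatrix(Z, list(nm.gene_ids), list(nm.barcodes), cols)


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Total-count log-normalization with an sklearn surface (X cells x genes)."""

    def __init__(self, scale_factor: float = 1e4):
        self.scale_factor = scale_factor

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = sp.csr_matrix(X, dtype=float)
        totals = np.asarray(X.sum(axis=1)).ravel()
        if (totals == 0).any():
            raise ValueError("cells with zero totals")
        X = X.multiply(self.scale_factor / totals[:, None]).tocsr()
        X.data = np.log1p(X.data)
        return X


class VariableGeneSelector(BaseEstimator, TransformerMixin):
    """Binned-dispersion gene selector (X cells x genes, log-normalized)."""

    def __init__(self, dispersion_cutoff: float = 0.5, n_bins: int = 20):
        self.dispersion_cutoff = dispersion_cutoff
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = X.toarray() if sp.issparse(X) else np.asarray(X)
        nm = NormalizedMatrix(
            sp.csr_matrix(X.T),
            [str(i) for i in range(X.shape[1])],
            [str(i) for i in range(X.shape[0])],
            1.0,
        )
        keep = set(select_variable_genes(nm, self.dispersion_cutoff, self.n_bins))
        self.support_ = np.array([str(i) in keep for i in range(X.shape[1])])
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        return X[:, self.support_]


class CovariateScaler(BaseEstimator, TransformerMixin):
    """Per-gene OLS residualization on nuisance covariates plus z-scoring.

    The covariate matrix (cells x k) is passed at construction or as
    ``fit(X, covariates=...)``; an intercept is always included.
    """

    def __init__(self, covariates=None):
        self.covariates = covariates

    def fit(self, X, y=None, covariates=None):
        self.n_features_in_ = X.shape[1]
        self.fit_covariates_ = covariates if covariates is not None else self.covariates
        return self

    def transform(self, X):
        X = X.toarray() if sp.issparse(X) else np.asarray(X)
        cov = self.fit_covariates_
        nm = NormalizedMatrix(
            sp.csr_matrix(X.T),
            [str(i) for i in range(X.shape[1])],
            [str(i) for i in range(X.shape[0])],
            1.0,
        )
        cov_df = None
        if cov is not None:
            cov_df = pd.DataFrame(np.asarray(cov, dtype=float), index=nm.barcodes)
        return regress_and_scale(nm, cov_df).values.T
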