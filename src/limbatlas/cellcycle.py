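"""Cell-cycle phase scoring from marker-gene pairs.

Each phase (G1, S, G2/M) carries a catalogue of ordered gene pairs
``(g_hi, g_lo)`` expected to satisfy ``expr(g_hi) > expr(g_lo)`` in cells of
that phase. The per-cell phase score is the fraction of informative pairs
(pairs whose two members are not tied in that cell) that vote for the phase.
Because only within-cell ranks are compared, scores are invariant under any
monotone per-cell transformation of expression. The derived covariate
``delta_g2m_s = s_G2M - s_S`` is used downstream as a nuisance regressor,
never as a hard filter.

Pair catalogues trained in a source species are translated through an
ortholog table before scoring; pairs with an unmapped member are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "PairSet",
    "PhaseScores",
    "translate_pairs",
    "score_phases",
    "PhasePairScorer",
    "read_pair_tables",
    "read_ortholog_table",
]

PHASE_ORDER = ("G1", "S", "G2M")  # also the tie-break priority for calls


@dataclass
class PairSet:
    """Ordered marker pairs for one cell-cycle phase."""

    phase: str
    pairs: list[tuple[str, str]]

    def __post_init__(self):
        if self.phase not in PHASE_ORDER:
            raise ValueError(f"phase must be one of {PHASE_ORDER}")
        for hi, lo in self.pairs:
            if hi == lo:
                raise ValueError(f"degenerate pair ({hi}, {lo})")


@dataclass
class PhaseScores:
    """Per-cell phase scores, their G2M-S difference, and the arg-max call."""

    barcodes: list[str]
    s_g1: np.ndarray
    s_s: np.ndarray
    s_g2m: np.ndarray
    delta_g2m_s: np.ndarray
    phase_call: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_g1": self.s_g1,
                "s_s": self.s_s,
                "s_g2m": self.s_g2m,
                "delta_g2m_s": self.delta_g2m_s,
                "phase_call": self.phase_call,
            },
            index=pd.Index(self.barcodes, name="barcode"),
        )


def translate_pairs(
    pairsets: list[PairSet], ortholog_table: dict[str, str]
) -> tuple[list[PairSet], dict[str, int]]:
    """Map both members of every pair through an ortholog table.

    Pairs with either member unmapped are dropped; per-phase drop counts are
    returned alongside. A phase left with zero pairs is an error, since it
    could no longer be scored.
    """
    out, dropped = [], {}
    for ps in pairsets:
        kept = []
        n_drop = 0
        for hi, lo in ps.pairs:
            if hi in ortholog_table and lo in ortholog_table:
                kept.append((ortholog_table[hi], ortholog_table[lo]))
            else:
                n_drop += 1
        if not kept:
            raise ValueError(
                f"no pair of phase {ps.phase} survived ortholog translation"
            )
        dropped[ps.phase] = n_drop
        out.append(PairSet(ps.phase, kept))
    return out, dropped


def _phase_score(expr: np.ndarray, gene_index: dict[str, int], ps: PairSet):
    """Vote-fraction score of one phase for every cell (column of expr)."""
    hi_idx, lo_idx, n_missing = [], [], 0
    for hi, lo in ps.pairs:
        if hi in gene_index and lo in gene_index:
            hi_idx.append(gene_index[hi])
            lo_idx.append(gene_index[lo])
        else:
            n_missing += 1
    if n_missing:
        logger.warning(
            "phase %s: %d pairs skipped (gene absent from matrix)",
            ps.phase,
            n_missing,
        )
    if not hi_idx:
        return np.full(expr.shape[1], 0.5)
    hi = expr[hi_idx]
    lo = expr[lo_idx]
    wins = (hi > lo).sum(axis=0).astype(float)
    informative = (hi != lo).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(informative > 0, wins / np.maximum(informative, 1), 0.5)
    return score


def score_phases(nm, pairsets: list[PairSet]) -> PhaseScores:
    """Score every cell for G1, S and G2/M and call the arg-max phase.

    ``nm`` is any object with ``values`` (genes x cells), ``gene_ids`` and
    ``barcodes`` — a NormalizedMatrix or a CountMatrix (within-cell ranks
    are identical on either). Exact score ties are broken with priority
    G1 > S > G2M.
    """
    by_phase = {ps.phase: ps for ps in pairsets}
    missing = [ph for ph in PHASE_ORDER if ph not in by_phase]
    if missing:
        raise ValueError(f"no pairs supplied for phases {missing}")
    expr = nm.values
    expr = expr.toarray() if hasattr(expr, "toarray") else np.asarray(expr)
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    scores = np.vstack(
        [_phase_score(expr, gene_index, by_phase[ph]) for ph in PHASE_ORDER]
    )
    call = np.array([PHASE_ORDER[i] for i in np.argmax(scores, axis=0)])
    return PhaseScores(
        barcodes=list(nm.barcodes),
        s_g1=scores[0],
        s_s=scores[1],
        s_g2m=scores[2],
        delta_g2m_s=scores[2] - scores[1],
        phase_call=call,
    )


class PhasePairScorer(BaseEstimator, TransformerMixin):
    """Marker-pair cell-cycle scorer with an sklearn transformer surface.

    Parameters
    ----------
    pair_sets : list of PairSet
        One catalogue per phase (G1, S, G2M), already ortholog-translated.
    gene_ids : list of str
        Column labels of the matrices passed to :meth:`transform`
        (cells x genes orientation).
    """

    def __init__(self, pair_sets=None, gene_ids=None):
        self.pair_sets = pair_sets
        self.gene_ids = gene_ids

    def fit(self, X, y=None):
        if not self.pair_sets or self.gene_ids is None:
            raise ValueError("pair_sets and gene_ids are required")
        self.n_features_in_ = len(self.gene_ids)
        return self

    def transform(self, X) -> pd.DataFrame:
        from types import SimpleNamespace

        X = X.T if hasattr(X, "T") else np.asarray(X).T
        nm = SimpleNamespace(
            values=X,
            gene_ids=self.gene_ids,
            barcodes=[str(i) for i in range(X.shape[1])],
        )
        return score_phases(nm, self.pair_sets).to_frame()


def read_pair_tables(path) -> list[PairSet]:
    """Read a TSV of (phase, gene_hi, gene_lo) rows into PairSets."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["phase", "gene_hi", "gene_lo"]
    )
    return [
        PairSet(ph, list(zip(sub["gene_hi"], sub["gene_lo"])))
        for ph, sub in df.groupby("phase", sort=False)
    ]


def write_pair_tables(pairsets: list[PairSet], path) -> None:
    rows = [
        (ps.phase, hi, lo) for ps in pairsets for hi, lo in ps.pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_ortholog_table(path) -> dict[str, str]:
    """Two-column TSV source_id -> target_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["src", "dst"], dtype=str)
    return dict(zip(df["src"], df["dst"]))
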