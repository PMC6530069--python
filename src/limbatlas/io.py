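"""Count-matrix containers and 10X-style triplet (Matrix Market) I/O.

The atlas substrate is a sparse genes x cells matrix of UMI counts with a
gene table (Ensembl-style id plus optional display name) and a barcode list.
Two upstream dialects are accepted: id-only gene tables (Drop-Seq style) and
id+name tables (Cell Ranger style).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneClassMap",
    "read_count_matrix",
    "write_count_matrix",
]


class FormatError(ValueError):
    """Raised when on-disk triplet files are internally inconsistent."""


def _disambiguate(ids: list[str]) -> list[str]:
    """Suffix duplicate identifiers ``.1``, ``.2``, ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Non-negative integer counts, one row per gene, one column per cell.
    gene_ids : list of str
        Unique gene identifiers (duplicates disambiguated at read time).
    gene_names : list of str
        Display names, same length as ``gene_ids``.
    barcodes : list of str
        Unique cell barcodes, one per column.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    gene_names: list[str] = field(default=None)  # type: ignore[assignment]
    barcodes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        if self.gene_names is None:
            self.gene_names = list(self.gene_ids)
        if self.barcodes is None:
            self.barcodes = [f"cell{i}" for i in range(self.values.shape[1])]
        self._validate()

    def _validate(self):
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene table has {len(self.gene_ids)} rows but matrix has "
                f"{n_genes} gene rows"
            )
        if len(self.gene_names) != len(self.gene_ids):
            raise FormatError("gene_names length differs from gene_ids")
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"barcode list has {len(self.barcodes)} entries but matrix "
                f"has {n_cells} cell columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene_ids not unique after disambiguation")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes not unique")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValueError("negative UMI counts")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer UMI counts")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            list(self.gene_names),
            [self.barcodes[i] for i in idx],
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            [self.gene_names[i] for i in idx],
            list(self.barcodes),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.gene_names == other.gene_names
            and self.barcodes == other.barcodes
            and self.values.shape == other.values.shape
            and (self.values != other.values).nnz == 0
        )


@dataclass
class GeneClassMap:
    """gene_id -> class tag in {mitochondrial, ribosomal, other}.

    Genes absent from the lookup resolve to ``"other"``.
    """

    lookup: dict[str, str] = field(default_factory=dict)

    CLASSES = ("mitochondrial", "ribosomal", "other")

    def __post_init__(self):
        bad = {v for v in self.lookup.values()} - set(self.CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")

    def tag(self, gene_id: str) -> str:
        return self.lookup.get(gene_id, "other")

    def mask(self, gene_ids: list[str], cls: str) -> np.ndarray:
        """Boolean mask over ``gene_ids`` for class ``cls``."""
        return np.array([self.tag(g) == cls for g in gene_ids], dtype=bool)

    @classmethod
    def from_tsv(cls, path) -> "GeneClassMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "cls"])
        return cls(dict(zip(df["gene_id"].astype(str), df["cls"].astype(str))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene_id": list(self.lookup), "cls": list(self.lookup.values())}
        ).to_csv(path, sep="\t", header=False, index=False)


def read_count_matrix(matrix_path, genes_path, barcodes_path) -> CountMatrix:
    """Read a 10X-style triplet: Matrix Market counts + gene table + barcodes.

    The gene table may have one column (id) or two (id, name). Duplicate ids
    are disambiguated with ``.1``, ``.2`` suffixes in file order. If the
    triplet is stored cells x genes (detected from the gene-table length),
    it is transposed to the internal genes x cells orientation.
    """
    mat = scipy.io.mmread(matrix_path)
    try:
        genes = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        genes = pd.DataFrame({0: pd.Series([], dtype=str)})
    with open(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    gene_ids = genes.iloc[:, 0].tolist()
    gene_names = (
        genes.iloc[:, 1].tolist() if genes.shape[1] > 1 else list(gene_ids)
    )
    n_genes, n_barcodes = len(gene_ids), len(barcodes)
    if mat.shape == (n_genes, n_barcodes):
        pass
    elif mat.shape == (n_barcodes, n_genes) and n_genes != n_barcodes:
        mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} inconsistent with {n_genes} genes "
            f"and {n_barcodes} barcodes"
        )
    dense_empty = mat.shape[0] == 0 or mat.shape[1] == 0
    if not dense_empty:
        data = mat.data if sp.issparse(mat) else np.asarray(mat).ravel()
        if data.size and data.min() < 0:
            raise ValueError("negative entries in count matrix")
    mat = sp.csr_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError("non-integer entries in count matrix")
    mat.data = np.round(mat.data)
    return CountMatrix(mat, _disambiguate(gene_ids), gene_names, barcodes)


def write_count_matrix(cm: CountMatrix, dir_path) -> None:
    """Write ``matrix.mtx``, ``genes.tsv`` and ``barcodes.tsv`` under dir_path."""
    os.makedirs(dir_path, exist_ok=True)
    coo = sp.coo_matrix(cm.values)
    coo = sp.coo_matrix(
        (coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape
    )
    scipy.io.mmwrite(os.path.join(dir_path, "matrix.mtx"), coo, field="integer")
    pd.DataFrame({"id": cm.gene_ids, "name": cm.gene_names}).to_csv(
        os.path.join(dir_path, "genes.tsv"), sep="\t", header=False, index=False
    )
    with open(os.path.join(dir_path, "barcodes.tsv"), "w") as fh:
        for b in cm.barcodes:
            fh.write(b + "\n")
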