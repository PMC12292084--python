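"""Sparse gene-by-cell matrix containers shared across the pipeline.

The raw substrate of every single-cell stage is a sparse non-negative
integer matrix with genes as rows and cells as columns, mirroring the
CellRanger triplet layout (matrix.mtx + genes.tsv + barcodes.tsv).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix", "NormalizedMatrix"]


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")
    return ids


@dataclass
class CountMatrix:
    """Gene x cell matrix of non-negative integer counts.

    ``values`` is stored as CSR; rows are genes, columns are cells.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene {e.args[0]!r}") from None

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cells], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown cell {e.args[0]!r}") from None

    def subset_genes(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(self.values[idx], self.gene_ids[idx], self.cell_ids)

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(
            self.values[:, idx], self.gene_ids, self.cell_ids[idx]
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.cell_ids, other.cell_ids)
            and (self.values != other.values).nnz == 0
        )


@dataclass
class NormalizedMatrix:
    """Gene x cell real-valued matrix on a log scale (zeros preserved)."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    _dense_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("shape/id mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_dense(self) -> np.ndarray:
        if self._dense_cache is None:
            self._dense_cache = np.asarray(self.values.todense(), dtype=float)
        return self._dense_cache

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene {e.args[0]!r}") from None

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cells], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown cell {e.args[0]!r}") from None

    def subset_genes(self, mask_or_index) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_index)
        return NormalizedMatrix(self.values[idx], self.gene_ids[idx], self.cell_ids)

    def subset_cells(self, mask_or_index) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_index)
        return NormalizedMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])
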