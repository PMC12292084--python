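"""Cell/gene quality filters, log-normalization, centering, and HVG selection.

Filter order is: gene detection filter, then cell QC (mitochondrial
fraction computed on the raw, pre-filter counts), then normalization.
"Detected" means count > 0 throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .matrix import CountMatrix, NormalizedMatrix

__all__ = [
    "QCThresholds",
    "filter_genes_by_detection",
    "filter_cells_qc",
    "log_normalize",
    "center_and_clip",
    "select_hvg",
    "mito_fractions",
    "run_qc",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    min_gene_detection_fraction: float = 0.001
    max_mito_fraction: float = 0.20
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 5000
    scale_factor: float = 1e4
    clip_max: float = 10.0
    n_hvg: int = 3000

    def __post_init__(self) -> None:
        if min(
            self.min_gene_detection_fraction,
            self.max_mito_fraction,
            self.min_genes_per_cell,
            self.max_genes_per_cell,
            self.scale_factor,
            self.clip_max,
            self.n_hvg,
        ) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")


def filter_genes_by_detection(
    counts: CountMatrix, thresholds: QCThresholds = QCThresholds()
) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ceil(f * n_cells) cells."""
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    need = math.ceil(thresholds.min_gene_detection_fraction * counts.n_cells)
    detected = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    keep = detected >= need
    if not keep.any():
        raise ValueError("gene detection filter removed every gene")
    log.info("gene detection filter removed %d/%d genes", (~keep).sum(), len(keep))
    return counts.subset_genes(keep)


def mito_fractions(counts: CountMatrix, mito_gene_set) -> np.ndarray:
    """Per-cell fraction of counts coming from mitochondrial genes."""
    mito_gene_set = set(mito_gene_set)
    unknown = mito_gene_set - set(counts.gene_ids)
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {sorted(unknown)[:5]}")
    mask = np.array([g in mito_gene_set for g in counts.gene_ids])
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(counts.values[mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    return frac


def filter_cells_qc(
    counts: CountMatrix,
    mito_gene_set,
    thresholds: QCThresholds = QCThresholds(),
    mito_fraction: np.ndarray | None = None,
) -> CountMatrix:
    """Keep cells with mito fraction <= 0.20 and detected genes in [200, 5000].

    ``mito_fraction`` may be precomputed on the raw (pre-gene-filter) matrix;
    otherwise it is computed on ``counts``.
    """
    if mito_fraction is None:
        mito_fraction = mito_fractions(counts, mito_gene_set)
    mito_fraction = np.asarray(mito_fraction, dtype=float)
    if mito_fraction.shape != (counts.n_cells,):
        raise ValueError("mito_fraction length mismatch")
    n_detected = np.asarray((counts.values > 0).sum(axis=0)).ravel()
    keep = (
        (mito_fraction <= thresholds.max_mito_fraction)
        & (n_detected >= thresholds.min_genes_per_cell)
        & (n_detected <= thresholds.max_genes_per_cell)
    )
    if not keep.any():
        raise ValueError("cell QC removed every cell")
    log.info("cell QC removed %d/%d cells", (~keep).sum(), len(keep))
    return counts.subset_cells(keep)


def log_normalize(
    counts: CountMatrix, thresholds: QCThresholds = QCThresholds()
) -> NormalizedMatrix:
    """entry = ln(1 + count * scale_factor / cell_total)."""
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        raise ValueError("cell with zero total count")
    mat = sp.csr_matrix(counts.values, dtype=float)
    scaled = mat @ sp.diags(thresholds.scale_factor / totals)
    scaled = sp.csr_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(scaled, counts.gene_ids, counts.cell_ids)


def center_and_clip(
    norm: NormalizedMatrix, thresholds: QCThresholds = QCThresholds()
) -> np.ndarray:
    """Per-gene mean removal, upper clip at ``clip_max``; no variance scaling."""
    dense = norm.to_dense().copy()
    dense -= dense.mean(axis=1, keepdims=True)
    np.minimum(dense, thresholds.clip_max, out=dense)
    return dense


def select_hvg(
    norm: NormalizedMatrix, thresholds: QCThresholds = QCThresholds()
) -> list:
    """Top ``n_hvg`` genes by variance of log-normalized values.

    Ties break by gene id; if fewer genes are available all are returned.
    """
    dense = norm.to_dense()
    var = dense.var(axis=1, ddof=1) if dense.shape[1] > 1 else np.zeros(len(dense))
    order = sorted(
        range(norm.n_genes), key=lambda i: (-var[i], str(norm.gene_ids[i]))
    )
    if norm.n_genes < thresholds.n_hvg:
        log.warning(
            "only %d genes available for %d requested HVGs; returning all",
            norm.n_genes,
            thresholds.n_hvg,
        )
    return [norm.gene_ids[i] for i in order[: thresholds.n_hvg]]


def run_qc(
    raw: CountMatrix,
    mito_gene_set=None,
    thresholds: QCThresholds = QCThresholds(),
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, NormalizedMatrix]:
    """Full QC chain: gene filter -> cell QC -> log-normalize."""
    if mito_gene_set is None:
        mito_gene_set = {g for g in raw.gene_ids if str(g).startswith(mito_prefix)}
    frac = mito_fractions(raw, mito_gene_set)
    filtered = filter_genes_by_detection(raw, thresholds)
    filtered = filter_cells_qc(filtered, mito_gene_set, thresholds, mito_fraction=frac)
    # drop cells whose surviving total hit zero after the gene filter
    totals = np.asarray(filtered.values.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        filtered = filtered.subset_cells(totals > 0)
    return filtered, log_normalize(filtered, thresholds)
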