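"""Expression-derived CNV signal and malignant-cell classification.

The pipeline: dilute tumor cells with normals so putative malignant cells
stay under 20% of the mix, log2-library-normalize, filter weak genes,
z-score and clip to [-3, 3], smooth along the genome with a 100-gene
moving window per chromosome, center each cell's window vector, then
summarize per cell as the mean squared window signal and the Pearson
correlation against the mean profile of the top 5% highest-scoring cells.
A tumor cell is called malignant when ms > 0.02 or corr > 0.2 (strict).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = [
    "CNVParams",
    "GenomicGeneOrder",
    "CNVProfile",
    "assemble_reference_mix",
    "log2_library_normalize",
    "cnv_gene_filter",
    "zscore_clip",
    "windowed_cnv_signal",
    "center_cnv_profiles",
    "malignancy_scores",
    "classify_malignant",
    "run_cnv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CNVParams:
    max_putative_malignant_fraction: float = 0.20
    min_cells_per_gene: int = 10
    min_mean_log2_expr: float = 0.1
    z_clip: float = 3.0
    window_size: int = 100
    top_cell_fraction: float = 0.05
    ms_threshold: float = 0.02
    corr_threshold: float = 0.2
    scale_factor: float = 1e4
    center_mode: str = "per_cell"  # or "per_window"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 0 < self.max_putative_malignant_fraction < 1:
            raise ValueError("max_putative_malignant_fraction must be in (0, 1)")
        if not 0 < self.top_cell_fraction < 1:
            raise ValueError("top_cell_fraction must be in (0, 1)")
        if min(self.ms_threshold, self.corr_threshold, self.z_clip) <= 0:
            raise ValueError("thresholds must be positive")


_CHR_RE = re.compile(r"^(chr)?(\d+|[XYxy])$")


def chromosome_sort_key(name: str):
    """Karyotype order chr1..chr22, X, Y; unknown names sort after, by name."""
    m = _CHR_RE.match(str(name))
    if m:
        tok = m.group(2)
        if tok.isdigit():
            return (0, int(tok), "")
        return (0, 23 if tok.upper() == "X" else 24, "")
    return (1, 0, str(name))


@dataclass
class GenomicGeneOrder:
    """Genes ordered by (karyotype chromosome order, start position, id)."""

    table: pd.DataFrame  # gene, chromosome, start -- already sorted

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame) -> "GenomicGeneOrder":
        required = {"gene", "chromosome", "start"}
        if not required <= set(annotation.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if annotation["gene"].duplicated().any():
            raise ValueError("duplicate genes in annotation")
        key = annotation["chromosome"].map(chromosome_sort_key)
        order = sorted(
            range(len(annotation)),
            key=lambda i: (key.iloc[i], annotation["start"].iloc[i], str(annotation["gene"].iloc[i])),
        )
        return cls(annotation.iloc[order].reset_index(drop=True))


@dataclass
class CNVProfile:
    windows: pd.DataFrame  # chromosome, first and last gene of each window
    signal: np.ndarray  # cell x window
    cell_ids: np.ndarray
    origin: np.ndarray  # "tumor" | "normal" per cell
    ms_score: np.ndarray | None = None
    corr_score: np.ndarray | None = None
    malignant: np.ndarray | None = None
    achieved_tumor_fraction: float | None = None
    reference_profile: np.ndarray | None = field(default=None, repr=False)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "origin": self.origin,
                "ms_score": self.ms_score,
                "corr_score": self.corr_score,
                "malignant": self.malignant,
            }
        )


def assemble_reference_mix(
    tumor: CountMatrix,
    normal_pool: CountMatrix,
    params: CNVParams = CNVParams(),
) -> tuple[CountMatrix, np.ndarray]:
    """Add the fewest normals needed to keep tumor fraction <= 20%.

    Returns the combined matrix (tumor cells first) and per-cell origin
    labels.  Subsampling from the pool is seeded for reproducibility; an
    insufficient pool is used in full with a warning.
    """
    if tumor.n_cells == 0:
        raise ValueError("no tumor cells")
    if normal_pool.n_cells == 0:
        raise ValueError("empty normal pool")
    if not np.array_equal(tumor.gene_ids, normal_pool.gene_ids):
        raise ValueError("tumor and normal matrices must share the gene axis")
    t = tumor.n_cells
    f = params.max_putative_malignant_fraction
    need = math.ceil(t * (1 - f) / f)
    if need <= normal_pool.n_cells:
        rng = np.random.default_rng(params.seed)
        idx = np.sort(rng.choice(normal_pool.n_cells, size=need, replace=False))
        normals = normal_pool.subset_cells(idx)
    else:
        normals = normal_pool
        log.warning(
            "normal pool (%d) insufficient for tumor fraction <= %.2f; achieved %.3f",
            normal_pool.n_cells,
            f,
            t / (t + normal_pool.n_cells),
        )
    import scipy.sparse as sp

    combined = CountMatrix(
        sp.hstack([tumor.values, normals.values]).tocsr(),
        tumor.gene_ids,
        np.concatenate([tumor.cell_ids, normals.cell_ids]),
    )
    origin = np.array(
        ["tumor"] * tumor.n_cells + ["normal"] * normals.n_cells, dtype=object
    )
    return combined, origin


def log2_library_normalize(
    counts: CountMatrix, params: CNVParams = CNVParams()
) -> np.ndarray:
    """log2(1 + count * scale_factor / cell_total), dense gene x cell."""
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        raise ValueError("cell with zero total count")
    dense = np.asarray(counts.values.todense(), dtype=float)
    dense *= params.scale_factor / totals
    return np.log2(1.0 + dense)


def cnv_gene_filter(
    expr_log2: np.ndarray,
    counts: CountMatrix,
    params: CNVParams = CNVParams(),
) -> np.ndarray:
    """Boolean gene mask: detected in >= 10 cells and mean log2 expr >= 0.1."""
    detected = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    mean_expr = expr_log2.mean(axis=1)
    keep = (detected >= params.min_cells_per_gene) & (
        mean_expr >= params.min_mean_log2_expr
    )
    return keep


def zscore_clip(expr: np.ndarray, params: CNVParams = CNVParams()) -> np.ndarray:
    """Per-gene z-score over all cells in the mix, clipped to [-z_clip, z_clip].

    Sample (n-1) standard deviation; genes with zero variance map to 0.
    """
    mean = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, ddof=1, keepdims=True) if expr.shape[1] > 1 else np.ones_like(mean)
    z = np.zeros_like(expr, dtype=float)
    ok = (sd > 0).ravel()
    z[ok] = (expr[ok] - mean[ok]) / sd[ok]
    return np.clip(z, -params.z_clip, params.z_clip)


def windowed_cnv_signal(
    z: np.ndarray,
    gene_ids: np.ndarray,
    order: GenomicGeneOrder,
    cell_ids: np.ndarray,
    origin: np.ndarray,
    params: CNVParams = CNVParams(),
) -> CNVProfile:
    """Moving average of z-scores over ``window_size`` genes per chromosome.

    Dense sliding windows (step 1) of exactly ``window_size`` genes;
    chromosomes with fewer retained genes collapse to one whole-chromosome
    window.  Windows never cross a chromosome boundary.
    """
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in gene_ids if g not in set(order.table["gene"])]
    if missing:
        raise ValueError(f"genes missing from genomic order: {missing[:5]}")
    ordered = order.table[order.table["gene"].isin(pos)].reset_index(drop=True)
    win_rows = []
    win_cols = []
    w = params.window_size
    for chrom, sub in ordered.groupby("chromosome", sort=False):
        idx = np.array([pos[g] for g in sub["gene"]])
        n = len(idx)
        zc = z[idx]  # genes (ordered) x cells
        if n < w:
            win_cols.append(zc.mean(axis=0))
            win_rows.append((chrom, sub["gene"].iloc[0], sub["gene"].iloc[-1], n))
        else:
            csum = np.cumsum(zc, axis=0)
            csum = np.vstack([np.zeros((1, z.shape[1])), csum])
            means = (csum[w:] - csum[:-w]) / w  # (n - w + 1) x cells
            for k in range(n - w + 1):
                win_cols.append(means[k])
                win_rows.append((chrom, sub["gene"].iloc[k], sub["gene"].iloc[k + w - 1], w))
    if not win_rows:
        raise ValueError("no chromosome yields a window")
    windows = pd.DataFrame(
        win_rows, columns=["chromosome", "first_gene", "last_gene", "n_genes"]
    )
    signal = np.column_stack(win_cols)  # cell x window
    return CNVProfile(windows=windows, signal=signal, cell_ids=np.asarray(cell_ids, dtype=object), origin=np.asarray(origin, dtype=object))


def center_cnv_profiles(profile: CNVProfile, params: CNVParams = CNVParams()) -> CNVProfile:
    """Remove each cell's baseline (default) or each window's mean."""
    if params.center_mode == "per_cell":
        profile.signal = profile.signal - profile.signal.mean(axis=1, keepdims=True)
    elif params.center_mode == "per_window":
        profile.signal = profile.signal - profile.signal.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown center_mode {params.center_mode!r}")
    return profile


def malignancy_scores(
    profile: CNVProfile, params: CNVParams = CNVParams()
) -> CNVProfile:
    """Mean-square window signal and correlation with the top-5% reference."""
    sig = profile.signal
    if sig.shape[1] < 2:
        raise ValueError("need at least 2 windows for the correlation score")
    ms = (sig ** 2).mean(axis=1)
    n_top = max(2, math.ceil(params.top_cell_fraction * sig.shape[0]))
    top = np.argsort(-ms, kind="mergesort")[:n_top]
    ref = sig[top].mean(axis=0)
    ref_c = ref - ref.mean()
    ref_norm = np.sqrt((ref_c ** 2).sum())
    rows = sig - sig.mean(axis=1, keepdims=True)
    row_norm = np.sqrt((rows ** 2).sum(axis=1))
    corr = np.zeros(sig.shape[0])
    if ref_norm > 0:
        ok = row_norm > 0
        corr[ok] = rows[ok] @ ref_c / (row_norm[ok] * ref_norm)
    profile.ms_score = ms
    profile.corr_score = corr
    profile.reference_profile = ref
    return profile


def classify_malignant(
    profile: CNVProfile, params: CNVParams = CNVParams()
) -> CNVProfile:
    """malignant <=> tumor origin and (ms > 0.02 or corr > 0.2), strict."""
    if profile.ms_score is None or profile.corr_score is None:
        raise ValueError("scores not computed")
    exceeds = (profile.ms_score > params.ms_threshold) | (
        profile.corr_score > params.corr_threshold
    )
    profile.malignant = exceeds & (profile.origin == "tumor")
    return profile


def run_cnv(
    tumor: CountMatrix,
    normal_pool: CountMatrix,
    annotation: pd.DataFrame,
    params: CNVParams = CNVParams(),
) -> CNVProfile:
    """Full chain from raw counts to malignancy calls."""
    mix, origin = assemble_reference_mix(tumor, normal_pool, params)
    achieved = tumor.n_cells / mix.n_cells
    expr = log2_library_normalize(mix, params)
    keep = cnv_gene_filter(expr, mix, params)
    if not keep.any():
        raise ValueError("CNV gene filter removed every gene")
    expr = expr[keep]
    gene_ids = mix.gene_ids[keep]
    z = zscore_clip(expr, params)
    order = GenomicGeneOrder.from_annotation(annotation)
    profile = windowed_cnv_signal(z, gene_ids, order, mix.cell_ids, origin, params)
    profile.achieved_tumor_fraction = achieved
    profile = center_cnv_profiles(profile, params)
    profile = malignancy_scores(profile, params)
    return classify_malignant(profile, params)
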