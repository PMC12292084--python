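"""Consensus TF->target networks, regulon activity, and stage specificity.

A stochastic importance backend (any callable mapping an expression
matrix, a TF list and a seed to scored edges) is run many times with
consecutive seeds; edges appearing in at least ``min_support`` runs are
retained with their importance averaged over the runs in which they
appeared.  Regulon activity is the normalized area under the recovery
curve of regulon genes within the top-ranked fraction of each cell's
expression profile; specificity per stage is 1 - sqrt(JSD) between the
normalized activity distribution and the stage indicator distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .matrix import NormalizedMatrix

__all__ = [
    "ConsensusNetwork",
    "Regulon",
    "builtin_importance_backend",
    "consensus_network",
    "build_regulons",
    "regulon_activity_auc",
    "regulon_specificity",
]

log = logging.getLogger(__name__)


@dataclass
class ConsensusNetwork:
    edges: pd.DataFrame  # tf, target, support, mean_importance
    n_runs: int
    min_support: int


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("regulon with no targets")
        if self.tf in self.targets:
            raise ValueError("tf cannot be its own target")


def _as_dense(expr) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(expr, NormalizedMatrix):
        return expr.to_dense(), np.asarray(expr.gene_ids, dtype=object)
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), expr.index.to_numpy(dtype=object)
    raise TypeError("expr must be a NormalizedMatrix or a genes x cells DataFrame")


def builtin_importance_backend(
    expr,
    tf_list,
    seed: int,
    top_k_per_target: int = 10,
) -> list[tuple[str, str, float]]:
    """Bootstrap-|r| importance: top_k TFs per non-TF gene on a resample."""
    dense, gene_ids = _as_dense(expr)
    gene_set = set(gene_ids)
    tf_list = [t for t in tf_list]
    unknown = [t for t in tf_list if t not in gene_set]
    if unknown:
        raise ValueError(f"TFs absent from expression matrix: {unknown[:5]}")
    n_cells = dense.shape[1]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_cells, size=n_cells)
    if len(np.unique(idx)) < 2:
        raise ValueError("fewer than 2 distinct cells in bootstrap resample")
    sub = dense[:, idx]
    pos = {g: i for i, g in enumerate(gene_ids)}
    tf_idx = np.array([pos[t] for t in tf_list])
    tgt_mask = np.ones(len(gene_ids), dtype=bool)
    tgt_mask[tf_idx] = False
    T = sub[tf_idx]
    G = sub[tgt_mask]
    tgt_ids = gene_ids[tgt_mask]
    Tc = T - T.mean(axis=1, keepdims=True)
    Gc = G - G.mean(axis=1, keepdims=True)
    tn = np.sqrt((Tc ** 2).sum(axis=1))
    gn = np.sqrt((Gc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(Tc @ Gc.T) / np.outer(tn, gn)
    r[~np.isfinite(r)] = 0.0
    k = min(top_k_per_target, len(tf_list))
    edges: list[tuple[str, str, float]] = []
    for j, target in enumerate(tgt_ids):
        col = r[:, j]
        top = sorted(range(len(tf_list)), key=lambda i: (-col[i], str(tf_list[i])))[:k]
        for i in top:
            edges.append((tf_list[i], target, float(col[i])))
    return edges


def consensus_network(
    backend,
    expr,
    tf_list,
    n_runs: int = 100,
    min_support: int = 80,
    seed0: int = 0,
    **backend_kwargs,
) -> ConsensusNetwork:
    """Aggregate ``n_runs`` backend runs with seeds seed0 .. seed0+n_runs-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if min_support > n_runs:
        raise ValueError("min_support cannot exceed n_runs")
    support: dict[tuple[str, str], int] = {}
    imp_sum: dict[tuple[str, str], float] = {}
    for run in range(n_runs):
        try:
            edges = backend(expr, tf_list, seed0 + run, **backend_kwargs)
        except Exception as e:  # annotate which run failed
            raise RuntimeError(f"importance backend failed on run {run}: {e}") from e
        for tf, target, importance in edges:
            if tf == target:
                raise ValueError(f"self-edge {tf}->{target} from backend")
            if importance < 0:
                raise ValueError("negative importance")
            key = (tf, target)
            support[key] = support.get(key, 0) + 1
            imp_sum[key] = imp_sum.get(key, 0.0) + importance
    rows = [
        {
            "tf": tf,
            "target": target,
            "support": s,
            "mean_importance": imp_sum[(tf, target)] / s,
        }
        for (tf, target), s in support.items()
        if s >= min_support
    ]
    edges_df = pd.DataFrame(rows, columns=["tf", "target", "support", "mean_importance"])
    if len(edges_df):
        edges_df = edges_df.sort_values(["tf", "target"], kind="mergesort").reset_index(drop=True)
    return ConsensusNetwork(edges_df, n_runs, min_support)


def build_regulons(
    network: ConsensusNetwork, allowlist: dict[str, set] | None = None
) -> list[Regulon]:
    """Group consensus edges by TF, optionally pruned by an allowlist."""
    if network.edges.empty:
        raise ValueError("empty consensus network")
    regulons = []
    for tf, sub in network.edges.groupby("tf", sort=True):
        targets = set(sub["target"])
        if allowlist is not None:
            targets &= set(allowlist.get(tf, ()))
        if targets:
            regulons.append(Regulon(tf, tuple(sorted(targets))))
    return regulons


def regulon_activity_auc(
    expr,
    regulons,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery-curve AUC of regulon genes in each cell's top-ranked genes.

    Genes are ranked per cell by expression, descending, with ties broken
    by a seeded permutation fixed for the run.  With T = ceil(top_fraction
    * n_genes), AUC is the step integral of the recovery curve over ranks
    1..T, normalized so a regulon occupying the topmost ranks scores 1.
    """
    dense, gene_ids = _as_dense(expr)
    n_genes, n_cells = dense.shape
    T = math.ceil(top_fraction * n_genes)
    if top_fraction * n_genes < 1:
        raise ValueError("top_fraction * n_genes < 1")
    pos = {g: i for i, g in enumerate(gene_ids)}
    for reg in regulons:
        missing = [t for t in reg.targets if t not in pos]
        if missing:
            raise ValueError(f"regulon {reg.tf} targets absent: {missing[:5]}")
    tie_break = np.random.default_rng(seed).permutation(n_genes)
    # ranks[g, c]: 1-based rank of gene g in cell c (descending expression)
    order = np.lexsort((tie_break[:, None] * np.ones((1, n_cells)), -dense), axis=0)
    ranks = np.empty((n_genes, n_cells), dtype=np.int64)
    np.put_along_axis(ranks, order, np.arange(1, n_genes + 1)[:, None], axis=0)
    weight = np.clip(T - ranks + 1, 0, None).astype(float)  # step-curve mass
    rows = []
    for reg in regulons:
        members = np.array([pos[t] for t in reg.targets])
        m = len(members)
        max_auc = float(sum(T - k + 1 for k in range(1, min(m, T) + 1)))
        rows.append(weight[members].sum(axis=0) / max_auc)
    auc = pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, n_cells)),
        index=[reg.tf for reg in regulons],
        columns=(expr.cell_ids if isinstance(expr, NormalizedMatrix) else expr.columns),
    )
    return auc.clip(0.0, 1.0)


def regulon_specificity(activity: pd.DataFrame, stage_labels) -> pd.DataFrame:
    """rss[r, s] = 1 - sqrt(JSD_base2(normalized activity, stage indicator))."""
    stage_labels = np.asarray(list(stage_labels), dtype=object)
    if len(stage_labels) != activity.shape[1]:
        raise ValueError("one stage label per cell required")
    stages = list(dict.fromkeys(stage_labels))
    out = pd.DataFrame(0.0, index=activity.index, columns=stages)
    for r in activity.index:
        act = activity.loc[r].to_numpy(dtype=float)
        total = act.sum()
        if total <= 0:
            log.warning("regulon %s has all-zero activity; rss set to 0", r)
            continue
        p = act / total
        for s in stages:
            ind = (stage_labels == s).astype(float)
            ind /= ind.sum()
            out.loc[r, s] = 1.0 - float(jensenshannon(p, ind, base=2))
    return out.clip(0.0, 1.0)
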