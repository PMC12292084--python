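"""Cluster-vs-stage homogeneity metrics: purity and entropy.

Purity of a clustering is sum_i max_j n_ij / N where n_ij counts cells of
stage j in cluster i.  Entropy is computed per cluster in bits over the
stage proportions; the printed entropy in bits is unbounded for more than
two categories, so a normalized variant (divided by log2 of the number of
stage categories) is reported alongside to keep the [0, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StageContingency",
    "HomogeneityReport",
    "stage_contingency",
    "purity",
    "cluster_entropy",
    "homogeneity_report",
]


@dataclass
class StageContingency:
    """Cluster x stage co-occurrence counts with marginals."""

    counts: pd.DataFrame  # rows: clusters, columns: stages

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if arr.sum() <= 0:
            raise ValueError("empty contingency table")

    @property
    def N(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def c_i(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def t_j(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def C(self) -> int:
        return self.counts.shape[1]


@dataclass
class HomogeneityReport:
    overall_purity: float
    per_cluster_purity: pd.Series
    per_cluster_entropy: pd.Series  # normalized to [0, 1]
    raw_entropy: pd.Series  # bits


def stage_contingency(cluster_labels, stage_labels) -> StageContingency:
    """Cluster x stage count table; category order is first appearance."""
    cluster_labels = list(cluster_labels)
    stage_labels = list(stage_labels)
    if len(cluster_labels) != len(stage_labels):
        raise ValueError(
            f"label length mismatch: {len(cluster_labels)} vs {len(stage_labels)}"
        )
    if not cluster_labels:
        raise ValueError("empty label vectors")
    clusters = list(dict.fromkeys(cluster_labels))
    stages = list(dict.fromkeys(stage_labels))
    table = pd.DataFrame(0, index=clusters, columns=stages, dtype=int)
    for c, s in zip(cluster_labels, stage_labels):
        table.loc[c, s] += 1
    return StageContingency(table)


def purity(table: StageContingency) -> tuple[float, pd.Series]:
    """Overall purity and per-cluster dominant-stage proportion."""
    arr = table.counts.to_numpy(dtype=float)
    row_max = arr.max(axis=1)
    overall = float(row_max.sum() / table.N)
    per_cluster = pd.Series(
        row_max / arr.sum(axis=1), index=table.counts.index, name="purity"
    )
    return overall, per_cluster


def cluster_entropy(table: StageContingency) -> tuple[pd.Series, pd.Series]:
    """Per-cluster entropy: (normalized in [0, 1], raw bits). 0*log0 := 0."""
    arr = table.counts.to_numpy(dtype=float)
    p = arr / arr.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    raw = pd.Series(-terms.sum(axis=1), index=table.counts.index, name="entropy_bits")
    denom = np.log2(table.C) if table.C > 1 else 1.0
    normalized = (raw / denom if table.C > 1 else raw * 0.0).rename("entropy")
    return normalized, raw


def homogeneity_report(table: StageContingency) -> HomogeneityReport:
    overall, per_cluster = purity(table)
    normalized, raw = cluster_entropy(table)
    return HomogeneityReport(overall, per_cluster, normalized, raw)
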