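"""Bulk-cohort stratification: Ward.D hierarchical subgroups, Kaplan-Meier
survival curves, and the k-sample log-rank test.

The agglomeration applies the Lance-Williams Ward update to the raw
(unsquared) Euclidean distance matrix, matching R's hclust "ward.D"
rather than "ward.D2"; both survival procedures are implemented directly
from the product-limit and observed-minus-expected definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

__all__ = [
    "SubgroupAssignment",
    "LogRankResult",
    "ward_linkage_labels",
    "hierarchical_subgroups",
    "km_estimate",
    "logrank_test",
]

log = logging.getLogger(__name__)


@dataclass
class SubgroupAssignment:
    sample_labels: pd.Series  # sample -> subgroup label (1..k, 1 = highest mean expression)
    gene_labels: pd.Series  # gene -> gene-cluster label


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def ward_linkage_labels(dist: np.ndarray, k: int) -> np.ndarray:
    """Cut a Ward.D agglomeration of a square distance matrix at k clusters.

    Lance-Williams update on the distances as given (no squaring):
        d(i+j, h) = ((n_i+n_h) d(i,h) + (n_j+n_h) d(j,h) - n_h d(i,j)) / (n_i+n_j+n_h)
    Ties in the minimum merge distance break on the smallest index pair.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("square distance matrix required")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    size = np.ones(n)
    active = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    while len(active) > k:
        best = (np.inf, None)
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1 :]:
                if d[i, j] < best[0] - 1e-12:
                    best = (d[i, j], (i, j))
        i, j = best[1]
        ni, nj = size[i], size[j]
        for h in active:
            if h in (i, j):
                continue
            nh = size[h]
            d_new = ((ni + nh) * d[i, h] + (nj + nh) * d[j, h] - nh * d[i, j]) / (
                ni + nj + nh
            )
            d[i, h] = d[h, i] = d_new
        size[i] = ni + nj
        members[i] = members[i] + members[j]
        active.remove(j)
        d[j, :] = d[:, j] = np.inf
    labels = np.empty(n, dtype=int)
    for lab, root in enumerate(active):
        labels[members[root]] = lab
    return labels


def hierarchical_subgroups(
    expr: pd.DataFrame,
    marker_genes,
    k_samples: int = 3,
    k_genes: int = 4,
) -> SubgroupAssignment:
    """Ward.D/Euclidean clustering of samples (and genes) on marker expression.

    ``expr`` is samples x genes on the log2(x+1) scale.  Subgroup labels are
    1..k ordered by decreasing mean expression sum for determinism; missing
    marker genes are dropped with a warning.
    """
    markers = [g for g in marker_genes if g in expr.columns]
    missing = [g for g in marker_genes if g not in expr.columns]
    if missing:
        log.warning("%d marker genes absent from expression matrix", len(missing))
    if not markers:
        raise ValueError("no marker genes present in expression matrix")
    sub = expr.loc[:, markers]
    if k_samples > sub.shape[0]:
        raise ValueError("k_samples exceeds sample count")
    if k_genes > sub.shape[1]:
        raise ValueError("k_genes exceeds marker count")
    s_labels = ward_linkage_labels(squareform(pdist(sub.to_numpy())), k_samples)
    g_labels = ward_linkage_labels(squareform(pdist(sub.to_numpy().T)), k_genes)
    # relabel sample subgroups by decreasing mean expression sum
    sums = sub.sum(axis=1).to_numpy()
    group_means = {
        lab: sums[s_labels == lab].mean() for lab in np.unique(s_labels)
    }
    rank_of = {
        lab: r + 1
        for r, lab in enumerate(
            sorted(group_means, key=lambda L: -group_means[L])
        )
    }
    sample_labels = pd.Series(
        [rank_of[L] for L in s_labels], index=sub.index, name="subgroup"
    )
    gene_sums = sub.sum(axis=0).to_numpy()
    g_means = {lab: gene_sums[g_labels == lab].mean() for lab in np.unique(g_labels)}
    g_rank = {
        lab: r + 1
        for r, lab in enumerate(sorted(g_means, key=lambda L: -g_means[L]))
    }
    gene_labels = pd.Series(
        [g_rank[L] for L in g_labels], index=markers, name="gene_cluster"
    )
    return SubgroupAssignment(sample_labels, gene_labels)


def km_estimate(records: pd.DataFrame) -> dict:
    """Product-limit survival curve per subgroup.

    ``records`` needs columns time (> 0), event (0/1) and subgroup; returns
    a mapping subgroup -> DataFrame(time, n_risk, n_event, n_censor,
    survival), one row per distinct observed time.
    """
    _check_records(records)
    out = {}
    for label, sub in records.groupby("subgroup", sort=True):
        times = sub["time"].to_numpy(dtype=float)
        events = sub["event"].to_numpy(dtype=int)
        distinct = np.unique(times)
        n_risk = len(times)
        s = 1.0
        rows = []
        for t in distinct:
            here = times == t
            d = int(events[here].sum())
            c = int(here.sum() - d)
            if d > 0:
                s *= 1.0 - d / n_risk
            rows.append((t, n_risk, d, c, s))
            n_risk -= int(here.sum())
        out[label] = pd.DataFrame(
            rows, columns=["time", "n_risk", "n_event", "n_censor", "survival"]
        )
    return out


def logrank_test(records: pd.DataFrame) -> LogRankResult:
    """k-sample log-rank via the observed-minus-expected chi-square form."""
    _check_records(records)
    groups = sorted(records["subgroup"].unique(), key=str)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two subgroups")
    if records["event"].sum() == 0:
        raise ValueError("no events observed")
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=int)
    glabels = records["subgroup"].to_numpy()
    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(((times == t) & (events == 1)).sum())
        n_g = np.array([(at_risk & (glabels == g)).sum() for g in groups], dtype=float)
        o_g = np.array(
            [((times == t) & (events == 1) & (glabels == g)).sum() for g in groups],
            dtype=float,
        )
        O += o_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, k - 1))
    return LogRankResult(chi2=stat, df=k - 1, p=max(min(p, 1.0), np.finfo(float).tiny))


def _check_records(records: pd.DataFrame) -> None:
    required = {"time", "event", "subgroup"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    t = records["time"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and positive")
    if not set(np.unique(records["event"])) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
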