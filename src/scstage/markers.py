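"""Late-vs-early marker genes by Wilcoxon rank-sum with BH correction.

The fold-change convention works on expm1 of the log-normalized values
with a pseudocount of 1; min.pct keeps a gene when the expression
fraction of *either* group reaches the threshold.  P-values come from
the tie-corrected normal approximation with continuity correction, or
from exact enumeration of the rank-sum distribution when both groups
have at most ``exact_max`` cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .matrix import NormalizedMatrix

__all__ = [
    "DEGThresholds",
    "wilcoxon_rank_sum",
    "exact_rank_sum_p",
    "wilcoxon_de",
    "bh_adjust",
    "filter_markers",
]


@dataclass(frozen=True)
class DEGThresholds:
    min_pct: float = 0.25
    alpha: float = 0.01
    min_log2fc: float = 1.0
    exact_max: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.min_pct <= 1:
            raise ValueError("min_pct must be in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of group assignments.

    Handles ties through midranks; p = min(1, 2 * min(lower, upper tail)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # midrank
        i = j + 1
    n1 = len(x)
    obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n1)]
    )
    eps = 1e-9
    lower = np.mean(sums <= obs + eps)
    upper = np.mean(sums >= obs - eps)
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray, exact_max: int = 8) -> float:
    """Two-sided Mann-Whitney p; exact when both groups are small."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    if len(x) <= exact_max and len(y) <= exact_max:
        return exact_rank_sum_p(x, y)
    return _approx_rank_sum_p(x[None, :], y[None, :])[0]


def _approx_rank_sum_p(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal approximation over rows (genes)."""
    from scipy.stats import norm, rankdata

    n1, n2 = X.shape[1], Y.shape[1]
    n = n1 + n2
    pooled = np.concatenate([X, Y], axis=1)
    ranks = rankdata(pooled, axis=1)
    R1 = ranks[:, :n1].sum(axis=1)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum over tie groups of (t^3 - t)
    srt = np.sort(pooled, axis=1)
    same = np.concatenate(
        [np.zeros((pooled.shape[0], 1), bool), srt[:, 1:] == srt[:, :-1]], axis=1
    )
    tie_sum = np.empty(pooled.shape[0])
    for i in range(pooled.shape[0]):  # per-row run-length of ties
        runs = np.diff(
            np.flatnonzero(np.concatenate([[True], ~same[i, 1:], [True]]))
        )
        tie_sum[i] = np.sum(runs.astype(float) ** 3 - runs)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    z = np.zeros_like(U)
    ok = var > 0
    z[ok] = (np.abs(U[ok] - mu) - 0.5) / np.sqrt(var[ok])
    z = np.clip(z, 0, None)
    p = 2.0 * norm.sf(z)
    p[~ok] = 1.0
    return np.minimum(p, 1.0)


def wilcoxon_de(
    norm: NormalizedMatrix,
    group_late,
    group_early,
    thresholds: DEGThresholds = DEGThresholds(),
) -> pd.DataFrame:
    """Per-gene late-vs-early test.

    Returns a frame with gene, log2fc, pct_late, pct_early, p, p_adj for
    genes passing the min.pct screen; BH is applied over tested genes only.
    """
    late_idx = norm.cell_index(group_late) if _needs_lookup(group_late) else np.asarray(group_late)
    early_idx = norm.cell_index(group_early) if _needs_lookup(group_early) else np.asarray(group_early)
    if len(late_idx) == 0 or len(early_idx) == 0:
        raise ValueError("empty group")
    if set(late_idx.tolist()) & set(early_idx.tolist()):
        raise ValueError("groups overlap")
    dense = norm.to_dense()
    X = dense[:, late_idx]
    Y = dense[:, early_idx]
    pct_late = (X > 0).mean(axis=1)
    pct_early = (Y > 0).mean(axis=1)
    tested = np.maximum(pct_late, pct_early) >= thresholds.min_pct
    Xt, Yt = X[tested], Y[tested]
    with np.errstate(over="ignore"):
        mean_late = np.expm1(Xt).mean(axis=1)
        mean_early = np.expm1(Yt).mean(axis=1)
    log2fc = np.log2((mean_late + 1.0) / (mean_early + 1.0))
    if X.shape[1] <= thresholds.exact_max and Y.shape[1] <= thresholds.exact_max:
        p = np.array([exact_rank_sum_p(x, y) for x, y in zip(Xt, Yt)])
    else:
        p = _approx_rank_sum_p(Xt, Yt)
    out = pd.DataFrame(
        {
            "gene": norm.gene_ids[tested],
            "log2fc": log2fc,
            "pct_late": pct_late[tested],
            "pct_early": pct_early[tested],
            "p": p,
        }
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.array([])
    return out


def _needs_lookup(group) -> bool:
    arr = np.asarray(group)
    return arr.dtype.kind not in "iub"


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns values in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def filter_markers(
    records: pd.DataFrame,
    thresholds: DEGThresholds = DEGThresholds(),
    direction: str = "up",
) -> pd.DataFrame:
    """Retain significant markers; sort by p_adj, then |log2fc|, then gene."""
    if direction == "up":
        keep = (records["p_adj"] < thresholds.alpha) & (
            records["log2fc"] > thresholds.min_log2fc
        )
    elif direction == "down":
        keep = (records["p_adj"] < thresholds.alpha) & (
            records["log2fc"] < -thresholds.min_log2fc
        )
    else:
        raise ValueError(f"unknown direction {direction!r}")
    out = records.loc[keep].copy()
    out["_abs"] = out["log2fc"].abs()
    out = out.sort_values(
        ["p_adj", "_abs", "gene"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_abs")
    return out.reset_index(drop=True)
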