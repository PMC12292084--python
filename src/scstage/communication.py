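"""Ligand-receptor communication scoring with permutation significance.

Strength between an ordered (sender, receiver) cell-type pair for one
interaction is the product of the sender's mean ligand expression and the
receiver's mean receptor expression (expm1 of the log-normalized values;
multi-subunit complexes aggregate by geometric mean, so any absent
subunit zeroes the complex).  Significance comes from globally permuting
cell-type labels; p = (1 + #{permuted >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import NormalizedMatrix

__all__ = [
    "LRDatabase",
    "ConditionNetwork",
    "group_mean_expression",
    "interaction_scores",
    "permutation_pvalues",
    "score_condition",
    "network_summary",
    "differential_network",
    "pathway_flow",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRInteraction:
    name: str
    ligand_genes: tuple[str, ...]
    receptor_genes: tuple[str, ...]
    pathway: str

    def __post_init__(self) -> None:
        if not self.ligand_genes or not self.receptor_genes:
            raise ValueError(f"interaction {self.name!r} with empty subunit set")


@dataclass
class LRDatabase:
    interactions: tuple[LRInteraction, ...]

    def __post_init__(self) -> None:
        names = [i.name for i in self.interactions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate interaction names")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LRDatabase":
        required = {"name", "ligand_genes", "receptor_genes", "pathway"}
        if not required <= set(df.columns):
            raise ValueError(f"LR database needs columns {sorted(required)}")
        inter = tuple(
            LRInteraction(
                name=row["name"],
                ligand_genes=tuple(str(row["ligand_genes"]).split(",")),
                receptor_genes=tuple(str(row["receptor_genes"]).split(",")),
                pathway=row["pathway"],
            )
            for _, row in df.iterrows()
        )
        return cls(inter)

    def pathways(self) -> list[str]:
        return list(dict.fromkeys(i.pathway for i in self.interactions))


@dataclass
class ConditionNetwork:
    counts: pd.DataFrame  # sender x receiver significant-interaction counts
    strength: pd.DataFrame  # sender x receiver summed significant strengths


def _expm1_dense(norm: NormalizedMatrix) -> np.ndarray:
    return np.expm1(norm.to_dense())


def group_mean_expression(norm: NormalizedMatrix, cell_types, gene_set) -> pd.Series:
    """Geometric mean over subunit genes of the per-type mean expression."""
    labels = np.asarray(list(cell_types), dtype=object)
    if len(labels) != norm.n_cells:
        raise ValueError("one cell-type label per cell required")
    genes = list(gene_set)
    idx = norm.gene_index(genes)
    vals = np.expm1(norm.to_dense()[idx])
    types = list(dict.fromkeys(labels))
    out = {}
    for t in types:
        mask = labels == t
        means = vals[:, mask].mean(axis=1)
        out[t] = float(np.prod(means) ** (1.0 / len(genes)))
    return pd.Series(out, name="mean_expression")


def _type_mean_matrix(vals: np.ndarray, labels: np.ndarray, types: list) -> np.ndarray:
    """genes x types matrix of arithmetic mean expression per cell type."""
    M = np.empty((vals.shape[0], len(types)))
    for j, t in enumerate(types):
        mask = labels == t
        if not mask.any():
            raise ValueError(f"unknown or empty cell type {t!r}")
        M[:, j] = vals[:, mask].mean(axis=1)
    return M


def _strength_tensor(
    vals: np.ndarray,
    labels: np.ndarray,
    types: list,
    db: LRDatabase,
    gene_pos: dict,
) -> np.ndarray:
    """(interaction, sender, receiver) strengths: L_mean x R_mean."""
    M = _type_mean_matrix(vals, labels, types)
    n_int = len(db.interactions)
    out = np.empty((n_int, len(types), len(types)))
    for i, inter in enumerate(db.interactions):
        lig = M[[gene_pos[g] for g in inter.ligand_genes]]
        rec = M[[gene_pos[g] for g in inter.receptor_genes]]
        L = np.prod(lig, axis=0) ** (1.0 / len(inter.ligand_genes))
        R = np.prod(rec, axis=0) ** (1.0 / len(inter.receptor_genes))
        out[i] = np.outer(L, R)
    return out


def _prepare(norm: NormalizedMatrix, labels, db: LRDatabase):
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != norm.n_cells:
        raise ValueError("one cell-type label per cell required")
    types = sorted(set(labels), key=str)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    gene_set = set(norm.gene_ids)
    usable = []
    for inter in db.interactions:
        missing = [
            g
            for g in (*inter.ligand_genes, *inter.receptor_genes)
            if g not in gene_set
        ]
        if missing:
            log.warning(
                "interaction %s dropped: genes %s absent", inter.name, missing[:3]
            )
        else:
            usable.append(inter)
    if not usable:
        raise ValueError("no database interaction has all genes in the matrix")
    db_use = LRDatabase(tuple(usable))
    genes_needed = sorted(
        {g for i in usable for g in (*i.ligand_genes, *i.receptor_genes)}
    )
    idx = norm.gene_index(genes_needed)
    vals = np.expm1(np.asarray(norm.values[idx].todense(), dtype=float))
    gene_pos = {g: i for i, g in enumerate(genes_needed)}
    return vals, labels, types, db_use, gene_pos


def interaction_scores(
    norm: NormalizedMatrix, labels, db: LRDatabase
) -> pd.DataFrame:
    """Mass-action strengths for every ordered type pair and interaction."""
    vals, labels, types, db_use, gene_pos = _prepare(norm, labels, db)
    tensor = _strength_tensor(vals, labels, types, db_use, gene_pos)
    rows = []
    for i, inter in enumerate(db_use.interactions):
        for a, sender in enumerate(types):
            for b, receiver in enumerate(types):
                rows.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "interaction": inter.name,
                        "pathway": inter.pathway,
                        "strength": tensor[i, a, b],
                    }
                )
    return pd.DataFrame(rows)


def permutation_pvalues(
    norm: NormalizedMatrix,
    labels,
    db: LRDatabase,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach one-sided permutation p-values to the interaction scores."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    vals, labels, types, db_use, gene_pos = _prepare(norm, labels, db)
    observed = _strength_tensor(vals, labels, types, db_use, gene_pos)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        t = _strength_tensor(vals, perm, types, db_use, gene_pos)
        exceed += t >= observed - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    rows = []
    for i, inter in enumerate(db_use.interactions):
        for a, sender in enumerate(types):
            for b, receiver in enumerate(types):
                rows.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "interaction": inter.name,
                        "pathway": inter.pathway,
                        "strength": observed[i, a, b],
                        "p": pvals[i, a, b],
                    }
                )
    return pd.DataFrame(rows)


def score_condition(
    norm: NormalizedMatrix,
    labels,
    db: LRDatabase,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Scores + permutation p for one condition (alias with clearer intent)."""
    return permutation_pvalues(norm, labels, db, n_perm=n_perm, seed=seed)


def network_summary(scores: pd.DataFrame, alpha: float = 0.05) -> ConditionNetwork:
    """Per sender->receiver: count and summed strength of significant triples."""
    if "p" not in scores.columns:
        raise ValueError("scores must carry permutation p-values")
    types = sorted(set(scores["sender"]) | set(scores["receiver"]), key=str)
    counts = pd.DataFrame(0, index=types, columns=types, dtype=int)
    strength = pd.DataFrame(0.0, index=types, columns=types)
    sig = scores[scores["p"] < alpha]
    for (s, r), sub in sig.groupby(["sender", "receiver"]):
        counts.loc[s, r] = len(sub)
        strength.loc[s, r] = sub["strength"].sum()
    return ConditionNetwork(counts, strength)


def differential_network(
    early: ConditionNetwork, late: ConditionNetwork
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Element-wise late - early for counts and strengths."""
    if list(early.counts.index) != list(late.counts.index) or list(
        early.counts.columns
    ) != list(late.counts.columns):
        raise ValueError("cell-type sets differ between conditions")
    return (
        late.counts - early.counts,
        late.strength - early.strength,
    )


def pathway_flow(
    scores_early: pd.DataFrame,
    scores_late: pd.DataFrame,
    db: LRDatabase,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Summed significant strength per pathway and condition + exclusivity."""
    rows = []
    for pathway in db.pathways():
        names = [i.name for i in db.interactions if i.pathway == pathway]
        if not names:
            raise ValueError(f"pathway {pathway!r} has no interactions")
        flows = {}
        for cond, scores in (("early", scores_early), ("late", scores_late)):
            sub = scores[
                (scores["interaction"].isin(names)) & (scores["p"] < alpha)
            ]
            flows[cond] = float(sub["strength"].sum())
        if flows["late"] > 0 and flows["early"] == 0:
            exclusive = "late"
        elif flows["early"] > 0 and flows["late"] == 0:
            exclusive = "early"
        else:
            exclusive = "none"
        rows.append(
            {
                "pathway": pathway,
                "flow_early": flows["early"],
                "flow_late": flows["late"],
                "exclusive": exclusive,
            }
        )
    return pd.DataFrame(rows)
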