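"""Synthetic single-cell and bulk-cohort data with full ground truth.

Counts follow a negative-binomial law whose mean factorizes as

    mu[g, c] = baseline[g] * size_factor[c] * dosage[g, c]
               * 2^lfc (stage-effect genes in late-stage target cells)
               * regulon co-activation (latent TF activity)
               * ligand/receptor condition amplitudes

so each downstream stage (CNV scoring, DE testing, network inference,
communication scoring) has a planted, recoverable signal.  One RNG stream
per logical block is derived from the master seed, so adding a block does
not perturb the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .io import read_triplet, read_tsv, write_triplet, write_tsv
from .matrix import CountMatrix

__all__ = [
    "CNVEvent",
    "StageEffect",
    "PlantedRegulon",
    "PlantedLRPair",
    "BulkGroup",
    "BulkConfig",
    "SimConfig",
    "SyntheticDataset",
    "SimTruth",
    "generate_single_cell_dataset",
    "generate_bulk_survival_cohort",
    "write_dataset",
    "read_dataset",
]

# fixed stream indices: adding a new block must append, never reorder
_STREAMS = {
    "genes": 0,
    "baseline": 1,
    "cells": 2,
    "counts": 3,
    "regulon": 4,
    "bulk_expr": 5,
    "bulk_noise": 6,
    "survival": 7,
}


def _rng(seed: int, block: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[block])))


@dataclass(frozen=True)
class CNVEvent:
    """Segmental dosage event on a gene-index span of one chromosome.

    ``start``/``end`` are 0-based, half-open indices into the chromosome's
    gene list.  ``copy_ratio`` acts multiplicatively on the NB mean.
    Affected cells are those matching ``cell_type`` and ``stage``
    (``None`` matches everything).
    """

    chromosome: str
    start: int
    end: int
    copy_ratio: float
    cell_type: str | None = None
    stage: str | None = None


@dataclass(frozen=True)
class StageEffect:
    """Late-vs-early log2 expression effect on one gene."""

    gene: str
    log2fc: float


@dataclass(frozen=True)
class PlantedRegulon:
    tf: str
    targets: tuple[str, ...]
    strength: float = 0.8  # co-expression strength in [0, 1]


@dataclass(frozen=True)
class PlantedLRPair:
    """Condition-specific ligand/receptor signal between two cell types."""

    ligand: str
    receptor: str
    pathway: str
    sender: str
    receiver: str
    amp_early: float = 0.0
    amp_late: float = 0.0
    receptor_bias: float = 3.0  # receptor enrichment in receiver cells


@dataclass(frozen=True)
class BulkGroup:
    label: str
    n_samples: int
    hazard: float
    marker_shift: Mapping[str, float] = field(default_factory=dict)


@dataclass
class BulkConfig:
    genes: tuple[str, ...]
    groups: tuple[BulkGroup, ...]
    noise_sd: float = 0.5
    censor_window: tuple[float, float] | None = None


@dataclass
class SimConfig:
    n_genes: int
    chromosomes: tuple[tuple[str, int], ...]
    n_cells_per_group: Mapping[tuple[str, str], int]
    cnv_events: tuple[CNVEvent, ...] = ()
    de_genes: tuple[StageEffect, ...] = ()
    regulons_true: tuple[PlantedRegulon, ...] = ()
    lr_pairs_true: tuple[PlantedLRPair, ...] = ()
    libsize_lognormal: tuple[float, float] = (0.0, 0.25)
    baseline_nb: tuple[float, float, float] = (0.0, 0.8, 2.0)  # (log-mean, log-sd, dispersion)
    mito_fraction: float = 0.0
    mito_prefix: str = "MT-"
    late_stages: tuple[str, ...] = ("IV",)
    de_cell_type: str = "epithelial"
    bulk: BulkConfig | None = None
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if sum(n for _, n in self.chromosomes) != self.n_genes:
            raise ValueError("chromosome gene counts must sum to n_genes")
        if not self.n_cells_per_group:
            raise ValueError("no cell groups declared")
        for key, n in self.n_cells_per_group.items():
            if n <= 0:
                raise ValueError(f"group {key} declared with non-positive count")
        chrom_sizes = dict(self.chromosomes)
        for ev in self.cnv_events:
            if ev.copy_ratio <= 0:
                raise ValueError("copy_ratio must be > 0")
            if ev.chromosome not in chrom_sizes:
                raise ValueError(f"unknown chromosome {ev.chromosome!r}")
            if not (0 <= ev.start < ev.end <= chrom_sizes[ev.chromosome]):
                raise ValueError(
                    f"event span [{ev.start}, {ev.end}) outside chromosome "
                    f"{ev.chromosome} of size {chrom_sizes[ev.chromosome]}"
                )
        if not 0 <= self.mito_fraction < 1:
            raise ValueError("mito_fraction must be in [0, 1)")
        if self.baseline_nb[2] <= 0:
            raise ValueError("NB dispersion must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["chromosomes"] = tuple((str(c), int(n)) for c, n in d["chromosomes"])
        d["n_cells_per_group"] = {
            (str(t), str(s)): int(n)
            for (t, s), n in (
                d["n_cells_per_group"].items()
                if isinstance(d["n_cells_per_group"], dict)
                else (((t, s), n) for t, s, n in d["n_cells_per_group"])
            )
        }
        d["cnv_events"] = tuple(CNVEvent(**e) for e in d.get("cnv_events", ()))
        d["de_genes"] = tuple(StageEffect(**e) for e in d.get("de_genes", ()))
        d["regulons_true"] = tuple(
            PlantedRegulon(tf=r["tf"], targets=tuple(r["targets"]), strength=r.get("strength", 0.8))
            for r in d.get("regulons_true", ())
        )
        d["lr_pairs_true"] = tuple(PlantedLRPair(**p) for p in d.get("lr_pairs_true", ()))
        if "libsize_lognormal" in d:
            d["libsize_lognormal"] = tuple(d["libsize_lognormal"])
        if "baseline_nb" in d:
            d["baseline_nb"] = tuple(d["baseline_nb"])
        if "late_stages" in d:
            d["late_stages"] = tuple(d["late_stages"])
        if d.get("bulk") is not None:
            b = d["bulk"]
            d["bulk"] = BulkConfig(
                genes=tuple(b["genes"]),
                groups=tuple(
                    BulkGroup(
                        label=g["label"],
                        n_samples=int(g["n_samples"]),
                        hazard=float(g["hazard"]),
                        marker_shift=dict(g.get("marker_shift", {})),
                    )
                    for g in b["groups"]
                ),
                noise_sd=float(b.get("noise_sd", 0.5)),
                censor_window=(
                    tuple(b["censor_window"]) if b.get("censor_window") else None
                ),
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimTruth:
    malignant: pd.Series  # cell id -> bool
    dosage: np.ndarray  # gene x cell multiplicative CNV dosage
    de_genes: pd.DataFrame  # gene, log2fc
    regulon_edges: pd.DataFrame  # tf, target, strength
    lr_amplitudes: pd.DataFrame  # ligand, receptor, pathway, sender, receiver, amp_early, amp_late


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    gene_annotation: pd.DataFrame  # gene, chromosome, start
    cell_metadata: pd.DataFrame  # cell_id, sample, tissue, stage, cell_type
    truth: SimTruth

    def __post_init__(self) -> None:
        if list(self.cell_metadata["cell_id"]) != list(self.counts.cell_ids):
            raise ValueError("cell metadata does not match count matrix cells")
        if list(self.gene_annotation["gene"]) != list(self.counts.gene_ids):
            raise ValueError("gene annotation does not match count matrix genes")


def _condition(stage: str, late_stages: Sequence[str]) -> str:
    return "late" if stage in late_stages else "early"


def generate_single_cell_dataset(config: SimConfig) -> SyntheticDataset:
    """Draw a gene x cell NB count matrix with planted CNV/DE/regulon/LR truth."""
    config.validate()

    # --- genes ---------------------------------------------------------
    rng_genes = _rng(config.seed, "genes")
    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)], dtype=object)
    chrom_of = np.empty(config.n_genes, dtype=object)
    start_of = np.empty(config.n_genes, dtype=np.int64)
    chrom_offset: dict[str, int] = {}
    pos = 0
    for name, n in config.chromosomes:
        chrom_offset[name] = pos
        chrom_of[pos : pos + n] = name
        start_of[pos : pos + n] = 1 + 1000 * np.arange(n)
        pos += n
    n_mito = int(math.ceil(config.mito_fraction * config.n_genes))
    if n_mito:
        # genes referenced by planted structures keep their ids
        protected = {e.gene for e in config.de_genes}
        for reg in config.regulons_true:
            protected.update((reg.tf, *reg.targets))
        for pair in config.lr_pairs_true:
            protected.update((pair.ligand, pair.receptor))
        eligible = np.array(
            [i for i, g in enumerate(gene_ids) if g not in protected]
        )
        if n_mito > len(eligible):
            raise ValueError("mito_fraction too high for unreferenced gene pool")
        mito_idx = rng_genes.choice(eligible, size=n_mito, replace=False)
        for i in mito_idx:
            gene_ids[i] = config.mito_prefix + gene_ids[i]
    annotation = pd.DataFrame(
        {"gene": gene_ids, "chromosome": chrom_of, "start": start_of}
    )
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # --- cells ---------------------------------------------------------
    groups = list(config.n_cells_per_group.items())
    cell_type = []
    stage = []
    for (ctype, st), n in groups:
        cell_type += [ctype] * n
        stage += [st] * n
    n_cells = len(cell_type)
    cell_type = np.array(cell_type, dtype=object)
    stage = np.array(stage, dtype=object)
    tissue = np.where(stage == "normal", "normal", "tumor").astype(object)
    cell_ids = np.array([f"C{i:06d}" for i in range(n_cells)], dtype=object)
    sample = np.array([f"S_{s}" for s in stage], dtype=object)
    metadata = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample": sample,
            "tissue": tissue,
            "stage": stage,
            "cell_type": cell_type,
        }
    )
    condition = np.array(
        [_condition(s, config.late_stages) for s in stage], dtype=object
    )

    # --- mean structure ------------------------------------------------
    mean_log, sd_log, dispersion = config.baseline_nb
    baseline = _rng(config.seed, "baseline").lognormal(
        mean_log, sd_log, size=config.n_genes
    )
    size_factor = _rng(config.seed, "cells").lognormal(
        config.libsize_lognormal[0], config.libsize_lognormal[1], size=n_cells
    )
    mu = np.outer(baseline, size_factor)

    # CNV dosage
    dosage = np.ones((config.n_genes, n_cells))
    for ev in config.cnv_events:
        cells = np.ones(n_cells, dtype=bool)
        if ev.cell_type is not None:
            cells &= cell_type == ev.cell_type
        if ev.stage is not None:
            cells &= stage == ev.stage
        g0 = chrom_offset[ev.chromosome] + ev.start
        g1 = chrom_offset[ev.chromosome] + ev.end
        block = dosage[g0:g1][:, cells]
        if block.size and np.any(block != 1.0):
            raise ValueError(
                f"overlapping cnv_events on chromosome {ev.chromosome}"
            )
        dosage[g0:g1, cells] = ev.copy_ratio
    mu *= dosage

    # late-vs-early stage effects in the designated cell type
    de_cells = (condition == "late") & (cell_type == config.de_cell_type)
    for eff in config.de_genes:
        if eff.gene not in gene_pos:
            raise ValueError(f"unknown gene in de_genes: {eff.gene!r}")
        mu[gene_pos[eff.gene], de_cells] *= 2.0 ** eff.log2fc

    # regulons: latent lognormal TF activity scales TF and targets
    rng_reg = _rng(config.seed, "regulon")
    for reg in config.regulons_true:
        for g in (reg.tf, *reg.targets):
            if g not in gene_pos:
                raise ValueError(f"unknown gene in regulons_true: {g!r}")
        activity = rng_reg.lognormal(0.0, 1.0, size=n_cells)
        activity /= activity.mean()
        mu[gene_pos[reg.tf]] *= activity
        scaled = activity ** reg.strength
        scaled /= scaled.mean()
        for t in reg.targets:
            mu[gene_pos[t]] *= scaled

    # condition-specific ligand/receptor amplitudes
    for pair in config.lr_pairs_true:
        for g in (pair.ligand, pair.receptor):
            if g not in gene_pos:
                raise ValueError(f"unknown gene in lr_pairs_true: {g!r}")
        for cond, amp in (("early", pair.amp_early), ("late", pair.amp_late)):
            senders = (cell_type == pair.sender) & (condition == cond)
            mu[gene_pos[pair.ligand], senders] *= 1.0 + amp
        receivers = cell_type == pair.receiver
        mu[gene_pos[pair.receptor], receivers] *= pair.receptor_bias

    # --- counts --------------------------------------------------------
    r = float(dispersion)
    p = r / (r + mu)
    counts_dense = _rng(config.seed, "counts").negative_binomial(r, p)
    counts = CountMatrix(sp.csr_matrix(counts_dense), gene_ids, cell_ids)

    malignant = pd.Series(
        (dosage != 1.0).any(axis=0), index=cell_ids, name="malignant"
    )
    truth = SimTruth(
        malignant=malignant,
        dosage=dosage,
        de_genes=pd.DataFrame(
            {"gene": [e.gene for e in config.de_genes],
             "log2fc": [e.log2fc for e in config.de_genes]}
        ),
        regulon_edges=pd.DataFrame(
            [
                {"tf": reg.tf, "target": t, "strength": reg.strength}
                for reg in config.regulons_true
                for t in reg.targets
            ],
            columns=["tf", "target", "strength"],
        ),
        lr_amplitudes=pd.DataFrame(
            [
                {
                    "ligand": p_.ligand,
                    "receptor": p_.receptor,
                    "pathway": p_.pathway,
                    "sender": p_.sender,
                    "receiver": p_.receiver,
                    "amp_early": p_.amp_early,
                    "amp_late": p_.amp_late,
                }
                for p_ in config.lr_pairs_true
            ],
            columns=[
                "ligand", "receptor", "pathway", "sender", "receiver",
                "amp_early", "amp_late",
            ],
        ),
    )
    return SyntheticDataset(counts, annotation, metadata, truth)


def generate_bulk_survival_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw a samples x genes log2(x+1) matrix plus exponential survival.

    Returns (expression, survival records, truth subgroup labels).
    """
    config.validate()
    bulk = config.bulk
    if bulk is None:
        raise ValueError("config.bulk is not set")
    if len(bulk.groups) < 2:
        raise ValueError("need at least two subgroups")
    for g in bulk.groups:
        if g.hazard < 0:
            raise ValueError(f"negative hazard for subgroup {g.label!r}")
        if g.hazard == 0 and bulk.censor_window is None:
            raise ValueError(
                f"hazard 0 for subgroup {g.label!r} requires a finite censor window"
            )

    genes = list(bulk.genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng_expr = _rng(config.seed, "bulk_expr")
    rng_noise = _rng(config.seed, "bulk_noise")
    rng_surv = _rng(config.seed, "survival")

    base = rng_expr.uniform(2.0, 6.0, size=len(genes))
    rows, sample_ids, labels = [], [], []
    times, events = [], []
    idx = 0
    for grp in bulk.groups:
        profile = base.copy()
        for g, shift in grp.marker_shift.items():
            if g not in gene_pos:
                raise ValueError(f"unknown marker gene {g!r} in subgroup {grp.label!r}")
            profile[gene_pos[g]] += shift
        for _ in range(grp.n_samples):
            rows.append(
                np.clip(profile + rng_noise.normal(0.0, bulk.noise_sd, len(genes)), 0, None)
            )
            sample_ids.append(f"P{idx:05d}")
            labels.append(grp.label)
            idx += 1
            t_event = (
                rng_surv.exponential(1.0 / grp.hazard) if grp.hazard > 0 else np.inf
            )
            if bulk.censor_window is not None:
                lo, hi = bulk.censor_window
                t_cens = rng_surv.uniform(lo, hi)
            else:
                t_cens = np.inf
            t = min(t_event, t_cens)
            if not np.isfinite(t):
                raise ValueError("non-finite survival time; set a censor window")
            times.append(max(t, 1e-9))
            events.append(int(t_event <= t_cens))

    expr = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=genes)
    survival = pd.DataFrame(
        {"sample": sample_ids, "time": times, "event": events}
    )
    truth = pd.Series(labels, index=sample_ids, name="subgroup")
    return expr, survival, truth


# ----------------------------------------------------------------------
# serialization


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Emit the MTX/TSV triplet, metadata, annotation, and truth tables."""
    if dataset.counts.n_cells == 0 or dataset.counts.n_genes == 0:
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    write_triplet(dataset.counts, directory)
    write_tsv(dataset.cell_metadata, directory / "cell_metadata.tsv")
    write_tsv(dataset.gene_annotation, directory / "gene_annotation.tsv")
    truth_dir = directory / "truth"
    malignant_df = dataset.truth.malignant.rename("malignant").rename_axis("cell_id").reset_index()
    write_tsv(malignant_df, truth_dir / "malignant.tsv")
    # dosage stored as sparse offsets from 1 so the MTX zero-default round-trips
    offset = sp.coo_matrix(dataset.truth.dosage - 1.0)
    truth_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(truth_dir / "dosage_offset.mtx"), offset)
    write_tsv(dataset.truth.de_genes, truth_dir / "de_genes.tsv")
    write_tsv(dataset.truth.regulon_edges, truth_dir / "regulon_edges.tsv")
    write_tsv(dataset.truth.lr_amplitudes, truth_dir / "lr_amplitudes.tsv")


def read_dataset(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    counts = read_triplet(directory)
    metadata = read_tsv(directory / "cell_metadata.tsv", dtype={"cell_id": str})
    annotation = read_tsv(directory / "gene_annotation.tsv", dtype={"gene": str})
    truth_dir = directory / "truth"
    malignant_df = read_tsv(truth_dir / "malignant.tsv", dtype={"cell_id": str})
    malignant = pd.Series(
        malignant_df["malignant"].to_numpy(dtype=bool),
        index=malignant_df["cell_id"].to_numpy(dtype=object),
        name="malignant",
    )
    dosage = (
        np.asarray(
            sp.coo_matrix(scipy.io.mmread(str(truth_dir / "dosage_offset.mtx"))).todense()
        )
        + 1.0
    )
    truth = SimTruth(
        malignant=malignant,
        dosage=dosage,
        de_genes=read_tsv(truth_dir / "de_genes.tsv"),
        regulon_edges=read_tsv(truth_dir / "regulon_edges.tsv"),
        lr_amplitudes=read_tsv(truth_dir / "lr_amplitudes.tsv"),
    )
    return SyntheticDataset(counts, annotation, metadata, truth)
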