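# scstage

Stage-resolved single-cell tumor analysis toolkit. It re-implements, as a
tested and reusable pipeline, the computational stages of a stage-resolved
tumor transcriptomics analysis:

- **`scstage.simulate`** — synthetic single-cell and bulk-cohort data with
  full ground truth: negative-binomial counts with planted segmental
  copy-number dosage, stage-specific fold changes, TF→target co-expression
  regulons, condition-specific ligand–receptor amplitudes, and subgroup
  survival hazards.
- **`scstage.qc`** — gene detection / cell quality filters (mito ≤ 20%,
  200–5000 detected genes), log-normalization (scale factor 10,000),
  per-gene centering with upper clip at 10, top-3000 variable genes.
- **`scstage.cnv`** — expression-derived CNV signal: tumor cells diluted
  with normals to ≤ 20%, per-gene z-scores clipped to ±3, 100-gene moving
  windows along the genome, per-cell mean-square and top-5%-reference
  correlation scores, malignancy call at ms > 0.02 or corr > 0.2.
- **`scstage.metrics`** — cluster-vs-stage purity and entropy (bits and
  normalized to [0, 1]).
- **`scstage.markers`** — Wilcoxon rank-sum differential expression with
  min.pct 0.25 screening, exact enumeration for small groups, BH
  adjustment, and strict retention at p_adj < 0.01 and log2FC > 1.
- **`scstage.grn`** — consensus TF→target networks from 100 seeded runs of
  a pluggable importance backend (edges kept at support ≥ 80), regulon
  construction, recovery-curve activity scoring, and Jensen–Shannon
  regulon specificity (1 − √JSD).
- **`scstage.stratify`** — Ward.D / Euclidean hierarchical subgroups of
  bulk cohorts on marker genes, Kaplan–Meier curves, k-sample log-rank
  test.
- **`scstage.communication`** — mass-action ligand–receptor scores
  (sender ligand mean × receiver receptor mean, geometric-mean subunit
  aggregation), label-permutation p-values, condition networks,
  differential networks, and pathway information flow with
  exclusive-early/late calls.

## CLI

Each stage is a subcommand of `scstage`:

```sh
scstage simulate --config cfg.yaml --out sim/          # synthetic dataset
scstage qc --in sim --out qc --mito-prefix MT-
scstage cnv --in qc --annotation sim/gene_annotation.tsv --out cnv \
        [--window 100 --ms-thr 0.02 --corr-thr 0.2]
scstage metrics --clusters clusters.tsv --stages stages.tsv --out report.tsv
scstage markers --in qc --groups groups.tsv --out markers.tsv
scstage grn --in qc --tfs tfs.tsv --out grn --runs 100 --min-support 80 --seed 1
scstage stratify --expr bulk_expression.tsv --surv bulk_survival.tsv \
        --markers markers.txt --k 3 --out stratify
scstage commnet --in-early early/ --in-late late/ --db lr_db.tsv \
        --perms 100 --seed 1 --out comm
```

Count matrices use the CellRanger-style triplet layout (`matrix.mtx`
Matrix Market coordinate integer, genes as rows, plus `genes.tsv` and
`barcodes.tsv`); metadata, annotation and result tables are TSV with a
header row. A YAML example for `simulate` is produced by
`tests/test_cli.py::pipeline_config`.

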