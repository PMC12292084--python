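import numpy as np
import pytest
import scipy.sparse as sp

from scstage.matrix import CountMatrix, NormalizedMatrix
from scstage.simulate import (
    BulkConfig,
    BulkGroup,
    CNVEvent,
    PlantedRegulon,
    SimConfig,
    StageEffect,
    generate_single_cell_dataset,
)


def make_counts(arr, gene_ids=None, cell_ids=None) -> CountMatrix:
    arr = np.asarray(arr)
    g, c = arr.shape
    return CountMatrix(
        sp.csr_matrix(arr),
        np.array(gene_ids if gene_ids is not None else [f"g{i}" for i in range(g)], dtype=object),
        np.array(cell_ids if cell_ids is not None else [f"c{i}" for i in range(c)], dtype=object),
    )


def make_norm(arr, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    arr = np.asarray(arr, dtype=float)
    g, c = arr.shape
    return NormalizedMatrix(
        sp.csr_matrix(arr),
        np.array(gene_ids if gene_ids is not None else [f"g{i}" for i in range(g)], dtype=object),
        np.array(cell_ids if cell_ids is not None else [f"c{i}" for i in range(c)], dtype=object),
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genes=120,
        chromosomes=(("chr1", 60), ("chr2", 60)),
        n_cells_per_group={
            ("epithelial", "IA"): 40,
            ("epithelial", "IV"): 40,
            ("immune", "IA"): 30,
            ("epithelial", "normal"): 60,
        },
        cnv_events=(CNVEvent("chr1", 0, 30, 0.5, cell_type="epithelial", stage="IV"),),
        de_genes=(StageEffect("G00070", 2.0), StageEffect("G00071", -1.5)),
        regulons_true=(PlantedRegulon("G00090", ("G00091", "G00092"), 0.8),),
        mito_fraction=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_single_cell_dataset(small_config)


@pytest.fixture()
def bulk_config() -> SimConfig:
    genes = tuple(f"B{i:03d}" for i in range(30))
    return SimConfig(
        n_genes=4,
        chromosomes=(("chr1", 4),),
        n_cells_per_group={("epithelial", "IA"): 3},
        bulk=BulkConfig(
            genes=genes,
            groups=(
                BulkGroup("A", 40, 0.05, {g: 2.5 for g in genes[:10]}),
                BulkGroup("B", 40, 0.15, {g: 2.5 for g in genes[10:20]}),
                BulkGroup("C", 40, 0.40, {g: 2.5 for g in genes[20:30]}),
            ),
            noise_sd=0.4,
        ),
        seed=11,
    )
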