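"""Reading and writing the MTX/TSV triplet layout and plain TSV tables."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import CountMatrix

__all__ = [
    "write_triplet",
    "read_triplet",
    "write_tsv",
    "read_tsv",
]


def write_triplet(counts: CountMatrix, directory: str | Path) -> None:
    """Write matrix.mtx (integer coordinate), genes.tsv and barcodes.tsv."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        coo = sp.coo_matrix(counts.values, dtype=np.int64)
        scipy.io.mmwrite(str(directory / "matrix.mtx"), coo, field="integer")
        pd.DataFrame(
            {"gene_id": counts.gene_ids, "gene_name": counts.gene_ids}
        ).to_csv(directory / "genes.tsv", sep="\t", header=False, index=False)
        pd.DataFrame({"barcode": counts.cell_ids}).to_csv(
            directory / "barcodes.tsv", sep="\t", header=False, index=False
        )
    except OSError as e:
        raise OSError(f"failed writing triplet under {directory}: {e}") from e


def read_triplet(directory: str | Path) -> CountMatrix:
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"missing {mtx}")
    values = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)
    return CountMatrix(
        values,
        genes.iloc[:, 0].to_numpy(dtype=object),
        barcodes.iloc[:, 0].to_numpy(dtype=object),
    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=index)
    except OSError as e:
        raise OSError(f"failed writing {path}: {e}") from e


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing {path}")
    return pd.read_csv(path, sep="\t", **kwargs)
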