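"""Readers and writers for the standard on-disk formats.

Expression matrices are exchanged either as Matrix Market triplets
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, the CellRanger v2
convention with genes as rows) or as dense CSV/TSV with gene rows and
cell columns.  Marker maps are JSON (``{"type": ["GENE", ...]}``) or
two-column CSV (``cell_type,gene``); partial labels are CSV with a
``cell_id,cell_type`` header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_mtx_dir(path: str | Path) -> ExpressionMatrix:
    """Read an MTX directory (matrix.mtx, genes.tsv, barcodes.tsv)."""
    path = Path(path)
    mat = spio.mmread(path / "matrix.mtx")
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    values = np.asarray(sparse.csr_matrix(mat).todense(), dtype=float)
    return ExpressionMatrix(values, genes, cells)


def write_mtx_dir(x: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(x.values))
    pd.Series(x.gene_ids).to_csv(path / "genes.tsv", sep="\t",
                                 header=False, index=False)
    pd.Series(x.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                 header=False, index=False)


def read_dense(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a dense CSV/TSV matrix with gene rows and cell columns."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float),
                            df.index.astype(str).tolist(),
                            df.columns.astype(str).tolist())


def write_dense(x: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.cell_ids)
    df.to_csv(path, sep=sep)


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Dispatch on path: a directory is read as MTX, a file as dense CSV/TSV."""
    path = Path(path)
    if path.is_dir():
        return read_mtx_dir(path)
    return read_dense(path)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def read_markers(path: str | Path) -> dict[str, list[str]]:
    """Read a marker map from JSON or two-column CSV (cell_type,gene)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"marker file not found: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        return {str(t): [str(g) for g in genes] for t, genes in raw.items()}
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"marker CSV needs columns cell_type,gene: {path}")
    tcol, gcol = df.columns[:2]
    out: dict[str, list[str]] = {}
    for t, g in zip(df[tcol].astype(str), df[gcol].astype(str)):
        out.setdefault(t, []).append(g)
    return out


def write_markers(markers: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({t: list(g) for t, g in markers.items()}, fh, indent=1)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a partial label table with columns cell_id, cell_type."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    df = pd.read_csv(path)
    if not {"cell_id", "cell_type"}.issubset(df.columns):
        raise ValueError(f"label CSV needs header cell_id,cell_type: {path}")
    return df[["cell_id", "cell_type"]].astype(str)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels[["cell_id", "cell_type"]].to_csv(path, index=False)
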