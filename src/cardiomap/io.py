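"""File I/O: Matrix Market count matrices, id lists, CSV result tables.

On disk the 10x convention is used (genes as rows of the .mtx); in memory
everything is genes x cells.  Orientation of a foreign .mtx is auto-detected
by matching header dimensions against the id-file lengths.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .containers import (
    AssignmentResult,
    FormatError,
    GeneExpressionMatrix,
    MarkerTable,
    ValidationError,
)

# floats are serialized with 17 significant digits so that write->read
# round-trips are exact to double precision
FLOAT_FORMAT = "%.17g"


def _read_id_file(path: str | os.PathLike) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_count_matrix(
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    cells_path: str | os.PathLike,
) -> GeneExpressionMatrix:
    """Read a Matrix Market counts file with gene/barcode id lists.

    The matrix is oriented to genes x cells automatically: if the header
    dimensions match (n_genes, n_cells) it is taken as-is, if they match
    (n_cells, n_genes) it is transposed, and a square ambiguous case with
    differing id counts raises a format error.
    """
    genes = _read_id_file(genes_path)
    cells = _read_id_file(cells_path)
    try:
        mat = spio.mmread(os.fspath(mtx_path))
    except Exception as e:  # malformed file
        raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {e}") from e
    mat = sp.coo_matrix(mat)
    ng, nc = len(genes), len(cells)
    if mat.shape == (ng, nc):
        pass
    elif mat.shape == (nc, ng) and ng != nc:
        mat = mat.T
    else:
        raise FormatError(
            f"matrix dimensions {mat.shape} do not match {ng} genes x {nc} cells"
        )
    dense = np.asarray(mat.todense())
    if np.issubdtype(dense.dtype, np.floating) and not np.allclose(
        dense, np.round(dense)
    ):
        raise ValidationError("count matrix contains non-integer entries")
    if (dense < 0).any():
        raise ValidationError("count matrix contains negative entries")
    meta = pd.DataFrame({"replicate": ["R1"] * nc}, index=cells)
    return GeneExpressionMatrix(
        counts=dense.astype(np.int64), gene_ids=genes, cell_ids=cells, cell_meta=meta
    )


def write_count_matrix(
    m: GeneExpressionMatrix,
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    cells_path: str | os.PathLike,
) -> None:
    """Write counts as Matrix Market (genes as rows) plus one-id-per-line files."""
    spio.mmwrite(os.fspath(mtx_path), sp.coo_matrix(m.counts))
    Path(genes_path).write_text("".join(g + "\n" for g in m.gene_ids))
    Path(cells_path).write_text("".join(c + "\n" for c in m.cell_ids))


def write_cell_meta(m: GeneExpressionMatrix, path: str | os.PathLike) -> None:
    df = m.cell_meta.copy()
    df.insert(0, "cell_id", df.index.astype(str))
    df.to_csv(path, index=False)


def read_cell_meta(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "replicate": str})
    return df.set_index("cell_id")


def write_results(obj, path: str | os.PathLike) -> Path:
    """Write a result object as CSV with stable column order and full precision.

    Accepts a MarkerTable, an AssignmentResult, or any DataFrame.
    """
    path = Path(path)
    if isinstance(obj, MarkerTable):
        df = obj.table
    elif isinstance(obj, AssignmentResult):
        df = obj.table[["cell_id", "assigned_type", "confidence", "mean_nn_distance", "gate_reason"]]
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    try:
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    except OSError as e:
        raise OSError(f"cannot write results to {path}: {e}") from e
    return path


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_embedding_csv(coords: np.ndarray, cell_ids: list[str], path) -> Path:
    df = pd.DataFrame(
        coords, columns=[f"dim{i + 1}" for i in range(coords.shape[1])]
    )
    df.insert(0, "cell_id", cell_ids)
    return write_results(df, path)
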