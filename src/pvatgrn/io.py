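"""File I/O for the formats the pipeline touches.

Counts travel as a Matrix Market file (genes x cells, matching the common
single-cell exchange layout) with ``genes.tsv`` and ``barcodes.tsv`` sidecars;
tables (cell metadata, edge lists, centralities, scores, reports) as
tab-separated files. Every table written by a pipeline stage carries a
comment header naming the producing stage, the global seed and a parameter
hash, so outputs are traceable to their run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix
from .errors import FormatError

__all__ = [
    "read_counts",
    "write_counts",
    "read_table",
    "write_table",
    "params_hash",
]


def params_hash(params: dict) -> str:
    """Short stable hash of a JSON-serializable parameter mapping."""
    payload = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_counts(counts: CountMatrix, directory: str | Path) -> Path:
    """Write matrix.mtx (genes x cells) + genes.tsv + barcodes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), counts.matrix.T.tocoo())
    (directory / "genes.tsv").write_text("\n".join(counts.gene_ids) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(counts.barcodes) + "\n")
    return directory


def read_counts(directory: str | Path) -> CountMatrix:
    """Read a matrix.mtx + sidecars directory back into a CountMatrix.

    Raises :class:`FormatError` when sidecar lengths do not match the matrix
    dimensions. An empty (0-entry but well-formed) matrix is returned as such.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    if not mtx_path.exists():
        raise FormatError(f"no matrix.mtx under {directory}")
    m = sp.csr_matrix(scipy.io.mmread(str(mtx_path))).T.tocsr()  # cells x genes
    genes = _read_lines(directory / "genes.tsv")
    barcodes = _read_lines(directory / "barcodes.tsv")
    if m.shape[1] != len(genes) or m.shape[0] != len(barcodes):
        raise FormatError(
            f"matrix is {m.shape[0]} cells x {m.shape[1]} genes but sidecars have "
            f"{len(barcodes)} barcodes / {len(genes)} genes"
        )
    counts = m.astype(np.int64)
    return CountMatrix(counts, genes, barcodes)


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar {path}")
    return [ln.split("\t")[0] for ln in path.read_text().splitlines() if ln.strip()]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    stage: str,
    seed: int | None = None,
    params: dict | None = None,
    index: bool = True,
) -> Path:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# stage={stage}"
    if seed is not None:
        header += f" seed={seed}"
    if params is not None:
        header += f" params_hash={params_hash(params)}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment headers skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
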