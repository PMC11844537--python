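"""Lightweight in-memory containers for count data.

The package passes single-cell counts around as a sparse cells x genes matrix
with explicit gene identifiers and cell barcodes, mirroring the on-disk layout
(Matrix Market file plus ``genes.tsv`` / ``barcodes.tsv`` sidecars). Per-cell
metadata travels separately as a :class:`pandas.DataFrame` ("cell table") whose
rows align with the matrix rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer counts.

    Parameters
    ----------
    matrix
        Sparse (CSR) cells x genes count matrix.
    gene_ids
        Gene identifiers, one per column.
    barcodes
        Cell barcodes, one per row.
    """

    matrix: sp.csr_matrix
    gene_ids: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(np.asarray(self.matrix))
        self.matrix = self.matrix.tocsr()
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        n_cells, n_genes = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene sidecar has {len(self.gene_ids)} entries but matrix has "
                f"{n_genes} gene columns"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"barcode sidecar has {len(self.barcodes)} entries but matrix has "
                f"{n_cells} cell rows"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Densify into a cells x genes DataFrame (desk-scale data only)."""
        return pd.DataFrame(
            self.matrix.toarray(), index=self.barcodes, columns=self.gene_ids
        )

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the masked cells/genes."""
        m = self.matrix
        barcodes = self.barcodes
        genes = self.gene_ids
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            m = m[cell_mask]
            barcodes = [b for b, keep in zip(barcodes, cell_mask) if keep] \
                if cell_mask.dtype == bool else [barcodes[i] for i in cell_mask]
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            m = m[:, gene_mask]
            genes = [g for g, keep in zip(genes, gene_mask) if keep] \
                if gene_mask.dtype == bool else [genes[i] for i in gene_mask]
        return CountMatrix(m.tocsr(), genes, barcodes)

    def total_counts(self) -> np.ndarray:
        """Per-cell total transcript counts."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with nonzero counts."""
        return np.asarray((self.matrix > 0).sum(axis=1)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Per-gene number of cells with nonzero counts."""
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()
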