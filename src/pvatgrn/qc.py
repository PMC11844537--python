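"""Cell- and gene-level quality-control filters.

Filters are applied in a fixed, documented order, each step on the population
surviving the previous one:

1. doublets: cells whose doublet score is at or above the cutoff;
2. genes detected in at most ``min_cells_per_gene`` cells;
3. cells with fewer than ``min_transcripts_per_cell`` total transcripts;
4. cells exceeding ``max_reads_per_cell`` total counts or
   ``max_genes_per_cell`` detected genes;
5. cells outside ``mad_multiplier`` median absolute deviations of the median
   of log1p(total counts) or log1p(genes detected), medians/MADs computed on
   the population that survived steps 1-4.

The MAD is the unscaled median absolute deviation (no 1.4826 normal
consistency factor) by default; set ``mad_scaled=True`` to scale. Setting a
minimum threshold to 0, a maximum to ``inf``, the doublet cutoff to a value
above 1, or the MAD multiplier to ``inf`` disables that step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .errors import InvalidParameterError

__all__ = ["QCThresholds", "QCReport", "apply_qc"]


@dataclass
class QCThresholds:
    """Quality-control cutoffs. Defaults are the study's stated values."""

    min_cells_per_gene: int = 3          # genes in <= this many cells removed
    min_transcripts_per_cell: int = 100  # cells with fewer total counts removed
    max_reads_per_cell: float = 15000    # cells with strictly more removed
    max_genes_per_cell: float = 4500     # cells with strictly more removed
    mad_multiplier: float = 5.0
    doublet_score_cutoff: float = 0.5    # cells with score >= cutoff removed
    max_mito_fraction: float | None = None  # optional; needs a mito_fraction column
    mad_scaled: bool = False

    def __post_init__(self) -> None:
        for name in (
            "min_cells_per_gene",
            "min_transcripts_per_cell",
            "max_reads_per_cell",
            "max_genes_per_cell",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.mad_multiplier <= 0:
            raise InvalidParameterError("mad_multiplier must be > 0")
        if not 0.0 <= self.doublet_score_cutoff:
            raise InvalidParameterError("doublet_score_cutoff must be >= 0")


@dataclass
class QCReport:
    """Per-step removal bookkeeping; removed + surviving = input, per axis."""

    input_cells: int
    input_genes: int
    steps: list[dict] = field(default_factory=list)
    output_cells: int = 0
    output_genes: int = 0
    empty: bool = False

    def record(self, step: str, cells_removed: int, genes_removed: int,
               cells_left: int, genes_left: int) -> None:
        self.steps.append(
            {
                "step": step,
                "cells_removed": int(cells_removed),
                "genes_removed": int(genes_removed),
                "cells_remaining": int(cells_left),
                "genes_remaining": int(genes_left),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _mad(values: np.ndarray, scaled: bool) -> float:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return mad * 1.4826 if scaled else mad


def apply_qc(
    counts: CountMatrix,
    cells: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Apply the QC filter cascade; returns filtered data and a step report.

    ``cells`` must align row-for-row with ``counts`` and carry a
    ``doublet_score`` column (may be all zero). An empty result at any step is
    reported through ``QCReport.empty``, not an exception.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if len(cells) != counts.n_cells:
        raise InvalidParameterError(
            f"cell table has {len(cells)} rows but counts has {counts.n_cells} cells"
        )
    if "doublet_score" not in cells.columns:
        raise InvalidParameterError("cell table must carry a 'doublet_score' column")

    report = QCReport(input_cells=counts.n_cells, input_genes=counts.n_genes)
    cells = cells.copy()

    def _done(cm: CountMatrix, tbl: pd.DataFrame):
        report.output_cells = cm.n_cells
        report.output_genes = cm.n_genes
        report.empty = cm.n_cells == 0 or cm.n_genes == 0
        return cm, tbl, report

    # 1. doublets
    keep = cells["doublet_score"].to_numpy() < thresholds.doublet_score_cutoff
    counts = counts.subset(cell_mask=keep)
    cells = cells.loc[keep]
    report.record("doublet_score", (~keep).sum(), 0, counts.n_cells, counts.n_genes)
    if counts.n_cells == 0:
        return _done(counts, cells)

    # optional mitochondrial-fraction cutoff (not part of the default cascade)
    if thresholds.max_mito_fraction is not None:
        if "mito_fraction" not in cells.columns:
            raise InvalidParameterError(
                "max_mito_fraction set but cell table lacks 'mito_fraction'"
            )
        keep = cells["mito_fraction"].to_numpy() <= thresholds.max_mito_fraction
        counts = counts.subset(cell_mask=keep)
        cells = cells.loc[keep]
        report.record("mito_fraction", (~keep).sum(), 0, counts.n_cells, counts.n_genes)
        if counts.n_cells == 0:
            return _done(counts, cells)

    # 2. genes in too few cells (0 disables the step entirely)
    if thresholds.min_cells_per_gene > 0:
        keep_genes = counts.cells_per_gene() > thresholds.min_cells_per_gene
    else:
        keep_genes = np.ones(counts.n_genes, dtype=bool)
    counts = counts.subset(gene_mask=keep_genes)
    report.record("gene_min_cells", 0, (~keep_genes).sum(), counts.n_cells, counts.n_genes)
    if counts.n_genes == 0:
        return _done(counts, cells)

    # 3. cells with too few transcripts
    keep = counts.total_counts() >= thresholds.min_transcripts_per_cell
    counts = counts.subset(cell_mask=keep)
    cells = cells.loc[keep]
    report.record("cell_min_transcripts", (~keep).sum(), 0, counts.n_cells, counts.n_genes)
    if counts.n_cells == 0:
        return _done(counts, cells)

    # 4. cells with too many reads or too many detected genes
    totals = counts.total_counts()
    ngenes = counts.genes_detected()
    keep = (totals <= thresholds.max_reads_per_cell) & (ngenes <= thresholds.max_genes_per_cell)
    counts = counts.subset(cell_mask=keep)
    cells = cells.loc[keep]
    report.record("cell_max_reads_genes", (~keep).sum(), 0, counts.n_cells, counts.n_genes)
    if counts.n_cells == 0:
        return _done(counts, cells)

    # 5. MAD outliers on log1p totals and log1p genes detected
    if np.isfinite(thresholds.mad_multiplier):
        log_tot = np.log1p(counts.total_counts())
        log_ng = np.log1p(counts.genes_detected())
        keep = np.ones(counts.n_cells, dtype=bool)
        for metric in (log_tot, log_ng):
            med = np.median(metric)
            mad = _mad(metric, thresholds.mad_scaled)
            if mad == 0:
                continue  # degenerate spread: no outliers by this metric
            keep &= np.abs(metric - med) <= thresholds.mad_multiplier * mad
        counts = counts.subset(cell_mask=keep)
        cells = cells.loc[keep]
        report.record("mad_outliers", (~keep).sum(), 0, counts.n_cells, counts.n_genes)

    if counts.n_cells == 0 or counts.n_genes == 0:
        warnings.warn("QC removed every cell or gene", stacklevel=2)
    return _done(counts, cells)
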