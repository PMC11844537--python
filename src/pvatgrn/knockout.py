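"""In-silico TF knockout, embedding vector fields, and perturbation scores.

Knocking out a TF sets its (normalized) expression to zero in every cell and
propagates the change through the fitted GRN coefficients for a small number
of steps, giving a cells x genes matrix of signed expression shifts. Two 2-D
vector fields over the embedding are then compared per cell:

- the developmental field, the local pseudotime gradient: where a cell's
  neighborhood says the control -> high-fat progression points;
- the knockout field, the expected embedding displacement under
  transition probabilities that favor neighbors whose expression offset
  correlates with the cell's knockout shift (the velocity-embedding
  projection construction), with the uniform-neighbor baseline subtracted.

The per-cell perturbation score is the inner product of the two fields:
positive where the knockout pushes cells along the developmental flow
(stabilizing those states), negative where it opposes it. Scores are
summarized over 10 equal-width pseudotime bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import InvalidParameterError
from .grn import GRNModel

__all__ = [
    "VectorField",
    "PerturbationScore",
    "smooth_expression",
    "propagate_knockout",
    "developmental_field",
    "ko_field",
    "perturbation_score",
]


def smooth_expression(
    expr: pd.DataFrame,
    cells: pd.DataFrame,
    k_neighbors: int = 30,
    embed_cols: tuple[str, str] = ("x", "y"),
) -> pd.DataFrame:
    """k-nearest-neighbor moment smoothing of normalized expression.

    Each cell's expression is replaced by the mean over itself and its k
    nearest embedding neighbors — the first-moment smoothing velocity and
    perturbation tools apply before simulating, which suppresses per-cell
    count noise while preserving the expression gradient along the
    trajectory. Knockout simulation and field projection operate on smoothed
    values; inference does not.
    """
    e = cells[list(embed_cols)].to_numpy(dtype=float)
    idx = _neighbor_indices(e, k_neighbors)
    x = expr.to_numpy(dtype=float)
    sm = (x[idx].sum(axis=1) + x) / (idx.shape[1] + 1)
    return pd.DataFrame(sm, index=expr.index, columns=expr.columns)


@dataclass
class VectorField:
    """Per-cell 2-D vectors in embedding units."""

    vectors: pd.DataFrame  # columns dx, dy; index = cell barcodes
    kind: str  # "developmental" | "knockout"

    def __post_init__(self) -> None:
        if not np.isfinite(self.vectors.to_numpy()).all():
            raise InvalidParameterError("vector field contains non-finite components")


@dataclass
class PerturbationScore:
    """Per-cell inner-product scores and their pseudotime-bin summaries."""

    scores: pd.Series
    bin_summary: pd.DataFrame  # columns: bin, n, mean, q1, median, q3
    bin_edges: np.ndarray


def propagate_knockout(
    grn: GRNModel,
    expr: pd.DataFrame,
    tf: str,
    n_steps: int = 3,
) -> pd.DataFrame:
    """Shift matrix (final - original expression) after knocking out ``tf``.

    Per cell the TF's value is set to 0 and held there; for ``n_steps``
    iterations every gene's simulated value is its original value plus the
    coefficient-weighted sum of its regulators' current deltas, clipped at 0
    (expression cannot go negative). Returns a cells x genes DataFrame of
    signed deltas; the knocked-out TF's column equals minus its original
    expression.
    """
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    if tf not in expr.columns:
        raise InvalidParameterError(f"TF {tf!r} absent from expression matrix")
    if grn.genes and tf not in grn.genes and tf not in set(grn.edges["regulator"]):
        raise InvalidParameterError(f"TF {tf!r} absent from the GRN gene universe")

    genes = list(expr.columns)
    gidx = {g: i for i, g in enumerate(genes)}
    a = np.zeros((len(genes), len(genes)))
    for row in grn.edges.itertuples(index=False):
        if row.regulator in gidx and row.target in gidx:
            a[gidx[row.regulator], gidx[row.target]] = row.coefficient

    x = expr.to_numpy(dtype=float)
    j = gidx[tf]
    delta = np.zeros_like(x)
    delta[:, j] = -x[:, j]
    for _ in range(n_steps):
        sim = np.clip(x + delta @ a, 0.0, None)
        sim[:, j] = 0.0
        delta = sim - x
        delta[:, j] = -x[:, j]
    return pd.DataFrame(delta, index=expr.index, columns=genes)


def _neighbor_indices(embedding: np.ndarray, k: int) -> np.ndarray:
    n = len(embedding)
    if k >= n:
        raise InvalidParameterError(f"k_neighbors={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    return idx[:, 1:]  # drop self


def developmental_field(
    cells: pd.DataFrame,
    k_neighbors: int = 30,
    pseudotime_col: str = "pseudotime",
    embed_cols: tuple[str, str] = ("x", "y"),
) -> VectorField:
    """Local pseudotime-gradient field.

    Per cell i, vector = (1/k) * sum over its k nearest embedding neighbors j
    of (t_j - t_i) (e_j - e_i): the mean neighbor offset weighted by the
    pseudotime increase in that direction. Reversing pseudotime negates the
    field exactly.
    """
    e = cells[list(embed_cols)].to_numpy(dtype=float)
    t = cells[pseudotime_col].to_numpy(dtype=float)
    idx = _neighbor_indices(e, k_neighbors)
    dt = t[idx] - t[:, None]                    # (n, k)
    de = e[idx] - e[:, None, :]                 # (n, k, 2)
    v = (dt[:, :, None] * de).mean(axis=1)
    return VectorField(
        pd.DataFrame(v, index=cells.index, columns=["dx", "dy"]), kind="developmental"
    )


def ko_field(
    shift: pd.DataFrame,
    expr: pd.DataFrame,
    cells: pd.DataFrame,
    k_neighbors: int = 30,
    kernel_scale: float = 1.0,
    embed_cols: tuple[str, str] = ("x", "y"),
    exclude_gene: str | None = None,
) -> VectorField:
    """Project knockout shifts into the embedding as a transition field.

    For each cell i and neighbor j, the Pearson correlation r_ij between the
    cell's shift vector and the expression offset (x_j - x_i) is passed
    through an exponential kernel exp(r / kernel_scale) and normalized into
    transition probabilities p_ij; the cell's vector is
    sum_j p_ij (e_j - e_i) - (1/k) sum_j (e_j - e_i) (uniform-baseline
    subtraction, making a no-preference cell map to the zero vector). A cell
    with a zero-variance shift gets the zero vector.

    ``exclude_gene`` (typically the knocked-out TF) drops that column from
    the correlation, so the field reflects downstream transcriptional
    consequences rather than the imposed zeroing itself; a TF with no
    retained outgoing edges then yields an exactly zero field.
    """
    if kernel_scale <= 0:
        raise InvalidParameterError("kernel_scale must be > 0")
    if shift.shape != expr.shape or not shift.index.equals(expr.index):
        raise InvalidParameterError("shift and expression matrices are not aligned")
    e = cells[list(embed_cols)].to_numpy(dtype=float)
    idx = _neighbor_indices(e, k_neighbors)
    if exclude_gene is not None:
        keep = [c for c in expr.columns if c != exclude_gene]
        expr = expr[keep]
        shift = shift[keep]
    x = expr.to_numpy(dtype=float)
    s = shift.to_numpy(dtype=float)
    n, k = idx.shape
    v = np.zeros((n, 2))
    s_center = s - s.mean(axis=1, keepdims=True)
    s_norm = np.linalg.norm(s_center, axis=1)
    for i in range(n):
        if s_norm[i] == 0:
            continue
        nb = idx[i]
        dx = x[nb] - x[i]                       # (k, genes)
        dxc = dx - dx.mean(axis=1, keepdims=True)
        dx_norm = np.linalg.norm(dxc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (dxc @ s_center[i]) / (dx_norm * s_norm[i])
        r = np.nan_to_num(r, nan=0.0)
        w = np.exp(r / kernel_scale)
        p = w / w.sum()
        de = e[nb] - e[i]                       # (k, 2)
        v[i] = p @ de - de.mean(axis=0)
    return VectorField(
        pd.DataFrame(v, index=cells.index, columns=["dx", "dy"]), kind="knockout"
    )


def perturbation_score(
    dev: VectorField,
    ko: VectorField,
    pseudotime: pd.Series,
    n_bins: int = 10,
    normalize_vectors: bool = False,
) -> PerturbationScore:
    """Per-cell inner product of developmental and knockout fields.

    ``normalize_vectors=True`` unit-normalizes both vectors per cell first (a
    pure alignment score in [-1, 1]); the default uses raw vectors. Cells are
    binned into ``n_bins`` equal-width intervals over the observed pseudotime
    range (half-open bins, last bin closed) and per-bin count, mean and
    quartiles are reported.
    """
    if not dev.vectors.index.equals(ko.vectors.index):
        raise InvalidParameterError("vector fields cover different cells")
    if len(pseudotime) != len(dev.vectors):
        raise InvalidParameterError("pseudotime length does not match the fields")
    a = dev.vectors.to_numpy(dtype=float)
    b = ko.vectors.to_numpy(dtype=float)
    if normalize_vectors:
        a = _unit_rows(a)
        b = _unit_rows(b)
    scores = pd.Series((a * b).sum(axis=1), index=dev.vectors.index, name="score")

    t = np.asarray(pseudotime, dtype=float)
    lo, hi = t.min(), t.max()
    if hi == lo:
        hi = lo + 1.0  # single bin holds everything
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(t, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b_i in range(n_bins):
        vals = scores.to_numpy()[which == b_i]
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {"bin": b_i, "n": len(vals), "mean": vals.mean(),
                 "q1": q1, "median": med, "q3": q3}
            )
        else:
            rows.append(
                {"bin": b_i, "n": 0, "mean": np.nan, "q1": np.nan,
                 "median": np.nan, "q3": np.nan}
            )
    return PerturbationScore(
        scores=scores, bin_summary=pd.DataFrame(rows), bin_edges=edges
    )


def _unit_rows(v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    return np.divide(v, norms, out=np.zeros_like(v), where=norms > 0)
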