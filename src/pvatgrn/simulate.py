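"""Synthetic two-condition single-cell data with a planted regulatory network.

The generator emulates the study system downstream stages are built for: a
brown-adipocyte population whose regulatory wiring differs between a control
and a high-fat ("HF") diet condition. A ground-truth weighted TF->gene network
is drawn once; a designated subset of "driver" TFs has all outgoing weights
multiplied by ``effect_size`` in the HF condition, so the drivers are the TFs
whose functional importance changes between conditions. Cells sit on a
control -> HF pseudotime axis t in [0, 1]; the active network for a cell is
the interpolation W(t) = (1-t)*W_control + t*W_hf (a ``step`` mode switches
abruptly at the condition threshold instead, emulating a settled late
time point). Counts are negative-binomial draws around library-size-scaled
latent expression.

TF latent expression is generated by a shallow cascade: each TF receives an
exogenous non-negative basal draw plus weighted input from lower-indexed TFs
that regulate it. TF->TF edges (restricted to a DAG by index order) make paths
of length > 1 exist in the planted graph, so betweenness centrality — one of
the three measures used to prioritize TFs downstream — is non-degenerate on
synthetic data, as it is on a real promoter-derived network in which TFs are
themselves regulated genes.

A separate generator produces factorial multi-sample composition metadata
(sex x diet x time-on-diet, a handful of animals per group) for the cell-type
proportion analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix
from .errors import InvalidParameterError

__all__ = [
    "GroundTruthGRN",
    "SimulatedPopulation",
    "simulate_grn",
    "simulate_cells",
    "simulate_composition",
    "default_composition",
]


@dataclass
class GroundTruthGRN:
    """Planted weighted regulatory network for the two diet conditions.

    Weight matrices are regulators x genes where the gene axis is
    ``tf_ids + target_ids`` (TFs are genes too and may be regulated by
    lower-indexed TFs; no self-loops). ``W_control`` and ``W_hf`` share one
    sparsity pattern; the rows of ``W_hf`` belonging to ``driver_tfs`` equal
    ``effect_size`` times the corresponding control rows, all other rows are
    identical between conditions.
    """

    tf_ids: list[str]
    target_ids: list[str]
    W_control: np.ndarray
    W_hf: np.ndarray
    driver_tfs: list[str]
    effect_size: float
    intercepts: np.ndarray  # per-gene basal expression, aligned to gene_ids

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tf_ids) + list(self.target_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def base_edges(self) -> pd.DataFrame:
        """Union sparsity pattern as a (regulator, target) edge list.

        This is the base-GRN prior handed to network inference: it says which
        TF->gene pairs are candidates, not what their weights are.
        """
        rows, cols = np.nonzero((self.W_control != 0) | (self.W_hf != 0))
        genes = self.gene_ids
        return pd.DataFrame(
            {
                "regulator": [self.tf_ids[i] for i in rows],
                "target": [genes[j] for j in cols],
            }
        )

    def edge_frame(self) -> pd.DataFrame:
        """Edge list with both condition weights (regulator, target, w_ctrl, w_hf)."""
        rows, cols = np.nonzero((self.W_control != 0) | (self.W_hf != 0))
        genes = self.gene_ids
        return pd.DataFrame(
            {
                "regulator": [self.tf_ids[i] for i in rows],
                "target": [genes[j] for j in cols],
                "weight_control": self.W_control[rows, cols],
                "weight_hf": self.W_hf[rows, cols],
            }
        )


@dataclass
class SimulatedPopulation:
    """Counts + cell table + the ground truth that generated them."""

    counts: CountMatrix
    cells: pd.DataFrame
    truth: GroundTruthGRN
    latent: np.ndarray | None = field(default=None, repr=False)


def _check_count(name: str, value: int, minimum: int = 0) -> int:
    if int(value) != value or value < minimum:
        raise InvalidParameterError(f"{name} must be an integer >= {minimum}, got {value!r}")
    return int(value)


def simulate_grn(
    n_tfs: int,
    n_targets: int,
    density: float,
    n_drivers: int,
    effect_size: float,
    seed: int,
    *,
    weight_median: float = 0.25,
    weight_sigma: float = 1.0,
    p_positive: float = 0.8,
    intercept_low: float = 1.0,
    intercept_high: float = 3.0,
) -> GroundTruthGRN:
    """Draw a planted two-condition regulatory network.

    Edge presence over regulator x gene pairs (excluding self-loops; TF->TF
    edges only from a lower- to a higher-indexed TF) is i.i.d. Bernoulli with
    probability ``density``. Nonzero weights have log-normal magnitude
    (median ``weight_median``, log-scale sd ``weight_sigma``) — regulatory
    effect sizes are heavy-tailed, with many weak edges and a few strong
    ones — and sign +1 with probability ``p_positive`` (promoter-prior
    networks are activation-biased). ``n_drivers`` TFs are chosen uniformly;
    their outgoing rows in ``W_hf`` are the control rows scaled by
    ``effect_size``. Per-gene basal intercepts are Uniform(intercept_low,
    intercept_high).
    """
    n_tfs = _check_count("n_tfs", n_tfs)
    n_targets = _check_count("n_targets", n_targets)
    n_drivers = _check_count("n_drivers", n_drivers)
    if n_drivers > n_tfs:
        raise InvalidParameterError(f"n_drivers ({n_drivers}) exceeds n_tfs ({n_tfs})")
    if not 0.0 <= density <= 1.0:
        raise InvalidParameterError(f"density must be in [0, 1], got {density}")
    if effect_size < 0:
        raise InvalidParameterError(f"effect_size must be >= 0, got {effect_size}")

    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:03d}" for i in range(n_tfs)]
    target_ids = [f"G{i:03d}" for i in range(n_targets)]
    n_genes = n_tfs + n_targets

    # candidate mask: any TF -> any target; TF i -> TF j only for i < j (DAG)
    allowed = np.zeros((n_tfs, n_genes), dtype=bool)
    allowed[:, n_tfs:] = True
    tri = np.triu(np.ones((n_tfs, n_tfs), dtype=bool), k=1)
    allowed[:, :n_tfs] = tri

    present = allowed & (rng.random((n_tfs, n_genes)) < density)
    magnitude = rng.lognormal(np.log(weight_median), weight_sigma, size=(n_tfs, n_genes))
    sign = np.where(rng.random((n_tfs, n_genes)) < p_positive, 1.0, -1.0)
    W_control = np.where(present, magnitude * sign, 0.0)

    driver_idx = np.sort(rng.choice(n_tfs, size=n_drivers, replace=False)) if n_drivers else np.array([], dtype=int)
    W_hf = W_control.copy()
    W_hf[driver_idx] *= effect_size

    intercepts = rng.uniform(intercept_low, intercept_high, size=n_genes)
    return GroundTruthGRN(
        tf_ids=tf_ids,
        target_ids=target_ids,
        W_control=W_control,
        W_hf=W_hf,
        driver_tfs=[tf_ids[i] for i in driver_idx],
        effect_size=float(effect_size),
        intercepts=intercepts,
    )


def simulate_cells(
    truth: GroundTruthGRN,
    n_cells: int,
    nb_dispersion: float = 0.3,
    library_size: int = 250,
    seed: int = 0,
    *,
    mode: str = "interpolate",
    condition_threshold: float = 0.5,
    tf_noise_shape: float = 2.0,
    embedding_noise: float = 0.1,
    n_background: int = 150,
) -> SimulatedPopulation:
    """Sample cells along the control -> high-fat pseudotime axis.

    Per cell: pseudotime t ~ Uniform[0, 1]; condition label "control" if
    t < ``condition_threshold`` else "high-fat"; active weights W(t) are the
    linear interpolation of the two condition matrices (``mode="step"``
    switches abruptly at the threshold). TF latent expression is a Gamma
    basal draw (shape ``tf_noise_shape``, mean = the TF's intercept) plus
    weighted input from upstream TFs, clipped at 0; target latent mean is
    intercept + regulator-weighted sum, clipped at 0. Latent means are scaled
    to ``library_size`` per cell and counts drawn negative-binomial with
    dispersion ``nb_dispersion`` (variance m + dispersion * m^2). The default
    library of 250 gives the ~200-gene default panel a mean depth of roughly
    one count per gene per cell, matching the per-gene depth of typical
    single-nucleus data (a few thousand reads spread over thousands of
    expressed genes). The 2-D embedding is (t, Gaussian noise of sd
    ``embedding_noise``).

    ``n_background`` unregulated genes (intercept-only Gamma latent noise,
    ids ``B###``) pad the panel so the network genes are a minor fraction of
    each cell's library, as in a real transcriptome — without them the fixed
    per-cell library couples every network gene to the driver's activity and
    library normalization systematically attenuates strong regulators'
    coefficients.
    """
    n_cells = _check_count("n_cells", n_cells, minimum=2)
    if nb_dispersion <= 0:
        raise InvalidParameterError(f"nb_dispersion must be > 0, got {nb_dispersion}")
    if library_size <= 0:
        raise InvalidParameterError(f"library_size must be > 0, got {library_size}")
    if mode not in ("interpolate", "step"):
        raise InvalidParameterError(f"mode must be 'interpolate' or 'step', got {mode!r}")

    rng = np.random.default_rng(seed)
    n_tfs, n_genes = truth.W_control.shape
    t = rng.uniform(0.0, 1.0, size=n_cells)
    condition = np.where(t < condition_threshold, "control", "high-fat")

    if mode == "interpolate":
        mix = t
    else:
        mix = (t >= condition_threshold).astype(float)
    # W per cell: (n_cells, n_tfs, n_genes) would be large; do it gene-block-wise.
    # latent[:, j] for TF j depends on upstream TF latents -> sequential over TFs.
    latent = np.zeros((n_cells, n_genes))
    basal = rng.gamma(
        tf_noise_shape,
        np.maximum(truth.intercepts[:n_tfs], 0.0)[None, :] / tf_noise_shape,
        size=(n_cells, n_tfs),
    )
    dW = truth.W_hf - truth.W_control
    for j in range(n_tfs):
        contrib = np.zeros(n_cells)
        regs = np.nonzero((truth.W_control[:, j] != 0) | (dW[:, j] != 0))[0]
        for i in regs:  # regs all have index < j by construction
            w = truth.W_control[i, j] + mix * dW[i, j]
            # centered upstream contribution: regulators shift a TF around its
            # basal level without compounding means down the cascade
            contrib += w * (latent[:, i] - latent[:, i].mean())
        latent[:, j] = np.clip(basal[:, j] + contrib, 0.0, None)

    # targets: vectorized; W(t) column for target g = Wc[:, g] + mix * dW[:, g]
    tf_lat = latent[:, :n_tfs]
    base_part = tf_lat @ truth.W_control[:, n_tfs:]
    delta_part = (tf_lat * mix[:, None]) @ dW[:, n_tfs:]
    latent[:, n_tfs:] = np.clip(
        truth.intercepts[n_tfs:][None, :] + base_part + delta_part, 0.0, None
    )

    n_background = _check_count("n_background", n_background)
    if n_background:
        bg_intercepts = rng.uniform(1.0, 3.0, size=n_background)
        bg = rng.gamma(
            tf_noise_shape,
            bg_intercepts[None, :] / tf_noise_shape,
            size=(n_cells, n_background),
        )
        latent = np.hstack([latent, bg])
    gene_ids = truth.gene_ids + [f"B{i:03d}" for i in range(n_background)]

    totals = latent.sum(axis=1)
    safe = np.where(totals > 0, totals, 1.0)
    mean_counts = latent / safe[:, None] * library_size
    mean_counts[totals == 0] = 0.0

    # NB with var = m + a m^2  <=>  n = 1/a, p = n/(n+m)
    n_param = 1.0 / nb_dispersion
    p_param = n_param / (n_param + mean_counts)
    counts = np.zeros_like(mean_counts, dtype=np.int64)
    nonzero = mean_counts > 0
    counts[nonzero] = rng.negative_binomial(n_param, p_param[nonzero])

    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "sample": [f"sim_{c}" for c in condition],
            "sex": "F",
            "diet": condition,
            "time": "8W",
            "cell_type": "brown_adipocyte",
            "condition": condition,
            "doublet_score": 0.0,
            "pseudotime": t,
            "x": t,
            "y": rng.normal(0.0, embedding_noise, size=n_cells),
        }
    ).set_index("barcode", drop=False)

    cm = CountMatrix(sp.csr_matrix(counts), gene_ids, barcodes)
    return SimulatedPopulation(counts=cm, cells=cells, truth=truth, latent=latent)


def default_composition() -> dict[tuple[str, str, str], dict[str, float]]:
    """Factorial sex x diet x time design with tissue-realistic proportions.

    Eight treatment groups (F/M x control/high-fat x 8W/24W) share a baseline
    profile dominated by adipocytes, endothelial cells and fibroblasts; the
    high-fat groups shift a few points of endothelial mass toward adipocytes
    and immune cells so group comparisons have signal to find.
    """
    base = {
        "adipocyte": 0.641,
        "endothelial": 0.160,
        "fibroblast": 0.093,
        "immune": 0.047,
        "pericyte": 0.034,
        "mesothelial": 0.022,
        "smc": 0.003,
        "neuronal": 0.002,
    }
    hf = dict(base)
    hf["endothelial"] -= 0.04
    hf["adipocyte"] += 0.025
    hf["immune"] += 0.015
    out: dict[tuple[str, str, str], dict[str, float]] = {}
    for sex, diet, time in itertools.product(("F", "M"), ("control", "high-fat"), ("8W", "24W")):
        profile = hf if diet == "high-fat" else base
        total = sum(profile.values())
        out[(sex, diet, time)] = {k: v / total for k, v in profile.items()}
    return out


def simulate_composition(
    group_proportions: Mapping[tuple[str, str, str], Mapping[str, float]],
    samples_per_group: int,
    cells_per_sample: int,
    seed: int = 0,
    *,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Draw per-sample cell-type labels from group-specific multinomials.

    ``group_proportions`` maps a (sex, diet, time) group key to a cell-type ->
    probability mapping (each must sum to 1 within ``tol``). Each group gets
    ``samples_per_group`` samples of ``cells_per_sample`` cells. Returns a cell
    table with columns sample, sex, diet, time, cell_type.
    """
    samples_per_group = _check_count("samples_per_group", samples_per_group, minimum=1)
    cells_per_sample = _check_count("cells_per_sample", cells_per_sample, minimum=1)
    rng = np.random.default_rng(seed)
    frames = []
    for group, probs in group_proportions.items():
        if not (isinstance(group, tuple) and len(group) == 3):
            raise InvalidParameterError(
                f"group key must be a (sex, diet, time) tuple, got {group!r}"
            )
        types = list(probs.keys())
        p = np.asarray([probs[ct] for ct in types], dtype=float)
        if abs(p.sum() - 1.0) > tol:
            raise InvalidParameterError(
                f"probabilities for group {group} sum to {p.sum():.12f}, not 1"
            )
        sex, diet, time = group
        for s in range(samples_per_group):
            sample_id = f"{sex}_{diet}_{time}_s{s + 1}"
            tally = rng.multinomial(cells_per_sample, p / p.sum())
            labels = np.repeat(types, tally)
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sample_id,
                        "sex": sex,
                        "diet": diet,
                        "time": time,
                        "cell_type": labels,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
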