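"""Rank-sum TF prioritization from high-fat / control centrality ratios.

For every TF present in both condition networks, each centrality measure's
HF / control ratio is computed (epsilon-stabilized against zero control
values). Per measure, TFs are ranked by descending ratio, the largest ratio
receiving rank 0 — so TFs whose importance grew most under the high-fat diet
get the smallest ranks. The three ranks are summed into a total score, and the
TFs with the smallest totals (ties broken by eigenvector rank, then
identifier) are selected for in-silico knockout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DivisionError, InvalidParameterError

__all__ = [
    "centrality_ratio",
    "rank_descending",
    "total_score",
    "score_table",
    "select_top_k",
]

MEASURES = ("eigenvector", "degree_out", "betweenness")


def centrality_ratio(
    hf: pd.DataFrame,
    control: pd.DataFrame,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Per-TF, per-measure (hf + eps) / (control + eps) ratios.

    The TF universe is the intersection of the two tables' indices; TFs
    missing from either side are excluded with a warning. With ``epsilon=0``
    a zero control value raises :class:`DivisionError`.
    """
    if epsilon < 0:
        raise InvalidParameterError("epsilon must be >= 0")
    common = hf.index.intersection(control.index)
    dropped = len(hf.index.union(control.index)) - len(common)
    if dropped:
        warnings.warn(
            f"excluding {dropped} TF(s) absent from one of the two conditions",
            stacklevel=2,
        )
    out = {}
    for m in MEASURES:
        num = hf.loc[common, m].astype(float)
        den = control.loc[common, m].astype(float)
        if epsilon == 0 and (den == 0).any():
            raise DivisionError(
                f"zero control {m} centrality with epsilon=0; pass epsilon > 0"
            )
        out[f"ratio_{m}"] = (num + epsilon) / (den + epsilon)
    ratios = pd.DataFrame(out, index=common)
    ratios.index.name = "tf"
    return ratios.sort_index()


def rank_descending(values: pd.Series) -> pd.Series:
    """Integer ranks starting at 0 for the largest value.

    Ties are broken deterministically: by descending value, then by
    lexicographic identifier. Ranks are a permutation of 0..m-1.
    """
    values = values.astype(float)
    if values.isna().any():
        raise InvalidParameterError("rank_descending input contains NaN")
    order = sorted(values.index, key=lambda tf: (-values[tf], str(tf)))
    ranks = pd.Series({tf: i for i, tf in enumerate(order)}, dtype=int)
    return ranks.reindex(values.index)


def total_score(
    rank_eigenvector: pd.Series,
    rank_degree_out: pd.Series,
    rank_betweenness: pd.Series,
) -> pd.Series:
    """Elementwise sum of the three per-measure ranks over one TF universe."""
    idx = set(rank_eigenvector.index)
    if set(rank_degree_out.index) != idx or set(rank_betweenness.index) != idx:
        raise InvalidParameterError("rank vectors cover different TF sets")
    return (
        rank_eigenvector
        + rank_degree_out.reindex(rank_eigenvector.index)
        + rank_betweenness.reindex(rank_eigenvector.index)
    ).astype(int)


def score_table(ratios: pd.DataFrame) -> pd.DataFrame:
    """Full TF score table from a ratio table.

    Input columns ``ratio_eigenvector``, ``ratio_degree_out``,
    ``ratio_betweenness`` (as produced by :func:`centrality_ratio`); output
    adds ``rank_<measure>`` per measure and ``total_score``, sorted ascending
    by total score (ties: eigenvector rank, then identifier).
    """
    out = ratios.copy()
    for m in MEASURES:
        out[f"rank_{m}"] = rank_descending(ratios[f"ratio_{m}"])
    out["total_score"] = total_score(
        out["rank_eigenvector"], out["rank_degree_out"], out["rank_betweenness"]
    )
    order = sorted(
        out.index,
        key=lambda tf: (out.at[tf, "total_score"], out.at[tf, "rank_eigenvector"], str(tf)),
    )
    return out.loc[order]


def select_top_k(scores: pd.DataFrame, k: int) -> list[str]:
    """The k TFs with the smallest total scores, in priority order.

    ``scores`` needs ``total_score`` and ``rank_eigenvector`` columns (a
    :func:`score_table` output or a published rank table). Ties are broken by
    ascending eigenvector rank, then lexicographic identifier.
    """
    m = len(scores)
    if k > m:
        raise InvalidParameterError(f"k={k} exceeds the {m} scored TFs")
    order = sorted(
        scores.index,
        key=lambda tf: (
            scores.at[tf, "total_score"],
            scores.at[tf, "rank_eigenvector"],
            str(tf),
        ),
    )
    return order[:k]
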