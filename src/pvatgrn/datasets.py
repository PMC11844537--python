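"""Bundled reference tables.

Four published TF prioritization tables for brown adipocytes from rat
thoracic-aorta perivascular adipose tissue, one per sex x time-on-diet
analysis (females/males at 8 and 24 weeks on control vs high-fat diet). Each
table lists 20 transcription factors with their per-measure descending-ratio
ranks (eigenvector, degree-out, betweenness; rank 0 = largest high-fat /
control centrality ratio) and the printed rank-sum total score. They serve as
worked examples for the ranking arithmetic and top-k selection.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_rank_tables", "RANK_TABLE_KEYS"]

RANK_TABLE_KEYS = ("females_8w", "females_24w", "males_8w", "males_24w")


def load_rank_tables() -> dict[str, pd.DataFrame]:
    """Load the four bundled 20-TF rank tables, keyed by analysis.

    Each frame is indexed by TF symbol with integer columns
    ``rank_eigenvector``, ``rank_degree_out``, ``rank_betweenness`` and the
    published ``total_score``.
    """
    out = {}
    base = resources.files("pvatgrn").joinpath("data", "rank_tables")
    for key in RANK_TABLE_KEYS:
        with resources.as_file(base.joinpath(f"{key}.tsv")) as path:
            out[key] = pd.read_csv(path, sep="\t", index_col="tf")
    return out
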