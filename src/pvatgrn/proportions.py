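"""Per-sample cell-type proportions and group comparisons.

Each sample's cell-type proportion is its cell count of that type divided by
its total cell count. Group differences are tested with a two-tailed Welch's
t-test (unequal variances, Welch-Satterthwaite degrees of freedom) on the
per-sample proportions, and effect sizes are reported as log2 fold changes of
group-mean proportions relative to a reference treatment group (the 8-week
control-diet male group in the study design this mirrors).

No multiple-testing correction is applied by default — comparisons are
reported at raw p-values — but a Benjamini-Hochberg FDR column can be added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, PvatGrnError

__all__ = [
    "ProportionTable",
    "WelchResult",
    "proportion_table",
    "welch_test",
    "log2fc_vs_reference",
    "compare_groups",
]

GROUP_COLS = ("sex", "diet", "time")


@dataclass
class ProportionTable:
    """Samples x cell-types proportion matrix plus per-sample group factors."""

    proportions: pd.DataFrame  # rows: samples, columns: cell types, rows sum to 1
    groups: pd.DataFrame       # rows: samples, columns: sex, diet, time

    def group_means(self) -> pd.DataFrame:
        """Mean proportion per (sex, diet, time) group and cell type."""
        joined = self.proportions.join(self.groups)
        return joined.groupby(list(self.groups.columns), observed=True)[
            list(self.proportions.columns)
        ].mean()


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def proportion_table(
    cells: pd.DataFrame,
    sample_col: str = "sample",
    type_col: str = "cell_type",
    group_cols: Sequence[str] = GROUP_COLS,
) -> ProportionTable:
    """Tabulate per-sample cell-type proportions.

    ``type_col`` selects the annotation resolution (e.g. a low- or
    high-resolution label column). Samples with zero cells cannot arise from a
    cell table; categorical sample columns with unused levels are dropped with
    a warning.
    """
    for col in (sample_col, type_col):
        if col not in cells.columns:
            raise InvalidParameterError(f"cell table lacks required column {col!r}")
    counts = pd.crosstab(cells[sample_col], cells[type_col])
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"excluding {int(empty.sum())} sample(s) with zero cells", stacklevel=2
        )
        counts = counts.loc[~empty]
    props = counts.div(counts.sum(axis=1), axis=0)
    present = [c for c in group_cols if c in cells.columns]
    groups = (
        cells[[sample_col, *present]].drop_duplicates(sample_col).set_index(sample_col)
    ).loc[props.index]
    props.index.name = "sample"
    props.columns.name = "cell_type"
    return ProportionTable(proportions=props, groups=groups)


def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-tailed Welch's t-test between two samples of proportions.

    t = (mean(x) - mean(y)) / sqrt(s_x^2/n_x + s_y^2/n_y) with unbiased sample
    variances; df from the Welch-Satterthwaite formula; p is the two-tailed
    Student-t tail probability. When both variances are zero the result is
    flagged degenerate: t = 0, p = 1 if the means agree, else t = +/-inf,
    p = 0 (never a silent NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidParameterError("welch_test requires >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        diff = x.mean() - y.mean()
        if diff == 0:
            return WelchResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0, degenerate=True)
        return WelchResult(
            t=float(np.sign(diff)) * np.inf,
            df=float(len(x) + len(y) - 2),
            p=0.0,
            degenerate=True,
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def log2fc_vs_reference(
    props: ProportionTable,
    reference_group: tuple[str, str, str],
    pseudocount: float = 1e-4,
) -> pd.DataFrame:
    """log2 fold change of group-mean proportions relative to a reference group.

    Returns a groups x cell-types matrix of
    ``log2((mean_group + pseudocount) / (mean_ref + pseudocount))``; the
    reference group's row is exactly 0.
    """
    if pseudocount < 0:
        raise InvalidParameterError("pseudocount must be >= 0")
    means = props.group_means()
    if tuple(reference_group) not in means.index:
        raise InvalidParameterError(
            f"reference group {reference_group!r} not present; groups: "
            f"{list(means.index)}"
        )
    ref = means.loc[tuple(reference_group)]
    with np.errstate(divide="ignore"):
        lfc = np.log2((means + pseudocount).div(ref + pseudocount, axis=1))
    lfc.loc[tuple(reference_group)] = 0.0
    return lfc


def compare_groups(
    props: ProportionTable,
    factor: str,
    reference_group: tuple[str, str, str] | None = None,
    pseudocount: float = 1e-4,
    fdr: bool = False,
) -> pd.DataFrame:
    """Welch-test each cell type between the levels of one treatment factor.

    Within every stratum of the remaining group factors, each pair of levels
    of ``factor`` is compared per cell type on per-sample proportions. Output
    columns: cell_type, stratum columns, group_a, group_b, t, df, p (and
    p_adj_bh if ``fdr``), plus each group's log2fc vs the reference group when
    one is given.
    """
    if factor not in props.groups.columns:
        raise InvalidParameterError(f"unknown group factor {factor!r}")
    others = [c for c in props.groups.columns if c != factor]
    joined = props.proportions.join(props.groups)
    lfc = (
        log2fc_vs_reference(props, reference_group, pseudocount)
        if reference_group is not None
        else None
    )
    rows = []
    for stratum, sub in joined.groupby(others, observed=True) if others else [((), joined)]:
        if not isinstance(stratum, tuple):
            stratum = (stratum,)
        levels = sorted(sub[factor].unique())
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                xa = sub.loc[sub[factor] == a]
                xb = sub.loc[sub[factor] == b]
                if len(xa) < 2 or len(xb) < 2:
                    continue
                for ct in props.proportions.columns:
                    res = welch_test(xa[ct].to_numpy(), xb[ct].to_numpy())
                    row = {
                        "cell_type": ct,
                        **dict(zip(others, stratum)),
                        "factor": factor,
                        "group_a": a,
                        "group_b": b,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "degenerate": res.degenerate,
                    }
                    if lfc is not None:
                        full_a = _full_key(others, stratum, factor, a, props)
                        full_b = _full_key(others, stratum, factor, b, props)
                        row["log2fc_a_vs_reference"] = float(lfc.loc[full_a, ct])
                        row["log2fc_b_vs_reference"] = float(lfc.loc[full_b, ct])
                    rows.append(row)
    out = pd.DataFrame(rows)
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adj_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def _full_key(others, stratum, factor, level, props):
    key = dict(zip(others, stratum))
    key[factor] = level
    return tuple(key[c] for c in props.groups.columns)
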