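import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pvatgrn import (
    BaseGRN,
    CountMatrix,
    fit_grn,
    load_rank_tables,
    normalize_expression,
    simulate_cells,
    simulate_grn,
)


@pytest.fixture(scope="session")
def rank_tables():
    return load_rank_tables()


@pytest.fixture(scope="session")
def small_truth():
    return simulate_grn(
        n_tfs=5, n_targets=20, density=0.3, n_drivers=1, effect_size=3.0, seed=7
    )


@pytest.fixture(scope="session")
def small_population(small_truth):
    return simulate_cells(small_truth, n_cells=300, seed=11)


@pytest.fixture(scope="session")
def fitted_pair():
    """One simulated dataset with both condition GRNs fitted (session cache)."""
    truth = simulate_grn(10, 40, 0.3, 1, 3.0, seed=5)
    pop = simulate_cells(truth, n_cells=1500, seed=105)
    expr = normalize_expression(pop.counts, target_sum=2 * pop.counts.n_genes)
    base = BaseGRN(truth.base_edges())
    cond = pop.cells["condition"]
    control = fit_grn(
        expr.loc[(cond == "control").to_numpy()], base, "control", seed=1
    )
    hf = fit_grn(
        expr.loc[(cond == "high-fat").to_numpy()], base, "high-fat", seed=2
    )
    return {"truth": truth, "pop": pop, "expr": expr, "control": control, "hf": hf}


def toy_counts(array, genes=None, barcodes=None) -> CountMatrix:
    array = np.asarray(array)
    genes = genes or [f"g{j}" for j in range(array.shape[1])]
    barcodes = barcodes or [f"c{i}" for i in range(array.shape[0])]
    return CountMatrix(sp.csr_matrix(array), genes, barcodes)


def toy_cells(n, **columns) -> pd.DataFrame:
    base = {"doublet_score": np.zeros(n)}
    base.update(columns)
    return pd.DataFrame(base, index=[f"c{i}" for i in range(n)])
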