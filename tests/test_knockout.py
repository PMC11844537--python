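"""Knockout propagation, vector fields, and perturbation scores."""

import numpy as np
import pandas as pd
import pytest

from pvatgrn import (
    GRNModel,
    VectorField,
    developmental_field,
    ko_field,
    perturbation_score,
    propagate_knockout,
)
from pvatgrn.errors import InvalidParameterError
from pvatgrn.knockout import smooth_expression


def make_model(edges, genes):
    frame = pd.DataFrame(edges, columns=["regulator", "target", "coefficient"])
    frame["sign_consistency"] = 1.0
    return GRNModel(condition="t", edges=frame, genes=genes)


def dense_oracle(x, a, ko_idx, n_steps):
    """Independent explicit-loop re-statement of the propagation recursion."""
    x = np.asarray(x, dtype=float)
    delta = np.zeros_like(x)
    delta[:, ko_idx] = -x[:, ko_idx]
    for _ in range(n_steps):
        sim = np.empty_like(x)
        for c in range(x.shape[0]):
            for g in range(x.shape[1]):
                acc = x[c, g]
                for r in range(x.shape[1]):
                    acc += a[r, g] * delta[c, r]
                sim[c, g] = max(acc, 0.0)
        sim[:, ko_idx] = 0.0
        delta = sim - x
        delta[:, ko_idx] = -x[:, ko_idx]
    return delta


class TestPropagateKnockout:
    def test_tf_without_out_edges_shifts_nothing_else(self):
        model = make_model([("other", "g1", 0.7)], ["tf", "other", "g1"])
        expr = pd.DataFrame(
            np.random.default_rng(0).random((10, 3)) + 1.0,
            columns=["tf", "other", "g1"],
        )
        shift = propagate_knockout(model, expr, "tf", n_steps=3)
        np.testing.assert_allclose(shift["tf"], -expr["tf"])
        assert (shift[["other", "g1"]] == 0).all().all()

    def test_single_edge_one_step_hand_computation(self):
        w = 0.6
        model = make_model([("tf", "g", w)], ["tf", "g"])
        expr = pd.DataFrame({"tf": [2.0, 0.5], "g": [5.0, 5.0]})  # g large: no clipping
        shift = propagate_knockout(model, expr, "tf", n_steps=1)
        np.testing.assert_allclose(shift["g"], [-w * 2.0, -w * 0.5])
        np.testing.assert_allclose(shift["tf"], [-2.0, -0.5])

    def test_matches_dense_iteration_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        a = np.where(rng.random((30, 30)) < 0.15, rng.normal(0, 0.4, (30, 30)), 0.0)
        np.fill_diagonal(a, 0.0)
        edges = [
            (genes[r], genes[t], a[r, t])
            for r in range(30)
            for t in range(30)
            if a[r, t] != 0
        ]
        model = make_model(edges, genes)
        expr = pd.DataFrame(rng.random((12, 30)) * 2, columns=genes)
        for n_steps in (1, 2, 3):
            got = propagate_knockout(model, expr, "g3", n_steps=n_steps)
            want = dense_oracle(expr.to_numpy(), a, 3, n_steps)
            np.testing.assert_allclose(got.to_numpy(), want, atol=1e-10)

    def test_ko_column_is_minus_original(self):
        model = make_model([("tf", "g", 1.0)], ["tf", "g"])
        expr = pd.DataFrame({"tf": [1.0, 3.0], "g": [2.0, 2.0]})
        shift = propagate_knockout(model, expr, "tf", n_steps=3)
        np.testing.assert_allclose(shift["tf"], -expr["tf"])

    def test_absent_tf_rejected(self):
        model = make_model([("tf", "g", 1.0)], ["tf", "g"])
        expr = pd.DataFrame({"tf": [1.0], "g": [1.0]})
        with pytest.raises(InvalidParameterError):
            propagate_knockout(model, expr, "nope")


def lattice_cells(n=40):
    t = np.linspace(0, 1, n)
    return pd.DataFrame(
        {"pseudotime": t, "x": t, "y": np.zeros(n)},
        index=[f"c{i}" for i in range(n)],
    )


class TestDevelopmentalField:
    def test_constant_pseudotime_zero_field(self):
        cells = lattice_cells()
        cells["pseudotime"] = 0.4
        field = developmental_field(cells, k_neighbors=5)
        np.testing.assert_allclose(field.vectors.to_numpy(), 0.0)

    def test_reversing_pseudotime_negates_field(self):
        rng = np.random.default_rng(1)
        cells = pd.DataFrame(
            {
                "pseudotime": rng.random(60),
                "x": rng.random(60),
                "y": rng.random(60),
            },
            index=[f"c{i}" for i in range(60)],
        )
        fwd = developmental_field(cells, k_neighbors=8)
        flipped = cells.assign(pseudotime=1 - cells["pseudotime"])
        rev = developmental_field(flipped, k_neighbors=8)
        np.testing.assert_allclose(fwd.vectors.to_numpy(), -rev.vectors.to_numpy())

    def test_lattice_points_along_positive_axis(self):
        field = developmental_field(lattice_cells(), k_neighbors=4)
        assert (field.vectors["dx"] > 0).all()
        np.testing.assert_allclose(field.vectors["dy"], 0.0, atol=1e-12)

    def test_k_too_large_rejected(self):
        with pytest.raises(InvalidParameterError):
            developmental_field(lattice_cells(10), k_neighbors=10)


class TestKoField:
    def test_zero_shift_gives_zero_field(self):
        rng = np.random.default_rng(2)
        cells = lattice_cells(30)
        expr = pd.DataFrame(rng.random((30, 6)), index=cells.index)
        shift = pd.DataFrame(np.zeros((30, 6)), index=cells.index)
        field = ko_field(shift, expr, cells, k_neighbors=5)
        np.testing.assert_allclose(field.vectors.to_numpy(), 0.0)

    def test_translation_invariance_of_embedding(self):
        rng = np.random.default_rng(3)
        # irregular coordinates: no exact distance ties to flip under shift
        cells = pd.DataFrame(
            {"pseudotime": rng.random(30), "x": rng.random(30), "y": rng.random(30)},
            index=[f"c{i}" for i in range(30)],
        )
        expr = pd.DataFrame(rng.random((30, 6)), index=cells.index)
        shift = pd.DataFrame(rng.normal(size=(30, 6)), index=cells.index)
        f1 = ko_field(shift, expr, cells, k_neighbors=5)
        moved = cells.assign(x=cells["x"] + 10, y=cells["y"] - 4)
        f2 = ko_field(shift, expr, moved, k_neighbors=5)
        np.testing.assert_allclose(
            f1.vectors.to_numpy(), f2.vectors.to_numpy(), atol=1e-9
        )

    def test_two_neighbor_toy_matches_hand_computation(self):
        # three collinear cells; middle cell's neighbors are the two ends
        cells = pd.DataFrame(
            {"pseudotime": [0.0, 0.5, 1.0], "x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]},
            index=["l", "m", "r"],
        )
        expr = pd.DataFrame(
            {"g1": [1.0, 2.0, 3.0], "g2": [3.0, 2.0, 1.0], "g3": [0.0, 1.0, 0.0]},
            index=cells.index,
        )
        shift = pd.DataFrame(
            {"g1": [0, 1.0, 0], "g2": [0, -1.0, 0], "g3": [0, 0.0, 0]},
            index=cells.index,
        )
        field = ko_field(shift, expr, cells, k_neighbors=2, kernel_scale=1.0)
        # hand computation for cell m:
        s = np.array([1.0, -1.0, 0.0])
        sc = s - s.mean()
        vecs = {}
        for nb, xnb in (("l", [1.0, 3.0, 0.0]), ("r", [3.0, 1.0, 0.0])):
            dx = np.array(xnb) - np.array([2.0, 2.0, 1.0])
            dxc = dx - dx.mean()
            vecs[nb] = float(sc @ dxc / (np.linalg.norm(dxc) * np.linalg.norm(sc)))
        w = {k: np.exp(v) for k, v in vecs.items()}
        total = sum(w.values())
        de = {"l": -1.0, "r": 1.0}
        expected_dx = (
            w["l"] / total * de["l"] + w["r"] / total * de["r"]
            - 0.5 * (de["l"] + de["r"])
        )
        assert field.vectors.loc["m", "dx"] == pytest.approx(expected_dx, abs=1e-12)
        assert field.vectors.loc["m", "dy"] == pytest.approx(0.0, abs=1e-12)


class TestPerturbationScore:
    def _field(self, vectors, kind="developmental"):
        return VectorField(
            pd.DataFrame(vectors, columns=["dx", "dy"],
                         index=[f"c{i}" for i in range(len(vectors))]),
            kind=kind,
        )

    def test_aligned_antialigned_orthogonal_unit_fields(self):
        n = 20
        t = pd.Series(np.linspace(0, 1, n), index=[f"c{i}" for i in range(n)])
        dev = self._field([(1.0, 0.0)] * n)
        assert (perturbation_score(dev, self._field([(1.0, 0.0)] * n, "knockout"), t).scores == 1).all()
        assert (perturbation_score(dev, self._field([(-1.0, 0.0)] * n, "knockout"), t).scores == -1).all()
        assert (perturbation_score(dev, self._field([(0.0, 1.0)] * n, "knockout"), t).scores == 0).all()

    def test_negating_dev_field_negates_scores(self):
        rng = np.random.default_rng(5)
        n = 50
        t = pd.Series(rng.random(n), index=[f"c{i}" for i in range(n)])
        dev = self._field(rng.normal(size=(n, 2)))
        ko = self._field(rng.normal(size=(n, 2)), "knockout")
        plus = perturbation_score(dev, ko, t).scores
        neg_dev = VectorField(-dev.vectors, "developmental")
        minus = perturbation_score(neg_dev, ko, t).scores
        np.testing.assert_allclose(plus.to_numpy(), -minus.to_numpy())

    def test_bins_partition_all_cells(self):
        rng = np.random.default_rng(6)
        n = 137
        t = pd.Series(rng.random(n), index=[f"c{i}" for i in range(n)])
        dev = self._field(rng.normal(size=(n, 2)))
        ko = self._field(rng.normal(size=(n, 2)), "knockout")
        ps = perturbation_score(dev, ko, t, n_bins=10)
        assert ps.bin_summary["n"].sum() == n
        assert len(ps.bin_summary) == 10

    def test_mismatched_cells_rejected(self):
        dev = self._field([(1.0, 0.0)] * 5)
        ko = self._field([(1.0, 0.0)] * 4, "knockout")
        with pytest.raises(InvalidParameterError):
            perturbation_score(dev, ko, pd.Series(np.linspace(0, 1, 5)))


def test_knockout_of_edgeless_tf_gives_zero_scores(fitted_pair):
    """A TF absent from all retained edges must produce zero field and scores."""
    model = fitted_pair["hf"]
    expr = fitted_pair["expr"]
    cells = fitted_pair["pop"].cells
    # background genes are never in the base prior, hence never regulators
    tf = next(g for g in expr.columns if g.startswith("B"))
    shift = propagate_knockout(model, expr, tf, n_steps=3)
    others = [c for c in expr.columns if c != tf]
    assert (shift[others].to_numpy() == 0).all()
    sm = smooth_expression(expr, cells, k_neighbors=20)
    shift_sm = propagate_knockout(model, sm, tf, n_steps=3)
    field = ko_field(shift_sm, sm, cells, k_neighbors=10, exclude_gene=tf)
    np.testing.assert_allclose(field.vectors.to_numpy(), 0.0)
    dev = developmental_field(cells, k_neighbors=10)
    ps = perturbation_score(dev, field, cells["pseudotime"])
    np.testing.assert_allclose(ps.scores.to_numpy(), 0.0)
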