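import numpy as np
import pandas as pd
import pytest

from neighborex.de import NeighborDE
from neighborex.graph import NeighborCategory, categorize_cells, delaunay_neighbors
from neighborex.io import ExpressionMatrix


def build_expr(rng, n_genes, groups):
    """Expression with unit blocks named by group; returns (expr, categories)."""
    units, cats = [], []
    mats = []
    for name, center, partner, n, shift in groups:
        ids = [f"{name}{i}" for i in range(n)]
        units += ids
        cats.append(NeighborCategory(center, partner, tuple(ids)))
        m = rng.lognormal(0, 0.3, size=(n_genes, n))
        m[0] *= shift  # gene 0 carries the planted effect
        mats.append(m)
    counts = np.concatenate(mats, axis=1)
    expr = ExpressionMatrix([f"g{i}" for i in range(n_genes)], units, np.zeros_like(counts))
    expr.normalized = counts
    return expr, cats


class TestImageMode:
    def test_planted_gene_called_up(self, rng):
        expr, cats = build_expr(
            rng, 30, [("h", "X", "Y", 100, 3.0), ("o", "X", "X", 100, 1.0)]
        )
        res = NeighborDE(expr, cats, mode="image").fit()
        row = res.table[(res.table.gene == "g0")].iloc[0]
        assert row["called"] and row["direction"] == "up"

    def test_null_world_has_no_excess_calls(self, rng):
        expr, cats = build_expr(
            rng, 300, [("h", "X", "Y", 100, 1.0), ("o", "X", "X", 100, 1.0)]
        )
        res = NeighborDE(expr, cats, mode="image").fit()
        assert len(res.called) <= 3

    def test_missing_homotypic_reference_skips_category(self, rng):
        expr, cats = build_expr(rng, 10, [("h", "X", "Y", 50, 2.0)])
        res = NeighborDE(expr, cats, mode="image").fit()
        assert res.table.empty
        assert res.skipped and "homotypic" in res.skipped[0][1]

    def test_fdr_never_below_p(self, image_dataset):
        cells, expr, truth, _ = image_dataset
        cats = categorize_cells(delaunay_neighbors(cells), cells)
        res = NeighborDE(expr, cats, mode="image").fit()
        assert (res.table["fdr"] >= res.table["p"] - 1e-12).all()
        up = res.table[res.table["log_ratio"] > 0]
        assert (up["direction"] == "up").all()

    def test_pipeline_invariant_to_gene_and_unit_order(self, rng):
        expr, cats = build_expr(
            rng, 20, [("h", "X", "Y", 40, 2.0), ("o", "X", "X", 60, 1.0)]
        )
        res1 = NeighborDE(expr, cats, mode="image").fit()
        gperm = rng.permutation(expr.n_genes)
        uperm = rng.permutation(expr.n_units)
        expr2 = ExpressionMatrix(
            [expr.genes[i] for i in gperm],
            [expr.units[j] for j in uperm],
            expr.counts[np.ix_(gperm, uperm)],
        )
        expr2.normalized = expr.normalized[np.ix_(gperm, uperm)]
        res2 = NeighborDE(expr2, cats, mode="image").fit()
        t1 = res1.table.sort_values(["category", "gene"]).reset_index(drop=True)
        t2 = res2.table.sort_values(["category", "gene"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)


class TestNgsMode:
    @pytest.fixture
    def ngs_world(self, rng):
        """A+B doublets elevated for g0 vs both references; g1 only vs B."""
        n = 60
        units, rows = [], []
        blocks = []
        for name, t1, t2, w, cls in [
            ("a", "A", "", 1.0, "singlet"),
            ("b", "B", "", 1.0, "singlet"),
            ("d", "A", "B", 0.5, "doublet"),
        ]:
            ids = [f"{name}{i}" for i in range(n)]
            units += ids
            rows += [(u, t1, t2, w, cls) for u in ids]
            m = rng.lognormal(0, 0.3, size=(20, n))
            blocks.append(m)
        a, b, d = blocks
        d[0] *= 3.0  # g0: true contact signal vs both references
        b[1] /= 3.0  # g1: elevated vs B only (asymmetric baseline)
        expr = ExpressionMatrix([f"g{i}" for i in range(20)], units, np.zeros((20, 3 * n)))
        expr.normalized = np.concatenate([a, b, d], axis=1)
        deconv = pd.DataFrame(
            rows, columns=["spot_id", "first_type", "second_type", "first_prop", "spot_class"]
        )
        return expr, deconv

    def test_both_references_rule(self, ngs_world):
        expr, deconv = ngs_world
        res = NeighborDE.from_spots(expr, deconv, null_merge_scale="normalized").fit(
            n_reps=20, seed=0
        )
        t = res.table.set_index("gene")
        assert bool(t.loc["g0", "called"])
        assert not bool(t.loc["g1", "called"])  # passes vs B only

    def test_pooled_reference_alternative(self, ngs_world):
        expr, deconv = ngs_world
        res = NeighborDE.from_spots(
            expr, deconv, pooled_homotypic=True, null_merge_scale="normalized"
        ).fit(n_reps=20, seed=0)
        assert bool(res.table.set_index("gene").loc["g0", "called"])

    def test_null_validation_passes_contact_gene(self, ngs_world):
        expr, deconv = ngs_world
        model = NeighborDE.from_spots(expr, deconv, null_merge_scale="normalized")
        res = model.fit(n_reps=50, seed=0)
        assert res.table.set_index("gene").loc["g0", "null_validated"] is True

    def test_pure_mixture_fails_null_validation(self, rng):
        # doublets constructed as the exact weighted mix of singlet profiles
        n = 60
        a = rng.lognormal(0.8, 0.3, size=(15, n))
        b = rng.lognormal(-0.8, 0.3, size=(15, n))
        w = 0.5
        d = w * a[:, rng.integers(0, n, n)] + (1 - w) * b[:, rng.integers(0, n, n)]
        units = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)] + [
            f"d{i}" for i in range(n)
        ]
        expr = ExpressionMatrix([f"g{i}" for i in range(15)], units, np.zeros((15, 3 * n)))
        expr.normalized = np.concatenate([a, b, d], axis=1)
        deconv = pd.DataFrame(
            [(f"a{i}", "A", "", 1.0, "singlet") for i in range(n)]
            + [(f"b{i}", "B", "", 1.0, "singlet") for i in range(n)]
            + [(f"d{i}", "A", "B", w, "doublet") for i in range(n)],
            columns=["spot_id", "first_type", "second_type", "first_prop", "spot_class"],
        )
        model = NeighborDE.from_spots(expr, deconv, null_merge_scale="normalized")
        val = model.null_validation("A+B", [f"g{i}" for i in range(15)], n_reps=50, seed=4)
        assert not val["passes"].any()

    def test_identical_het_and_artificial_gives_zero_passes(self, rng):
        # degenerate: singletons pools identical constant -> het == artificial
        n = 40
        base = rng.lognormal(0, 0.2, size=(10, 1))
        block = np.tile(base, (1, n))
        units = (
            [f"a{i}" for i in range(n)]
            + [f"b{i}" for i in range(n)]
            + [f"d{i}" for i in range(n)]
        )
        expr = ExpressionMatrix([f"g{i}" for i in range(10)], units, np.zeros((10, 3 * n)))
        expr.normalized = np.concatenate([block, block, block], axis=1)
        deconv = pd.DataFrame(
            [(f"a{i}", "A", "", 1.0, "singlet") for i in range(n)]
            + [(f"b{i}", "B", "", 1.0, "singlet") for i in range(n)]
            + [(f"d{i}", "A", "B", 0.5, "doublet") for i in range(n)],
            columns=["spot_id", "first_type", "second_type", "first_prop", "spot_class"],
        )
        model = NeighborDE.from_spots(expr, deconv, null_merge_scale="normalized")
        val = model.null_validation("A+B", [f"g{i}" for i in range(10)], n_reps=20, seed=1)
        assert not val["passes"].any()


class TestOutputs:
    def test_tsv_outputs_and_summary(self, rng, tmp_path):
        expr, cats = build_expr(
            rng, 15, [("h", "X", "Y", 40, 3.0), ("o", "X", "X", 60, 1.0)]
        )
        res = NeighborDE(expr, cats, mode="image").fit()
        paths = res.to_tsv(tmp_path)
        assert any(p.endswith("de_summary.tsv") for p in paths)
        summary = pd.read_csv(tmp_path / "de_summary.tsv", sep="\t")
        assert summary.loc[0, "n_up"] >= 1
        cat_file = pd.read_csv(tmp_path / "de_X+Y.tsv", sep="\t")
        assert set(["gene", "log_ratio", "p", "fdr", "test", "direction"]) <= set(cat_file.columns)
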