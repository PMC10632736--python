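import numpy as np
import pandas as pd
import pytest

from neighborex.graph import (
    categorize_cells,
    delaunay_neighbors,
    knn_neighbors,
    mutual_knn_neighbors,
    prune_by_radius,
    radial_neighbors,
)

from _oracles import delaunay_edges_oracle
from conftest import random_cells


def cells_from(points, types=None):
    points = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(points))],
            "x": points[:, 0],
            "y": points[:, 1],
            "cell_type": types or ["T1"] * len(points),
        }
    )


def edge_index_set(g):
    return {tuple(sorted((int(a[1:]), int(b[1:])))) for a, b in g.edges}


class TestDelaunay:
    def test_triangle_is_complete(self):
        g = delaunay_neighbors(cells_from([(0, 0), (1, 0), (0, 1)]))
        assert len(g.edges) == 3

    def test_square_matches_circumcircle_oracle(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        g = delaunay_neighbors(cells_from(pts))
        assert edge_index_set(g) >= delaunay_edges_oracle(pts) - {(1, 3), (0, 2)}
        assert all(g.degree(n) >= 2 for n in g.nodes)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, size=(50, 2))
        g = delaunay_neighbors(cells_from(pts))
        assert edge_index_set(g) == delaunay_edges_oracle(pts)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            delaunay_neighbors(cells_from([(0, 0), (0, 0), (1, 1), (2, 0)]))

    def test_collinear_fallback_warns(self):
        with pytest.warns(UserWarning, match="complete graph"):
            g = delaunay_neighbors(cells_from([(0, 0), (1, 0), (2, 0)]))
        assert len(g.edges) == 3


class TestKnnRadial:
    def test_collinear_k1(self):
        g = knn_neighbors(cells_from([(0, 0), (1, 0), (3, 0)]), k=1)
        assert {tuple(sorted(e)) for e in edge_index_set(g)} == {(0, 1), (1, 2)}

    def test_k_equals_n_minus_1_complete(self, rng):
        cells = random_cells(rng, 8)
        g = knn_neighbors(cells, k=7)
        assert len(g.edges) == 8 * 7 // 2

    def test_knn_matches_exhaustive_distances(self, rng):
        cells = random_cells(rng, 30)
        k = 4
        g = knn_neighbors(cells, k=k)
        pts = cells[["x", "y"]].to_numpy()
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        expected = set()
        for i in range(30):
            for j in np.argsort(d[i], kind="stable")[:k]:
                expected.add(tuple(sorted((i, int(j)))))
        assert edge_index_set(g) == expected

    def test_mutual_knn_is_subset_of_union_knn(self, rng):
        cells = random_cells(rng, 25)
        union = knn_neighbors(cells, k=3)
        mutual = mutual_knn_neighbors(cells, k=3)
        assert mutual.edges <= union.edges

    def test_radial_extremes(self, rng):
        cells = random_cells(rng, 12)
        pts = cells[["x", "y"]].to_numpy()
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dmin = d[d > 0].min()
        assert len(radial_neighbors(cells, r=0.5 * dmin).edges) == 0
        assert len(radial_neighbors(cells, r=d.max() + 1).edges) == 12 * 11 // 2

    def test_radial_matches_thresholding(self, rng):
        cells = random_cells(rng, 30)
        pts = cells[["x", "y"]].to_numpy()
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        # midpoint between two realized distances so <= r is unambiguous
        ds = np.sort(d[np.triu_indices(30, 1)])
        r = float(0.5 * (ds[len(ds) // 2] + ds[len(ds) // 2 + 1]))
        g = radial_neighbors(cells, r=r)
        expected = {
            (i, j) for i in range(30) for j in range(i + 1, 30) if d[i, j] <= r
        }
        assert edge_index_set(g) == expected

    def test_graphs_are_symmetric_and_loop_free(self, rng):
        cells = random_cells(rng, 20)
        for g in (delaunay_neighbors(cells), knn_neighbors(cells, 3),
                  radial_neighbors(cells, 0.3)):
            assert all(a != b for a, b in g.edges)
            assert all(a <= b for a, b in g.edges)  # canonical undirected form


class TestPrune:
    def test_infinite_radius_is_identity(self, rng):
        cells = random_cells(rng, 15)
        g = delaunay_neighbors(cells)
        assert prune_by_radius(g, cells, r=np.inf).edges == g.edges

    def test_outlier_isolated_after_pruning(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1), (10, 0.5)]
        cells = cells_from(pts)
        g = delaunay_neighbors(cells)
        pruned = prune_by_radius(g, cells, r=2.0)
        assert pruned.degree("c4") == 0
        assert pruned.edges <= g.edges


class TestCategorize:
    def test_membership_rules(self):
        # line of cells: X X X Y Z with k-ish adjacency via delaunay on a band
        pts = [(0, 0), (1, 0), (2, 0), (3, 0.01), (3.5, -0.01), (1, 1), (2, 1)]
        types = ["X", "X", "X", "Y", "Z", "X", "X"]
        cells = cells_from(pts, types)
        g = delaunay_neighbors(cells)
        cats = {c.label: set(c.members) for c in categorize_cells(g, cells, min_members=1)}
        # pure-X cells fall in X/X; X cells adjacent to Y join X+Y, etc.
        assert "X/X" in cats and "X+Y" in cats
        assert not (cats["X/X"] & cats.get("X+Y", set()))
        assert not (cats["X/X"] & cats.get("X+Z", set()))

    def test_multi_partner_cell_joins_both_categories(self):
        pts = [(0, 0), (1, 0), (0.5, 1), (0.5, -1)]
        types = ["X", "Y", "Z", "X"]
        cells = cells_from(pts, types)
        g = delaunay_neighbors(cells)
        cats = {c.label: set(c.members) for c in categorize_cells(g, cells, min_members=1)}
        assert "c0" in cats["X+Y"] and "c0" in cats["X+Z"]
        assert "X/X" not in cats or "c0" not in cats["X/X"]

    def test_homotypic_disjoint_from_heterotypic(self, rng):
        cells = random_cells(rng, 120, n_types=3)
        g = delaunay_neighbors(cells)
        cats = categorize_cells(g, cells, min_members=1)
        for t in ("T1", "T2", "T3"):
            homo = {m for c in cats if c.label == f"{t}/{t}" for m in c.members}
            het = {
                m
                for c in cats
                if c.center_type == t and not c.homotypic
                for m in c.members
            }
            assert not homo & het

    def test_invariant_to_cell_ordering(self, rng):
        cells = random_cells(rng, 60, n_types=3)
        shuffled = cells.sample(frac=1, random_state=1).reset_index(drop=True)
        c1 = categorize_cells(delaunay_neighbors(cells), cells, min_members=1)
        c2 = categorize_cells(delaunay_neighbors(shuffled), shuffled, min_members=1)
        as_map = lambda cs: {c.label: set(c.members) for c in cs}
        assert as_map(c1) == as_map(c2)

    def test_min_members_drops_small_categories(self, rng):
        cells = random_cells(rng, 60, n_types=3)
        g = delaunay_neighbors(cells)
        big = categorize_cells(g, cells, min_members=1000)
        assert big == []
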