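"""Immediate-neighbor graphs from cell coordinates, and niche categorization.

For image-based spatial data the physical neighbors of each cell are found
by Delaunay triangulation, k-nearest neighbors, or a radial distance cutoff
(Delaunay optionally pruned by a radius to remove long convex-hull edges).
Cells are then grouped by their neighborhood composition: a cell surrounded
exclusively by its own type belongs to the homotypic group of that type; a
cell touching one or more foreign types belongs to a heterotypic group for
each distinct foreign partner type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Undirected, self-loop-free contact graph over cell ids."""

    nodes: list[str]
    edges: set[tuple[str, str]]  # canonical: (min, max) by string order
    method: str

    def __post_init__(self) -> None:
        known = set(self.nodes)
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            canon.add((a, b) if a <= b else (b, a))
        self.edges = canon

    def neighbors_of(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degree(self, node: str) -> int:
        return sum(node in e for e in self.edges)

    def to_frame(self, cells: pd.DataFrame | None = None) -> pd.DataFrame:
        rows = sorted(self.edges)
        df = pd.DataFrame(rows, columns=["cell_a", "cell_b"])
        if cells is not None:
            xy = cells.set_index("cell_id")[["x", "y"]]
            pa = xy.loc[df["cell_a"]].to_numpy()
            pb = xy.loc[df["cell_b"]].to_numpy()
            df["length"] = np.hypot(*(pa - pb).T)
        return df


@dataclass(frozen=True)
class NeighborCategory:
    """Cells/spots sharing one niche context (center type, partner type)."""

    center_type: str
    partner_type: str
    members: tuple[str, ...]

    @property
    def homotypic(self) -> bool:
        return self.center_type == self.partner_type

    @property
    def label(self) -> str:
        sep = "/" if self.homotypic else "+"
        return f"{self.center_type}{sep}{self.partner_type}"

    def __len__(self) -> int:
        return len(self.members)


def _coords(cells: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    ids = cells["cell_id"].astype(str).tolist()
    pts = cells[["x", "y"]].to_numpy(dtype=float)
    return pts, ids


def _check_duplicates(pts: np.ndarray, ids: list[str]) -> None:
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        dup_groups = [
            [ids[i] for i in np.flatnonzero(inverse == g)]
            for g in np.flatnonzero(counts > 1)
        ]
        raise ValueError(
            f"duplicate coordinates for cells {dup_groups[:3]}; deduplicate before "
            "building a triangulation"
        )


def delaunay_neighbors(cells: pd.DataFrame) -> NeighborGraph:
    """Contact graph from the Delaunay triangulation of cell centroids."""
    pts, ids = _coords(cells)
    _check_duplicates(pts, ids)
    n = len(ids)
    if n < 3 or np.linalg.matrix_rank(pts - pts[0]) < 2:
        warnings.warn(
            "fewer than 3 non-collinear points; falling back to complete graph",
            stacklevel=2,
        )
        edges = {(ids[i], ids[j]) for i, j in combinations(range(n), 2)}
        return NeighborGraph(ids, edges, "delaunay")
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i, j in combinations(simplex, 2):
            edges.add((ids[i], ids[j]))
    return NeighborGraph(ids, edges, "delaunay")


def knn_neighbors(cells: pd.DataFrame, k: int) -> NeighborGraph:
    """Symmetrized k-nearest-neighbor graph (union of directed kNN edges).

    Distance ties are broken by input order; ``mutual=True`` via
    :func:`mutual_knn_neighbors` keeps only reciprocated edges.
    """
    pts, ids = _coords(cells)
    n = len(ids)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells (got k={k}, n={n})")
    directed = _knn_directed(pts, k)
    edges = {(ids[i], ids[j]) for i, j in directed}
    return NeighborGraph(ids, edges, "knn")


def mutual_knn_neighbors(cells: pd.DataFrame, k: int) -> NeighborGraph:
    """Mutual-kNN variant: edge only when each point is in the other's k set."""
    pts, ids = _coords(cells)
    n = len(ids)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells (got k={k}, n={n})")
    directed = _knn_directed(pts, k)
    edges = {(ids[i], ids[j]) for i, j in directed if (j, i) in directed}
    return NeighborGraph(ids, edges, "knn-mutual")


def _knn_directed(pts: np.ndarray, k: int) -> set[tuple[int, int]]:
    d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
    np.fill_diagonal(d, np.inf)
    out = set()
    for i in range(len(pts)):
        # stable sort => ties broken by index order (logged once)
        order = np.argsort(d[i], kind="stable")[:k]
        for j in order:
            out.add((i, int(j)))
    return out


def radial_neighbors(cells: pd.DataFrame, r: float) -> NeighborGraph:
    """Edge between every pair of cells within Euclidean distance ``r``."""
    if r <= 0:
        raise ValueError("radius must be positive")
    pts, ids = _coords(cells)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r)
    edges = {(ids[i], ids[j]) for i, j in pairs}
    return NeighborGraph(ids, edges, "radial")


def prune_by_radius(
    g: NeighborGraph, cells: pd.DataFrame, r: float | None = None
) -> NeighborGraph:
    """Drop edges longer than ``r``; default r = 95th pct of edge lengths.

    Used mainly to remove spurious long Delaunay edges along the convex hull.
    """
    xy = cells.set_index(cells["cell_id"].astype(str))[["x", "y"]]
    lengths = {
        e: float(np.hypot(*(xy.loc[e[0]] - xy.loc[e[1]])))
        for e in g.edges
    }
    if r is None:
        if not lengths:
            return NeighborGraph(list(g.nodes), set(), g.method + "+radial")
        r = float(np.percentile(list(lengths.values()), 95))
    edges = {e for e, l in lengths.items() if l <= r}
    return NeighborGraph(list(g.nodes), edges, g.method + "+radial")


def categorize_cells(
    g: NeighborGraph,
    cells: pd.DataFrame,
    min_members: int = 10,
    exclusive_nearest: bool = False,
) -> list[NeighborCategory]:
    """Group cells into homotypic and heterotypic niche categories.

    A cell of type X whose neighbors are all X joins the homotypic category
    X/X. A cell of type X with foreign neighbors joins a heterotypic
    category X+Y for every distinct foreign neighbor type Y (or, with
    ``exclusive_nearest``, only the category of its nearest foreign
    neighbor). Categories smaller than ``min_members`` are dropped.
    Membership is independent of the input ordering of cells.
    """
    ctype = dict(zip(cells["cell_id"].astype(str), cells["cell_type"].astype(str)))
    unknown = [n for n in g.nodes if n not in ctype]
    if unknown:
        raise ValueError(f"nodes without a cell type: {unknown[:5]}")
    xy = cells.set_index(cells["cell_id"].astype(str))[["x", "y"]]
    adj = g.neighbors_of()
    members: dict[tuple[str, str], list[str]] = {}
    n_isolated = 0
    for node in g.nodes:
        nbrs = adj[node]
        if not nbrs:
            n_isolated += 1
            continue
        x = ctype[node]
        foreign = sorted({ctype[nb] for nb in nbrs if ctype[nb] != x})
        if not foreign:
            members.setdefault((x, x), []).append(node)
        elif exclusive_nearest:
            fnbrs = [nb for nb in nbrs if ctype[nb] != x]
            p0 = xy.loc[node].to_numpy(dtype=float)
            nearest = min(
                fnbrs,
                key=lambda nb: (float(np.hypot(*(xy.loc[nb].to_numpy(dtype=float) - p0))), nb),
            )
            members.setdefault((x, ctype[nearest]), []).append(node)
        else:
            for y in foreign:
                members.setdefault((x, y), []).append(node)
    if n_isolated:
        warnings.warn(f"dropped {n_isolated} isolated cells", stacklevel=2)
    cats = []
    for (x, y), mem in sorted(members.items()):
        if len(mem) < min_members:
            logger.info("dropping category %s+%s with %d members", x, y, len(mem))
            continue
        cats.append(NeighborCategory(x, y, tuple(sorted(mem))))
    return cats
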