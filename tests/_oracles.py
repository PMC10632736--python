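"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: closed-form statistics
are recomputed from first principles with plain Python arithmetic, the
Delaunay check enumerates empty circumcircles, and the U statistic is a
direct pairwise comparison count.
"""

import math
from itertools import combinations

import numpy as np


def student_t_oracle(a, b):
    """Pooled-variance t statistic from the textbook formula."""
    a, b = list(map(float, a)), list(map(float, b))
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    return (m1 - m2) / (sp * math.sqrt(1 / n1 + 1 / n2))


def welch_t_oracle(a, b):
    """Welch t statistic and Satterthwaite df from the textbook formulas."""
    a, b = list(map(float, a)), list(map(float, b))
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1) / n1
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1) / n2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df


def mann_whitney_u_oracle(a, b):
    """U = min over groups of the pairwise win count (ties count half)."""
    u1 = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    u2 = sum((y > x) + 0.5 * (x == y) for x in a for y in b)
    return min(u1, u2)


def bh_oracle(p):
    """Benjamini-Hochberg step-up by explicit sorting and cumulative min."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def delaunay_edges_oracle(pts, eps=1e-9):
    """Delaunay edge set via exhaustive empty-circumcircle triangles.

    An edge belongs to the Delaunay graph iff it is an edge of some
    triangle whose circumcircle contains no other input point strictly
    inside. Vectorized over all triples; assumes points in general
    position (no duplicates).
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    triples = np.array(list(combinations(range(n), 3)))
    a, b, c = pts[triples[:, 0]], pts[triples[:, 1]], pts[triples[:, 2]]
    d = 2 * (a[:, 0] * (b[:, 1] - c[:, 1]) + b[:, 0] * (c[:, 1] - a[:, 1]) + c[:, 0] * (a[:, 1] - b[:, 1]))
    degenerate = np.abs(d) < eps
    aa = (a**2).sum(1)
    bb = (b**2).sum(1)
    cc = (c**2).sum(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = (aa * (b[:, 1] - c[:, 1]) + bb * (c[:, 1] - a[:, 1]) + cc * (a[:, 1] - b[:, 1])) / d
        uy = (aa * (c[:, 0] - b[:, 0]) + bb * (a[:, 0] - c[:, 0]) + cc * (b[:, 0] - a[:, 0])) / d
    centers = np.column_stack([ux, uy])
    radii2 = ((a - centers) ** 2).sum(1)
    # distance of every point to every circumcenter
    dist2 = ((pts[None, :, :] - centers[:, None, :]) ** 2).sum(-1)
    inside = dist2 < radii2[:, None] * (1 - 1e-12) - eps
    # ignore the three defining points
    rows = np.arange(len(triples))
    for k in range(3):
        inside[rows, triples[:, k]] = False
    empty = ~inside.any(axis=1) & ~degenerate
    edges = set()
    for t in triples[empty]:
        for i, j in combinations(sorted(t), 2):
            edges.add((i, j))
    return edges
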