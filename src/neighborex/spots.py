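"""NGS-mode niche groups, the artificial-spot null model, and annotation checks.

Barcoded-bead platforms near cellular resolution yield spots containing one
cell type (singlets, "homotypic spots") or two (doublets, "heterotypic
spots"), as called by a doublet-mode deconvolution tool that also estimates
the first type's transcript proportion. Heterotypic spots are treated as
evidence of direct cell contact.

The null model builds *artificial* heterotypic spots: for a true doublet
with types (A, B) and weight w, each replicate is w*a + (1-w)*b where a and
b are homotypic spots of types A and B drawn at random. Such spots carry the
pure mixture signal without any contact-induced expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import NeighborCategory
from .io import ExpressionMatrix, MarkerSet, validate_deconvolution

logger = logging.getLogger(__name__)


@dataclass
class ArtificialSpotSet:
    """Resampled mixture replicates for one true heterotypic spot."""

    template_spot: str
    pair: tuple[str, str]  # canonical (lexicographic) order
    weight: float  # proportion of pair[0]
    replicates: np.ndarray  # (n_reps, n_genes)
    seed: int


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def classify_spots(
    deconv: pd.DataFrame, min_members: int = 10
) -> list[NeighborCategory]:
    """Group spots into homotypic (A/A) and heterotypic (A+B) categories.

    Doublets (A, B) and (B, A) land in the same category under lexicographic
    canonicalization. Categories below ``min_members`` are dropped.
    """
    validate_deconvolution(deconv)
    members: dict[tuple[str, str], list[str]] = {}
    for row in deconv.itertuples(index=False):
        if row.spot_class == "singlet":
            key = (str(row.first_type), str(row.first_type))
        else:
            key = canonical_pair(str(row.first_type), str(row.second_type))
        members.setdefault(key, []).append(str(row.spot_id))
    cats = []
    for (a, b), mem in sorted(members.items()):
        if len(mem) < min_members:
            logger.info("dropping spot category %s/%s with %d members", a, b, len(mem))
            continue
        cats.append(NeighborCategory(a, b, tuple(sorted(mem))))
    return cats


def doublet_weights(deconv: pd.DataFrame) -> dict[str, float]:
    """Per doublet spot, the proportion of the canonical pair's first type."""
    out = {}
    for row in deconv[deconv["spot_class"] == "doublet"].itertuples(index=False):
        a, b = str(row.first_type), str(row.second_type)
        w = float(row.first_prop)
        if canonical_pair(a, b)[0] != a:
            w = 1.0 - w
        out[str(row.spot_id)] = w
    return out


def make_artificial_spots(
    het_spot: str,
    weight: float,
    pair: tuple[str, str],
    pool_a: np.ndarray,
    pool_b: np.ndarray,
    n_reps: int = 100,
    seed: int = 0,
) -> ArtificialSpotSet:
    """Build ``n_reps`` mixture replicates for one heterotypic spot.

    ``pool_a``/``pool_b`` are (n_spots, n_genes) normalized-expression
    matrices of the homotypic pools for the two constituent types (in
    canonical pair order); sampling is uniform with replacement.
    """
    if not 0 <= weight <= 1:
        raise ValueError("weight must lie in [0, 1]")
    for name, pool in (("first", pool_a), ("second", pool_b)):
        if pool.ndim != 2 or pool.shape[0] == 0:
            raise ValueError(
                f"empty homotypic pool for the {name} type of pair {pair}"
            )
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, pool_a.shape[0], size=n_reps)
    ib = rng.integers(0, pool_b.shape[0], size=n_reps)
    reps = weight * pool_a[ia] + (1.0 - weight) * pool_b[ib]
    return ArtificialSpotSet(het_spot, pair, weight, reps, seed)


def homotypic_pools(
    expr: ExpressionMatrix,
    categories: list[NeighborCategory],
    layer: str = "normalized",
) -> dict[str, np.ndarray]:
    """(n_spots, n_genes) expression pool per homotypic type.

    ``layer`` selects normalized values (for correlation checks and
    normalized-scale merging) or raw counts (for count-scale merging).
    """
    mat = expr.counts if layer == "counts" else expr._require_normalized()
    pools = {}
    for cat in categories:
        if cat.homotypic:
            idx = expr.unit_indices(cat.members)
            pools[cat.center_type] = np.asarray(mat[:, idx].T, dtype=float).copy()
    return pools


def validate_by_correlation(
    expr: ExpressionMatrix,
    deconv: pd.DataFrame,
    categories: list[NeighborCategory],
    n_reps: int = 100,
    seed: int = 0,
    aggregate: str = "mean_corr",
) -> pd.DataFrame:
    """Check heterotypic annotations against all candidate mixture pairs.

    For every true heterotypic spot, artificial spots are built for each
    unordered pair of types with a homotypic pool, using the spot's own
    weight. Pearson correlation between the true spot and each replicate is
    averaged per pair (``aggregate='mean_corr'``; ``'corr_of_mean'``
    correlates against the replicate-mean profile instead), and the spot is
    valid when the best-correlated pair matches its annotation.

    Returns a frame (spot_id, pair, best_pair, valid, reason).
    """
    if aggregate not in ("mean_corr", "corr_of_mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    norm = expr._require_normalized()
    pools = homotypic_pools(expr, categories)
    types = sorted(pools)
    if len(types) < 2:
        raise ValueError("need homotypic pools for at least 2 cell types")
    candidate_pairs = [
        (a, b) for i, a in enumerate(types) for b in types[i + 1 :]
    ]
    weights = doublet_weights(deconv)
    rng = np.random.default_rng(seed)
    rows = []
    het_cats = [c for c in categories if not c.homotypic]
    for cat in het_cats:
        pair = canonical_pair(cat.center_type, cat.partner_type)
        for spot in cat.members:
            x = norm[:, expr.unit_indices([spot])[0]]
            if np.ptp(x) == 0:
                rows.append((spot, pair, None, False, "constant_expression"))
                continue
            w = weights.get(spot, 0.5)
            best_pair, best_score = None, -np.inf
            for cand in candidate_pairs:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                aset = make_artificial_spots(
                    spot, w, cand, pools[cand[0]], pools[cand[1]],
                    n_reps=n_reps, seed=sub_seed,
                )
                score = _corr_score(x, aset.replicates, aggregate)
                if score > best_score:
                    best_pair, best_score = cand, score
            valid = best_pair == pair
            rows.append((spot, pair, best_pair, valid, "" if valid else "argmax_mismatch"))
    return pd.DataFrame(
        rows, columns=["spot_id", "pair", "best_pair", "valid", "reason"]
    )


def _corr_score(x: np.ndarray, reps: np.ndarray, aggregate: str) -> float:
    if aggregate == "corr_of_mean":
        reps = reps.mean(axis=0, keepdims=True)
    xc = x - x.mean()
    xs = np.sqrt((xc**2).sum())
    rc = reps - reps.mean(axis=1, keepdims=True)
    rs = np.sqrt((rc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corrs = (rc @ xc) / (rs * xs)
    corrs = corrs[np.isfinite(corrs)]
    return float(corrs.mean()) if corrs.size else -np.inf


def validate_by_markers(
    expr: ExpressionMatrix,
    categories: list[NeighborCategory],
    markers: list[MarkerSet],
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Require each heterotypic spot to express a marker of both its types.

    A spot is valid when, for each constituent type, at least one of that
    type's markers has expression > 0 in the spot. A category passes when at
    least ``min_fraction`` of its spots are valid. Returns a per-category
    frame (pair, n_spots, n_valid, fraction_valid, passes).
    """
    norm = expr._require_normalized()
    marker_idx: dict[str, np.ndarray] = {}
    gene_pos = {g: i for i, g in enumerate(expr.genes)}
    for ms in markers:
        idx = [gene_pos[g] for g in ms.markers if g in gene_pos]
        if idx:
            marker_idx[ms.cell_type] = np.array(idx, dtype=int)
    rows = []
    for cat in categories:
        if cat.homotypic:
            continue
        pair = canonical_pair(cat.center_type, cat.partner_type)
        if pair[0] not in marker_idx or pair[1] not in marker_idx:
            warnings.warn(
                f"missing marker set for category {cat.label}; skipped", stacklevel=2
            )
            continue
        idx = expr.unit_indices(cat.members)
        sub = norm[:, idx]
        ok_a = (sub[marker_idx[pair[0]], :] > 0).any(axis=0)
        ok_b = (sub[marker_idx[pair[1]], :] > 0).any(axis=0)
        valid = ok_a & ok_b
        frac = float(valid.mean())
        rows.append(
            (f"{pair[0]}+{pair[1]}", len(cat), int(valid.sum()), frac, frac >= min_fraction)
        )
    return pd.DataFrame(
        rows, columns=["pair", "n_spots", "n_valid", "fraction_valid", "passes"]
    )
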