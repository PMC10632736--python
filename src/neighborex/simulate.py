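"""Synthetic spatial-transcriptomics data with known ground truth.

Two generators mirror the two data regimes the analysis supports:

* image mode — cells with exact coordinates laid out in spatial type
  domains (vertical stripes per cell type), so contact zones exist along
  the stripe borders; counts are negative binomial and *contact-planted*
  genes are multiplicatively elevated in cells whose true Delaunay
  neighbors include the partner type.
* NGS mode — singlet and doublet bead spots; a doublet of pair (A, B)
  with weight w has expected expression w*mu_A + (1-w)*mu_B, with
  contact-planted genes elevated beyond the mixture and *mixing-only*
  genes elevated in doublets purely through the asymmetry of their
  baseline between the two types (no contact effect) — exactly the signal
  the artificial-spot null model is designed to absorb.

Every cell type carries a block of signature genes (elevated baseline)
which double as marker sets and make type profiles separable for the
correlation-based annotation check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MarkerSet
from .graph import delaunay_neighbors
from .spots import canonical_pair


@dataclass(frozen=True)
class PlantedEffect:
    """A contact-induced expression change for one gene in one niche."""

    gene: str
    center_type: str
    partner_type: str
    log2_fc: float


@dataclass(frozen=True)
class MixingGene:
    """A gene asymmetric between two types but with no contact effect."""

    gene: str
    high_type: str
    low_type: str


@dataclass
class SimConfig:
    """Parameters of the synthetic generators.

    Baseline counts are negative binomial with per-gene means drawn
    lognormal around ``base_mean`` and common ``dispersion`` (variance
    m + m^2/dispersion). Each type's signature block is elevated by
    ``signature_strength``. Planted and mixing genes get a flat moderate
    baseline so the planted fold change is the estimand.
    """

    seed: int = 0
    n_units: int = 2000
    n_types: int = 4
    n_genes: int = 500
    dispersion: float = 10.0
    base_mean: float = 2.0
    signature_fraction: float = 0.1
    signature_strength: float = 8.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    mixing_only: tuple[MixingGene, ...] = ()
    mixing_strength: float = 4.0
    doublet_fraction: float = 0.5
    proportion_beta: tuple[float, float] = (2.0, 2.0)
    distribution: str = "nb"  # nb | poisson

    def __post_init__(self) -> None:
        if not 0 <= self.doublet_fraction <= 1:
            raise ValueError("doublet_fraction must lie in [0, 1]")
        if self.distribution not in ("nb", "poisson"):
            raise ValueError("distribution must be 'nb' or 'poisson'")
        planted = {p.gene for p in self.planted_effects}
        mixing = {m.gene for m in self.mixing_only}
        if planted & mixing:
            raise ValueError(
                f"genes cannot be both contact-planted and mixing-only: "
                f"{sorted(planted & mixing)}"
            )
        for p in self.planted_effects:
            if not np.isfinite(p.log2_fc):
                raise ValueError(f"non-finite fold change for {p.gene}")

    @property
    def types(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_types)]

    @property
    def genes(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]


def baseline_means(cfg: SimConfig) -> pd.DataFrame:
    """Per-type per-gene negative-binomial means (genes x types frame).

    Deterministic given ``cfg.seed``. Signature blocks are consecutive
    gene slices per type, skipping planted/mixing genes; planted and
    mixing genes get the flat ``base_mean`` baseline (mixing genes then
    scaled up/down in their high/low type).
    """
    rng = np.random.default_rng(cfg.seed)
    genes, types = cfg.genes, cfg.types
    base = np.exp(rng.normal(np.log(cfg.base_mean), 0.5, size=cfg.n_genes))
    mu = np.tile(base[:, None], (1, cfg.n_types))
    special = {p.gene for p in cfg.planted_effects} | {m.gene for m in cfg.mixing_only}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in special:
        if g not in gene_pos:
            raise ValueError(f"planted/mixing gene {g!r} outside the gene universe")
        mu[gene_pos[g], :] = cfg.base_mean
    block = max(1, int(cfg.signature_fraction * cfg.n_genes / cfg.n_types))
    free = [i for i, g in enumerate(genes) if g not in special]
    for t in range(cfg.n_types):
        sig = free[t * block : (t + 1) * block]
        mu[sig, t] *= cfg.signature_strength
    for m in cfg.mixing_only:
        gi = gene_pos[m.gene]
        ti = {t: j for j, t in enumerate(types)}
        mu[gi, ti[m.high_type]] *= cfg.mixing_strength
        mu[gi, ti[m.low_type]] /= cfg.mixing_strength
    return pd.DataFrame(mu, index=genes, columns=types)


def marker_sets(cfg: SimConfig, n_markers: int = 5) -> list[MarkerSet]:
    """Marker genes per type: the strongest signature genes."""
    mu = baseline_means(cfg)
    out = []
    for t in cfg.types:
        ratio = mu[t] / mu.drop(columns=t).mean(axis=1)
        top = ratio.sort_values(ascending=False, kind="stable").index[:n_markers]
        out.append(MarkerSet(cell_type=t, markers=tuple(top)))
    return out


def _sample_counts(rng: np.random.Generator, mean: np.ndarray, cfg: SimConfig) -> np.ndarray:
    mean = np.clip(mean, 0, None)
    if cfg.distribution == "poisson":
        return rng.poisson(mean)
    theta = cfg.dispersion
    p = theta / (theta + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(theta, p[pos])
    return out


def simulate_image_mode(cfg: SimConfig):
    """Cells in striped type domains with contact-planted genes.

    Returns (cells, expr, truth): a cell table (cell_id, x, y, cell_type),
    an :class:`ExpressionMatrix` of raw counts, and a ground-truth frame
    (gene, category, true_log2_fc, class).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_units
    xy = rng.uniform(0, 1, size=(n, 2))
    # two stripes per type (T1..Tk, T1..Tk) so every adjacent type pair has
    # two contact borders, giving heterotypic groups of useful size
    n_stripes = 2 * cfg.n_types
    stripe = np.minimum((xy[:, 0] * n_stripes).astype(int), n_stripes - 1)
    types = [cfg.types[s % cfg.n_types] for s in stripe]
    ids = [f"c{i + 1:05d}" for i in range(n)]
    cells = pd.DataFrame({"cell_id": ids, "x": xy[:, 0], "y": xy[:, 1], "cell_type": types})

    g = delaunay_neighbors(cells)
    adj = g.neighbors_of()
    ctype = dict(zip(ids, types))

    mu_types = baseline_means(cfg)
    type_idx = {t: j for j, t in enumerate(cfg.types)}
    mu = mu_types.to_numpy()[:, [type_idx[t] for t in types]]  # genes x cells

    gene_pos = {gname: i for i, gname in enumerate(cfg.genes)}
    truth_rows = []
    for eff in cfg.planted_effects:
        gi = gene_pos[eff.gene]
        hit = [
            j
            for j, cid in enumerate(ids)
            if ctype[cid] == eff.center_type
            and any(ctype[nb] == eff.partner_type for nb in adj[cid])
        ]
        if not hit:
            raise ValueError(
                f"no contact zone for planted effect {eff.gene} "
                f"({eff.center_type} vs {eff.partner_type}); adjust the geometry"
            )
        mu[gi, hit] *= 2.0**eff.log2_fc
        truth_rows.append(
            (eff.gene, f"{eff.center_type}+{eff.partner_type}", eff.log2_fc, "contact")
        )
    counts = _sample_counts(rng, mu, cfg)
    expr = ExpressionMatrix(cfg.genes, ids, counts)
    truth = pd.DataFrame(truth_rows, columns=["gene", "category", "true_log2_fc", "class"])
    return cells, expr, truth


def simulate_ngs_mode(cfg: SimConfig, pairs: list[tuple[str, str]] | None = None):
    """Singlet/doublet bead spots with contact and mixing-only genes.

    Doublet pairs are drawn uniformly from ``pairs`` (default: the pairs
    named by planted/mixing genes, else all unordered type pairs). Returns
    (expr, deconv, truth): raw counts, the deconvolution table (spot_id,
    first_type, second_type, first_prop, spot_class) with first_type the
    canonical first element, and the ground-truth frame.
    """
    rng = np.random.default_rng(cfg.seed)
    mu_types = baseline_means(cfg)
    type_idx = {t: j for j, t in enumerate(cfg.types)}
    mu_mat = mu_types.to_numpy()

    if pairs is None:
        named = {
            canonical_pair(p.center_type, p.partner_type) for p in cfg.planted_effects
        } | {canonical_pair(m.high_type, m.low_type) for m in cfg.mixing_only}
        pairs = sorted(named) or [
            (a, b) for i, a in enumerate(cfg.types) for b in cfg.types[i + 1 :]
        ]
    pairs = [canonical_pair(*p) for p in pairs]

    n = cfg.n_units
    n_doublet = int(round(cfg.doublet_fraction * n))
    n_singlet = n - n_doublet
    gene_pos = {g: i for i, g in enumerate(cfg.genes)}

    ids, first, second, prop, klass = [], [], [], [], []
    mean_cols = np.empty((cfg.n_genes, n))
    a_beta, b_beta = cfg.proportion_beta
    for i in range(n_singlet):
        t = cfg.types[int(rng.integers(cfg.n_types))]
        ids.append(f"s{i + 1:05d}")
        first.append(t)
        second.append("")
        prop.append(1.0)
        klass.append("singlet")
        mean_cols[:, i] = mu_mat[:, type_idx[t]]
    for i in range(n_doublet):
        pa, pb = pairs[int(rng.integers(len(pairs)))]
        w = float(rng.beta(a_beta, b_beta))
        m = w * mu_mat[:, type_idx[pa]] + (1 - w) * mu_mat[:, type_idx[pb]]
        for eff in cfg.planted_effects:
            if canonical_pair(eff.center_type, eff.partner_type) == (pa, pb):
                m = m.copy()
                m[gene_pos[eff.gene]] *= 2.0**eff.log2_fc
        j = n_singlet + i
        ids.append(f"d{i + 1:05d}")
        first.append(pa)
        second.append(pb)
        prop.append(w)
        klass.append("doublet")
        mean_cols[:, j] = m
    counts = _sample_counts(rng, mean_cols, cfg)
    expr = ExpressionMatrix(cfg.genes, ids, counts)
    deconv = pd.DataFrame(
        {
            "spot_id": ids,
            "first_type": first,
            "second_type": second,
            "first_prop": prop,
            "spot_class": klass,
        }
    )
    truth_rows = [
        (
            p.gene,
            "+".join(canonical_pair(p.center_type, p.partner_type)),
            p.log2_fc,
            "contact",
        )
        for p in cfg.planted_effects
    ] + [
        (m.gene, "+".join(canonical_pair(m.high_type, m.low_type)), 0.0, "mixing_only")
        for m in cfg.mixing_only
    ]
    truth = pd.DataFrame(truth_rows, columns=["gene", "category", "true_log2_fc", "class"])
    return expr, deconv, truth


def default_image_config(
    seed: int = 0, n_cells: int = 2000, log2_fc: float = 1.5, genes_per_pair: int = 8
) -> SimConfig:
    """Canonical image-mode fixture: 4 striped types, 48 contact genes."""
    effects = []
    k = 0
    for t in range(3):  # adjacent stripe pairs share a border
        a, b = f"T{t + 1}", f"T{t + 2}"
        for _ in range(genes_per_pair):
            effects.append(PlantedEffect(f"g{400 + k:04d}", a, b, log2_fc))
            k += 1
        for _ in range(genes_per_pair):
            effects.append(PlantedEffect(f"g{400 + k:04d}", b, a, log2_fc))
            k += 1
    return SimConfig(seed=seed, n_units=n_cells, planted_effects=tuple(effects))


def default_ngs_config(seed: int = 0, n_spots: int = 2000, log2_fc: float = 1.5) -> SimConfig:
    """Canonical NGS-mode fixture: contact genes plus mixing-only genes."""
    effects, mixing = [], []
    k = 0
    for a, b in [("T1", "T2"), ("T2", "T3"), ("T3", "T4")]:
        for _ in range(3):
            effects.append(PlantedEffect(f"g{400 + k:04d}", a, b, log2_fc))
            k += 1
        mixing.append(MixingGene(f"g{430 + len(mixing):04d}", a, b))
        mixing.append(MixingGene(f"g{430 + len(mixing):04d}", b, a))
    return SimConfig(
        seed=seed,
        n_units=n_spots,
        planted_effects=tuple(effects),
        mixing_only=tuple(mixing),
    )


def write_fixture_bundle(out_dir: str | Path, seed: int = 0, n_units: int = 800):
    """Write the canonical small fixture pair (image + NGS) as plain text.

    Deterministic for a fixed seed; the files are the formats the readers
    consume (dense TSV counts, cell/deconvolution/marker/ground-truth
    tables). Returns the list of written paths.
    """
    from .io import save_expression

    out = Path(out_dir)
    written = []

    img_cfg = default_image_config(seed=seed, n_cells=n_units)
    cells, expr, truth = simulate_image_mode(img_cfg)
    d = out / "image"
    d.mkdir(parents=True, exist_ok=True)
    save_expression(expr, d / "counts.tsv")
    cells.to_csv(d / "cells.tsv", sep="\t", index=False)
    truth.to_csv(d / "truth.tsv", sep="\t", index=False)
    written += [d / "counts.tsv", d / "cells.tsv", d / "truth.tsv"]

    ngs_cfg = default_ngs_config(seed=seed, n_spots=n_units)
    expr, deconv, truth = simulate_ngs_mode(ngs_cfg)
    d = out / "ngs"
    d.mkdir(parents=True, exist_ok=True)
    save_expression(expr, d / "counts.tsv")
    deconv.to_csv(d / "deconv.tsv", sep="\t", index=False)
    truth.to_csv(d / "truth.tsv", sep="\t", index=False)
    rows = [
        {"cell_type": ms.cell_type, "gene": g}
        for ms in marker_sets(ngs_cfg)
        for g in ms.markers
    ]
    pd.DataFrame(rows).to_csv(d / "markers.tsv", sep="\t", index=False)
    written += [d / "counts.tsv", d / "deconv.tsv", d / "truth.tsv", d / "markers.tsv"]
    return [str(p) for p in written]
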