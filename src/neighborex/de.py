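"""Neighbor-dependent differential expression: model and results objects.

:class:`NeighborDE` is the modelling entry point. It is constructed from a
log-normalized :class:`~neighborex.io.ExpressionMatrix` plus niche
categories (image mode) or a deconvolution table (NGS mode); ``fit()``
runs the heterotypic-vs-homotypic comparison per category and per gene and
returns a :class:`DEResults` carrying effect sizes (log2 ratios), p-values,
BH-adjusted FDR, the test actually used, and call flags.

Call criteria
-------------
image mode:  |log2 ratio| > 0.4, p < 0.01 and FDR < 0.05 against the
             homotypic reference of the center type.
NGS mode:    the heterotypic A+B group must pass |log2 ratio| > 0.4 and
             p < 0.01 against *both* homotypic references A/A and B/B
             (the reported statistics carry the max p / min |log ratio|);
             called genes are then retested against pooled artificial
             mixture spots (null validation: log ratio > 0.4, p < 0.01,
             FDR < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as st
from .graph import NeighborCategory
from .io import ExpressionMatrix
from .spots import (
    canonical_pair,
    classify_spots,
    doublet_weights,
    homotypic_pools,
    make_artificial_spots,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene", "category", "n_het", "n_homo", "log_ratio", "p", "fdr",
    "test", "direction", "called", "null_validated",
]


@dataclass(frozen=True)
class DEThresholds:
    """Call criteria for neighbor-dependent genes."""

    log_ratio: float = 0.4
    p: float = 0.01
    fdr: float = 0.05  # applied in image mode
    null_fdr: float = 0.01  # artificial-spot validation (NGS mode)
    pseudo: float = 1e-9
    log_base: float = 2.0


class NeighborDE:
    """Detect genes whose expression depends on the neighboring cell type.

    Parameters
    ----------
    expr : log-normalized expression matrix (genes x units).
    categories : niche categories from ``categorize_cells`` (image mode) or
        ``classify_spots`` (NGS mode).
    mode : 'image' or 'ngs'.
    deconv : deconvolution table, required in NGS mode (for the artificial
        spot weights of the null validation).
    thresholds : call criteria; defaults to the standard criteria above.
    min_group : minimum group size for a comparison to be attempted.
    min_detect_frac : a gene is testable in a comparison only if it is
        detected (normalized expression > 0) in at least this fraction of
        one of the two groups; guards the parametric tests against
        near-silent genes whose group means are dominated by zeros.
    use_normality : gate parametric tests on Shapiro-Wilk normality.
    pooled_homotypic : in NGS mode, compare against the pooled A/A + B/B
        reference instead of requiring both separately.
    null_merge_scale : scale on which artificial spots are merged.
        'counts' (default) mixes raw counts and log-normalizes each
        replicate, reproducing exactly how a passive mixture of two cells
        would be measured; 'normalized' mixes log-normalized profiles
        directly, which is slightly biased low for the null (log1p is
        concave, so a real mixture sits above the mix of logs) and is kept
        for data where raw counts are unavailable.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        categories: list[NeighborCategory],
        mode: str = "image",
        deconv: pd.DataFrame | None = None,
        thresholds: DEThresholds = DEThresholds(),
        min_group: int = 10,
        min_detect_frac: float = 0.1,
        use_normality: bool = False,
        pooled_homotypic: bool = False,
        null_merge_scale: str = "counts",
    ) -> None:
        if null_merge_scale not in ("counts", "normalized"):
            raise ValueError("null_merge_scale must be 'counts' or 'normalized'")
        if mode not in ("image", "ngs"):
            raise ValueError(f"mode must be 'image' or 'ngs', got {mode!r}")
        if mode == "ngs" and deconv is None:
            raise ValueError("NGS mode requires a deconvolution table")
        expr._require_normalized()
        self.expr = expr
        self.categories = list(categories)
        self.mode = mode
        self.deconv = deconv
        self.thresholds = thresholds
        self.min_group = min_group
        self.min_detect_frac = min_detect_frac
        self.use_normality = use_normality
        self.pooled_homotypic = pooled_homotypic
        self.null_merge_scale = null_merge_scale

    # -- construction helpers --------------------------------------------
    @classmethod
    def from_spots(
        cls, expr: ExpressionMatrix, deconv: pd.DataFrame, min_group: int = 10, **kw
    ) -> "NeighborDE":
        cats = classify_spots(deconv, min_members=min_group)
        return cls(expr, cats, mode="ngs", deconv=deconv, min_group=min_group, **kw)

    # -- fitting ----------------------------------------------------------
    def fit(self, n_reps: int = 100, seed: int = 0, null_validate: bool | None = None) -> "DEResults":
        """Run all category comparisons; returns a :class:`DEResults`.

        ``null_validate`` defaults to True in NGS mode (requires homotypic
        pools for both constituent types of each heterotypic category).
        """
        if null_validate is None:
            null_validate = self.mode == "ngs"
        norm = self.expr._require_normalized()
        homos = {c.center_type: c for c in self.categories if c.homotypic}
        frames = []
        skipped: list[tuple[str, str]] = []
        for cat in self.categories:
            if cat.homotypic:
                continue
            try:
                df = self._fit_category(cat, homos, norm)
            except _SkipCategory as e:
                logger.info("skipping category %s: %s", cat.label, e)
                skipped.append((cat.label, str(e)))
                continue
            frames.append(df)
        table = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=RESULT_COLUMNS)
        )
        res = DEResults(self, table, skipped)
        if null_validate and self.mode == "ngs" and len(table):
            res = self._null_validate(res, n_reps=n_reps, seed=seed)
        return res

    def _group_matrix(self, members) -> np.ndarray:
        idx = self.expr.unit_indices(members)
        return self.expr.normalized[:, idx]

    def _fit_category(self, cat, homos, norm) -> pd.DataFrame:
        th = self.thresholds
        het = self._group_matrix(cat.members)
        if het.shape[1] < self.min_group:
            raise _SkipCategory(f"heterotypic group too small (n={het.shape[1]})")
        if self.mode == "image":
            ref = homos.get(cat.center_type)
            if ref is None:
                raise _SkipCategory(f"no homotypic reference {cat.center_type}")
            refs = [self._group_matrix(ref.members)]
        else:
            pair = canonical_pair(cat.center_type, cat.partner_type)
            if self.pooled_homotypic:
                mats = []
                for t in pair:
                    if t in homos:
                        mats.append(self._group_matrix(homos[t].members))
                if not mats:
                    raise _SkipCategory(f"no homotypic reference for pair {pair}")
                refs = [np.concatenate(mats, axis=1)]
            else:
                missing = [t for t in pair if t not in homos]
                if missing:
                    raise _SkipCategory(f"missing homotypic reference(s) {missing}")
                refs = [self._group_matrix(homos[t].members) for t in pair]
        for ref in refs:
            if ref.shape[1] < self.min_group:
                raise _SkipCategory(f"homotypic reference too small (n={ref.shape[1]})")

        rows = []
        n_degenerate = 0
        for gi, gene in enumerate(self.expr.genes):
            hvals = het[gi]
            per_ref = []
            degenerate = False
            if (hvals > 0).mean() < self.min_detect_frac and all(
                (ref[gi] > 0).mean() < self.min_detect_frac for ref in refs
            ):
                n_degenerate += 1
                continue
            for ref in refs:
                rvals = ref[gi]
                if np.ptp(hvals) == 0 and np.ptp(rvals) == 0 and hvals.mean() == rvals.mean():
                    degenerate = True
                    break
                sel = st.choose_test(hvals, rvals, use_normality=self.use_normality)
                _, p = st.run_selected_test(hvals, rvals, sel)
                lr = st.log_ratio(hvals, rvals, pseudo=th.pseudo, base=th.log_base)
                per_ref.append((lr, p, sel.test))
            if degenerate:
                n_degenerate += 1
                continue
            # carry the weaker evidence across references: max p, min |lr|
            lrs = [x[0] for x in per_ref]
            ps = [x[1] for x in per_ref]
            consistent_sign = all(l > 0 for l in lrs) or all(l < 0 for l in lrs)
            k = int(np.argmin(np.abs(lrs)))
            lr, p = lrs[k], max(ps)
            test = per_ref[int(np.argmax(ps))][2]
            passes_margin = consistent_sign and min(abs(l) for l in lrs) > th.log_ratio
            passes_p = all(pv < th.p for pv in ps)
            rows.append(
                {
                    "gene": gene,
                    "category": cat.label,
                    "n_het": het.shape[1],
                    "n_homo": min(r.shape[1] for r in refs),
                    "log_ratio": lr,
                    "p": p,
                    "fdr": np.nan,
                    "test": test,
                    "direction": "up" if lr > 0 else "down",
                    "called": bool(passes_margin and passes_p),
                    "null_validated": pd.NA,
                }
            )
        if n_degenerate:
            logger.info(
                "category %s: %d genes degenerate (all-zero), skipped",
                cat.label, n_degenerate,
            )
        if not rows:
            raise _SkipCategory("no testable genes")
        df = pd.DataFrame(rows)
        df["fdr"] = st.bh_fdr(df["p"].to_numpy())
        if self.mode == "image":
            df["called"] &= df["fdr"] < th.fdr
        return df

    # -- null validation (NGS) -------------------------------------------
    def null_validation(
        self, category_label: str, genes, n_reps: int = 100, seed: int = 0
    ) -> pd.DataFrame:
        """Retest ``genes`` against pooled artificial mixture spots.

        For each heterotypic spot of the category, ``n_reps`` artificial
        spots are built from random homotypic spots of the two constituent
        types at the spot's own mixing weight; genes are then tested
        heterotypic vs pooled artificial with the same test-selection
        machinery. Returns (gene, log_ratio, p, fdr, passes) where
        ``passes`` applies log ratio > threshold, p < threshold and
        FDR < null_fdr across the supplied gene set.
        """
        if self.mode != "ngs":
            raise ValueError("null validation applies to NGS mode")
        th = self.thresholds
        genes = list(genes)
        merge_counts = self.null_merge_scale == "counts"
        pools = homotypic_pools(
            self.expr, self.categories, layer="counts" if merge_counts else "normalized"
        )
        weights = doublet_weights(self.deconv)
        cat = next((c for c in self.categories if c.label == category_label), None)
        if cat is None:
            raise KeyError(f"unknown category {category_label!r}")
        pair = canonical_pair(cat.center_type, cat.partner_type)
        missing = [t for t in pair if t not in pools]
        if missing:
            raise ValueError(f"no homotypic pool for {missing} in {category_label}")
        master = np.random.default_rng(seed)
        reps = []
        for spot in cat.members:
            sub_seed = int(master.integers(0, 2**31 - 1))
            aset = make_artificial_spots(
                spot, weights.get(spot, 0.5), pair,
                pools[pair[0]], pools[pair[1]],
                n_reps=n_reps, seed=sub_seed,
            )
            reps.append(aset.replicates)
        art = np.concatenate(reps, axis=0)  # (n_spots * n_reps, n_genes)
        if merge_counts:
            # measure each merged pseudo-spot the way a real one is measured
            totals = art.sum(axis=1, keepdims=True)
            if np.any(totals <= 0):
                raise ValueError(
                    "artificial spots with zero total counts; use "
                    "null_merge_scale='normalized' for data without raw counts"
                )
            scale = self.expr.norm_scale if self.expr.norm_scale is not None else 1e4
            art = np.log1p(scale * art / totals)
        het = self._group_matrix(cat.members)
        gene_pos = {g: i for i, g in enumerate(self.expr.genes)}
        ps, lrs = [], []
        for gene in genes:
            gi = gene_pos[gene]
            hvals, avals = het[gi], art[:, gi]
            sel = st.choose_test(hvals, avals, use_normality=self.use_normality)
            _, p = st.run_selected_test(hvals, avals, sel)
            ps.append(p)
            lrs.append(st.log_ratio(hvals, avals, pseudo=th.pseudo, base=th.log_base))
        fdrs = st.bh_fdr(np.array(ps))
        passes = [
            (lr > th.log_ratio) and (p < th.p) and (f < th.null_fdr)
            for lr, p, f in zip(lrs, ps, fdrs)
        ]
        return pd.DataFrame(
            {"gene": genes, "log_ratio": lrs, "p": ps, "fdr": fdrs, "passes": passes}
        )

    def _null_validate(self, res: "DEResults", n_reps: int, seed: int) -> "DEResults":
        pools = homotypic_pools(self.expr, self.categories)
        table = res.table.copy()
        master = np.random.default_rng(seed)
        for label, sub in table.groupby("category", sort=True):
            cat_seed = int(master.integers(0, 2**31 - 1))
            called = sub[sub["called"]]
            if called.empty:
                continue
            cat = next(c for c in self.categories if c.label == label)
            pair = canonical_pair(cat.center_type, cat.partner_type)
            if pair[0] not in pools or pair[1] not in pools:
                logger.info("no pools for %s; null validation not applicable", label)
                continue
            val = self.null_validation(
                label, called["gene"].tolist(), n_reps=n_reps, seed=cat_seed
            )
            table.loc[called.index, "null_validated"] = val["passes"].to_numpy()
        return DEResults(self, table, res.skipped)


class _SkipCategory(Exception):
    pass


class DEResults:
    """Results of a :class:`NeighborDE` fit.

    ``table`` is a tidy frame with one row per (gene, heterotypic category):
    log2 ratio, p, BH FDR, the selected test, direction, whether the gene is
    called neighbor-dependent, and (NGS mode) whether it survived the
    artificial-spot null validation.
    """

    def __init__(self, model: NeighborDE, table: pd.DataFrame, skipped=()) -> None:
        self.model = model
        self.table = table.reset_index(drop=True)
        self.skipped = list(skipped)

    @property
    def called(self) -> pd.DataFrame:
        """Genes passing the call criteria (and null validation when run)."""
        t = self.table
        mask = t["called"].astype(bool)
        failed_null = t["null_validated"].apply(lambda v: v is False)
        return t[mask & ~failed_null]

    def summary(self) -> pd.DataFrame:
        """Per-category counts of up/down neighbor-dependent genes."""
        rows = []
        for label, sub in self.table.groupby("category", sort=True):
            calls = self.called[self.called["category"] == label]
            rows.append(
                {
                    "category": label,
                    "n_genes_tested": len(sub),
                    "n_up": int((calls["direction"] == "up").sum()),
                    "n_down": int((calls["direction"] == "down").sum()),
                }
            )
        return pd.DataFrame(rows, columns=["category", "n_genes_tested", "n_up", "n_down"])

    def volcano_data(self, category: str) -> pd.DataFrame:
        """(gene, log_ratio, p, fdr, called) columns for one category."""
        sub = self.table[self.table["category"] == category]
        return sub[["gene", "log_ratio", "p", "fdr", "called"]].reset_index(drop=True)

    def to_tsv(self, out_dir, float_format: str = "%.6g") -> list[str]:
        """One TSV per category plus a summary TSV; returns written paths."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for label, sub in self.table.groupby("category", sort=True):
            safe = label.replace("/", "-").replace(" ", "_")
            p = out / f"de_{safe}.tsv"
            sub.to_csv(p, sep="\t", index=False, float_format=float_format)
            written.append(str(p))
        p = out / "de_summary.tsv"
        self.summary().to_csv(p, sep="\t", index=False, float_format=float_format)
        written.append(str(p))
        return written
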