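"""Which cell type of a heterotypic pair expresses a neighbor-dependent gene.

Across the A+B heterotypic spots that express a gene, its normalized
expression y is regressed on x, the transcript proportion of the
lexicographically first type of the pair:

    y_i = alpha + beta * x_i + eps_i

by ordinary least squares (closed-form normal equations). A positive slope
with p < 0.05 attributes the expression to the first type, a negative slope
to the second; otherwise the origin is undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import NeighborCategory
from .io import ExpressionMatrix
from .spots import canonical_pair, doublet_weights

__all__ = ["OriginCall", "OriginRegression", "OriginResults", "cross_check_reference"]


@dataclass(frozen=True)
class OriginCall:
    """Origin inference for one gene in one heterotypic pair.

    x is the proportion of ``pair[0]`` (lexicographic convention), so
    ``origin == pair[0]`` iff the slope is positive and significant.
    """

    gene: str
    pair: tuple[str, str]
    alpha_hat: float
    beta_hat: float
    p_slope: float
    n: int
    origin: str  # pair[0] | pair[1] | "undetermined"
    reason: str = ""


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS fit; returns (alpha_hat, beta_hat, p_slope)."""
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    beta = ((x - xbar) * (y - ybar)).sum() / sxx
    alpha = ybar - beta * xbar
    resid = y - alpha - beta * x
    dof = n - 2
    if dof <= 0:
        return float(alpha), float(beta), 1.0
    s2 = (resid**2).sum() / dof
    if s2 == 0:
        p = 0.0 if beta != 0 else 1.0
    else:
        se = np.sqrt(s2 / sxx)
        t = beta / se
        p = 2 * sps.t.sf(abs(t), dof)
    return float(alpha), float(beta), float(p)


class OriginRegression:
    """Proportion-regression model over the heterotypic spots of one pair.

    Parameters
    ----------
    expr : log-normalized expression matrix.
    category : the heterotypic category A+B whose spots are modelled.
    deconv : deconvolution table supplying per-spot first-type proportions.
    min_spots : minimum number of expressing spots for a fit.
    require_expressing : restrict each gene's fit to spots with normalized
        expression > 0 (the count of such spots is the regression's n).
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        category: NeighborCategory,
        deconv: pd.DataFrame,
        min_spots: int = 20,
        alpha: float = 0.05,
        require_expressing: bool = True,
    ) -> None:
        if category.homotypic:
            raise ValueError("origin regression applies to heterotypic categories")
        expr._require_normalized()
        self.expr = expr
        self.category = category
        self.pair = canonical_pair(category.center_type, category.partner_type)
        self.min_spots = min_spots
        self.alpha = alpha
        self.require_expressing = require_expressing
        w = doublet_weights(deconv)
        missing = [s for s in category.members if s not in w]
        if missing:
            raise ValueError(f"spots without doublet proportions: {missing[:5]}")
        self._spots = list(category.members)
        self._x = np.array([w[s] for s in self._spots])

    def fit(self, genes=None) -> "OriginResults":
        """Fit the proportion regression for each gene (default: all)."""
        genes = list(genes) if genes is not None else list(self.expr.genes)
        norm = self.expr._require_normalized()
        idx = self.expr.unit_indices(self._spots)
        calls = [
            self._fit_gene(g, norm[self.expr.gene_index(g), idx]) for g in genes
        ]
        return OriginResults(self, calls)

    def _fit_gene(self, gene: str, y: np.ndarray) -> OriginCall:
        x = self._x
        if self.require_expressing:
            mask = y > 0
            x, y = x[mask], y[mask]
        n = int(y.size)
        und = lambda reason: OriginCall(
            gene, self.pair, np.nan, np.nan, np.nan, n, "undetermined", reason
        )
        if n < self.min_spots:
            return und("insufficient spots")
        if np.ptp(x) == 0:
            return und("degenerate design")
        alpha_hat, beta_hat, p = _ols_slope(x, y)
        if p < self.alpha and beta_hat > 0:
            origin = self.pair[0]
        elif p < self.alpha and beta_hat < 0:
            origin = self.pair[1]
        else:
            origin = "undetermined"
        return OriginCall(gene, self.pair, alpha_hat, beta_hat, p, n, origin)


class OriginResults:
    """Per-gene origin calls for one heterotypic pair."""

    def __init__(self, model: OriginRegression, calls: list[OriginCall]) -> None:
        self.model = model
        self.calls = calls

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": c.gene,
                    "pair": f"{c.pair[0]}+{c.pair[1]}",
                    "beta_hat": c.beta_hat,
                    "alpha_hat": c.alpha_hat,
                    "p_slope": c.p_slope,
                    "n": c.n,
                    "origin": c.origin,
                    "reason": c.reason,
                }
                for c in self.calls
            ]
        )

    def summary(self) -> pd.DataFrame:
        t = self.table
        return (
            t.groupby("origin", sort=True)
            .size()
            .rename("n_genes")
            .reset_index()
        )

    def to_tsv(self, path, float_format: str = "%.6g") -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=float_format)


def cross_check_reference(
    calls: list[OriginCall] | OriginResults,
    ref_means: pd.DataFrame,
) -> pd.DataFrame:
    """Compare regression origins with a dissociated (sc/snRNA-seq) reference.

    ``ref_means`` is a genes x cell-types frame of mean expression. The
    reference-favored type of a gene is the arg-max over the pair's two
    types; agreement is recorded per determined call. Genes absent from the
    reference are excluded (counted in the ``excluded`` attribute column).
    """
    if isinstance(calls, OriginResults):
        calls = calls.calls
    rows = []
    n_excluded = 0
    for c in calls:
        if c.origin == "undetermined":
            continue
        if c.gene not in ref_means.index:
            n_excluded += 1
            continue
        sub = ref_means.loc[c.gene, list(c.pair)]
        ref_type = str(sub.idxmax())
        rows.append(
            {
                "gene": c.gene,
                "pair": f"{c.pair[0]}+{c.pair[1]}",
                "origin": c.origin,
                "reference_type": ref_type,
                "agree": c.origin == ref_type,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "pair", "origin", "reference_type", "agree"])
    df.attrs["excluded"] = n_excluded
    df.attrs["agreement_fraction"] = float(df["agree"].mean()) if len(df) else np.nan
    if not len(df):
        import warnings

        warnings.warn("no overlap between calls and reference", stacklevel=2)
    return df
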