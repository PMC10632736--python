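"""Spatial maps of neighbor-dependent expression.

Two encodings mirror how niche effects are usually shown:

* single-gene maps — each cell/spot drawn at its coordinates, fill color
  by expression, boundary color by niche category (heterotypic partners
  get distinct boundary colors, the homotypic reference another, all
  remaining units gray at reduced opacity);
* RGB niche maps — up to three neighbor-dependent genes bound to the
  red/green/blue channels; each channel is the gene's normalized
  expression divided by its maximum over that gene's heterotypic group,
  so channel values lie in [0, 1] and the map is invariant to rescaling
  any single gene. With two genes the blue channel is identically zero.

SVG output is byte-deterministic for fixed inputs (fixed hash salt, no
embedded timestamps), so rendered maps can be diffed and hashed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .graph import NeighborCategory
from .io import ExpressionMatrix

BOUNDARY_CYCLE = ["red", "green", "blue", "orange", "purple", "brown"]


@dataclass(frozen=True)
class RGBAssignment:
    """Binding of up to three (gene, partner_type) pairs to color channels.

    ``center_type`` fixes the cell type of interest; channel k shows the
    expression of ``channel_genes[k][0]`` within the heterotypic group
    (center_type, partner_type), max-normalized within that group.
    """

    center_type: str
    channel_genes: tuple[tuple[str, str], ...]  # ((gene, partner_type), ...)

    def __post_init__(self) -> None:
        if not 1 <= len(self.channel_genes) <= 3:
            raise ValueError("assign between 1 and 3 channel genes")


def rgb_values(
    assignment: RGBAssignment,
    expr: ExpressionMatrix,
    categories: list[NeighborCategory],
) -> pd.DataFrame:
    """Per-unit (r, g, b) channel values in [0, 1].

    Each channel is normalized expression / max over the channel's
    heterotypic group; units outside all the displayed groups get
    (0, 0, 0). A group whose maximum is zero yields an all-zero channel
    (with a warning).
    """
    norm = expr._require_normalized()
    cat_by_pair = {
        (c.center_type, c.partner_type): c for c in categories if not c.homotypic
    }
    out = pd.DataFrame(
        0.0, index=pd.Index(expr.units, name="unit"), columns=["r", "g", "b"]
    )
    for channel, (gene, partner) in zip("rgb", assignment.channel_genes):
        key = (assignment.center_type, partner)
        if key not in cat_by_pair:
            raise KeyError(f"no heterotypic category {key[0]}+{key[1]}")
        cat = cat_by_pair[key]
        gi = expr.gene_index(gene)
        idx = expr.unit_indices(cat.members)
        vals = norm[gi, idx]
        gmax = vals.max()
        if gmax == 0:
            warnings.warn(
                f"zero maximum for {gene} in group {cat.label}; channel left at 0",
                stacklevel=2,
            )
            continue
        out.loc[list(cat.members), channel] = np.clip(vals / gmax, 0.0, 1.0)
    return out


def render_map(
    cells: pd.DataFrame,
    colors: pd.DataFrame | None = None,
    boundary_categories: list[NeighborCategory] | None = None,
    out: str | None = None,
    title: str | None = None,
    point_size: float = 12.0,
    figsize: tuple[float, float] = (7.0, 7.0),
):
    """Draw cells/spots at their coordinates.

    ``colors``: per-unit r/g/b frame (from :func:`rgb_values`); unlisted or
    all-zero units are drawn gray at reduced opacity. ``boundary_categories``
    get colored edges in listing order with a legend. Saving to ``.svg``
    produces identical bytes for identical inputs.
    """
    with matplotlib.rc_context({"svg.hashsalt": "neighborex"}):
        fig, ax = plt.subplots(figsize=figsize)
        ids = cells["cell_id"].astype(str).to_numpy()
        xs = cells["x"].to_numpy(dtype=float)
        ys = cells["y"].to_numpy(dtype=float)

        face = np.tile([0.6, 0.6, 0.6], (len(ids), 1))
        alpha = np.full(len(ids), 0.35)
        if colors is not None and len(colors):
            pos = {u: i for i, u in enumerate(ids)}
            for unit, row in colors.iterrows():
                i = pos.get(str(unit))
                if i is None:
                    continue
                rgb = row[["r", "g", "b"]].to_numpy(dtype=float)
                if rgb.max() > 0:
                    face[i] = rgb
                    alpha[i] = 1.0

        edge = np.full(len(ids), "none", dtype=object)
        handles = []
        if boundary_categories:
            pos = {u: i for i, u in enumerate(ids)}
            for k, cat in enumerate(boundary_categories):
                col = BOUNDARY_CYCLE[k % len(BOUNDARY_CYCLE)]
                for m in cat.members:
                    i = pos.get(m)
                    if i is not None:
                        edge[i] = col
                        alpha[i] = 1.0
                handles.append(
                    plt.Line2D(
                        [], [], marker="o", linestyle="", markerfacecolor="white",
                        markeredgecolor=col, label=cat.label,
                    )
                )
        rgba = np.column_stack([face, alpha])
        ax.scatter(xs, ys, s=point_size, c=rgba, edgecolors=list(edge), linewidths=0.8)
        ax.set_aspect("equal")
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        if title:
            ax.set_title(title)
        if handles:
            ax.legend(handles=handles, loc="upper right", fontsize=8)
        if out is not None:
            fig.savefig(out, metadata=_deterministic_metadata(str(out)))
            plt.close(fig)
            return out
        return fig


def _deterministic_metadata(path: str) -> dict:
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return {}
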