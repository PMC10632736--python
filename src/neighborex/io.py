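"""Reading, writing and preprocessing of expression matrices and annotation tables.

The in-memory container is :class:`ExpressionMatrix`, a genes x units matrix
(units are cells in image-based data, barcoded spots in NGS data) holding raw
counts and, after :func:`log_normalize`, library-size log-normalized values.
Preprocessing mirrors the common single-cell convention: drop low-complexity
units, log-normalize to a fixed library size, then keep the most variable
genes plus any supplied cell-type markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class ExpressionMatrix:
    """Genes x units expression matrix with optional normalized layer.

    Parameters
    ----------
    genes : ordered unique gene identifiers (length G)
    units : ordered unique cell/spot identifiers (length U)
    counts : (G, U) nonnegative array of raw counts
    normalized : (G, U) nonnegative array of log-normalized expression,
        or ``None`` until :func:`log_normalize` has been applied.
    """

    genes: list[str]
    units: list[str]
    counts: np.ndarray
    normalized: np.ndarray | None = None
    norm_scale: float | None = None  # scale used by log_normalize, if applied

    def __post_init__(self) -> None:
        self.genes = list(map(str, self.genes))
        self.units = list(map(str, self.units))
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.units)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.units)} units"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ParseError("duplicate gene identifiers")
        if len(set(self.units)) != len(self.units):
            raise ParseError("duplicate unit identifiers")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized layer shape mismatch")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def unit_indices(self, units: Sequence[str]) -> np.ndarray:
        pos = {u: i for i, u in enumerate(self.units)}
        try:
            return np.array([pos[u] for u in units], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown unit {e.args[0]!r}") from None

    def subset_units(self, units: Sequence[str]) -> "ExpressionMatrix":
        idx = self.unit_indices(units)
        return ExpressionMatrix(
            genes=list(self.genes),
            units=[self.units[i] for i in idx],
            counts=self.counts[:, idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
            norm_scale=self.norm_scale,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return ExpressionMatrix(
            genes=[self.genes[i] for i in idx],
            units=list(self.units),
            counts=self.counts[idx, :],
            normalized=None if self.normalized is None else self.normalized[idx, :],
            norm_scale=self.norm_scale,
        )

    def to_frame(self, layer: str = "counts") -> pd.DataFrame:
        data = self.counts if layer == "counts" else self._require_normalized()
        return pd.DataFrame(data, index=self.genes, columns=self.units)

    def _require_normalized(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("normalized layer not populated; run log_normalize first")
        return self.normalized


@dataclass(frozen=True)
class MarkerSet:
    """Marker genes for one cell type."""

    cell_type: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError(f"empty marker list for cell type {self.cell_type!r}")


def load_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Load a genes x units count matrix.

    ``format='tsv'`` (or ``'csv'``): dense delimited text, genes as rows,
    first column gene ids, header row of unit ids. ``format='mtx'``: Matrix
    Market coordinate file with sidecar name files ``<stem>_genes.txt`` and
    ``<stem>_barcodes.txt`` (one name per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv", "dense", "dense-delimited"):
        sep = "," if format == "csv" or path.suffix == ".csv" else r"\s+"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.EmptyDataError:
            raise ParseError(f"{path}: empty file") from None
        except (pd.errors.ParserError, ValueError) as e:
            raise ParseError(f"{path}: {e}") from None
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ParseError(f"{path}: no data rows/columns")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise ParseError(f"{path}: non-numeric entries in columns {list(bad)}")
        return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), vals)
    if format in ("mtx", "matrix-market", "matrix-market-triplet"):
        genes_file = path.with_name(path.stem + "_genes.txt")
        units_file = path.with_name(path.stem + "_barcodes.txt")
        for f in (genes_file, units_file):
            if not f.exists():
                raise ParseError(f"missing sidecar name file {f}")
        try:
            m = mmread(str(path))
        except ValueError as e:
            raise ParseError(f"{path}: {e}") from None
        genes = genes_file.read_text().split()
        units = units_file.read_text().split()
        m = np.asarray(m.todense() if hasattr(m, "todense") else m)
        if m.shape != (len(genes), len(units)):
            raise ParseError(
                f"{path}: matrix shape {m.shape} does not match sidecars "
                f"({len(genes)} genes, {len(units)} barcodes)"
            )
        return ExpressionMatrix(genes, units, m)
    raise ValueError(f"unknown format {format!r}")


def save_expression(m: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write counts as dense TSV or Matrix Market with sidecar name files."""
    path = Path(path)
    if format == "tsv":
        m.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        mmwrite(str(path), coo_matrix(m.counts))
        path.with_name(path.stem + "_genes.txt").write_text("\n".join(m.genes) + "\n")
        path.with_name(path.stem + "_barcodes.txt").write_text("\n".join(m.units) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def filter_low_quality(m: ExpressionMatrix, min_features: int = 200) -> ExpressionMatrix:
    """Drop units detecting fewer than ``min_features`` genes.

    A gene counts as detected in a unit when its raw count is > 0. The gene
    set is unchanged. ``min_features=0`` disables the filter (used e.g. for
    tissues where low-complexity beads are a large share of the data).
    """
    detected = (m.counts > 0).sum(axis=0)
    keep = detected >= min_features
    if not keep.any():
        warnings.warn("filter_low_quality removed every unit", stacklevel=2)
    return ExpressionMatrix(
        genes=list(m.genes),
        units=[u for u, k in zip(m.units, keep) if k],
        counts=m.counts[:, keep],
        normalized=None if m.normalized is None else m.normalized[:, keep],
        norm_scale=m.norm_scale,
    )


def log_normalize(m: ExpressionMatrix, scale: float = 1e4, base: float | None = None) -> ExpressionMatrix:
    """Library-size log-normalization.

    normalized[g, u] = log(1 + scale * counts[g, u] / total_counts[u]),
    natural log by default (``base`` switches the logarithm base).
    """
    totals = m.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        bad = [m.units[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(
            f"units with zero total count: {bad[:5]}{'...' if len(bad) > 5 else ''}; "
            "run filter_low_quality first"
        )
    norm = np.log1p(scale * m.counts / totals)
    if base is not None:
        norm = norm / np.log(base)
    return replace(m, normalized=norm, norm_scale=scale)


def select_features(
    m: ExpressionMatrix,
    top_n: int = 2000,
    markers: Sequence[MarkerSet] = (),
) -> ExpressionMatrix:
    """Keep the ``top_n`` most variable genes plus all marker genes.

    Variability is the variance of the log-normalized expression across
    units. Marker genes are retained regardless of their variance rank.
    Gene order of the input is preserved.
    """
    norm = m._require_normalized()
    if top_n > m.n_genes:
        warnings.warn(
            f"top_n={top_n} exceeds gene count {m.n_genes}; keeping all genes",
            stacklevel=2,
        )
        top_n = m.n_genes
    var = norm.var(axis=1)
    # stable: ties broken by original gene order
    order = np.argsort(-var, kind="stable")[:top_n]
    keep = set(order.tolist())
    marker_names = {g for ms in markers for g in ms.markers}
    keep |= {i for i, g in enumerate(m.genes) if g in marker_names}
    idx = sorted(keep)
    return m.subset_genes([m.genes[i] for i in idx])


# -- annotation tables ----------------------------------------------------

def load_cell_map(path: str | Path) -> pd.DataFrame:
    """Read a per-cell table with columns cell_id, x, y, cell_type."""
    df = _read_table(path, required={"cell_id", "x", "y", "cell_type"})
    df["cell_id"] = df["cell_id"].astype(str)
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ParseError(f"duplicate cell ids: {dupes[:5]}")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ParseError("non-finite coordinates")
    return df.reset_index(drop=True)


def load_deconvolution(path: str | Path) -> pd.DataFrame:
    """Read a per-spot doublet-mode deconvolution table.

    Columns: spot_id, first_type, second_type, first_prop, spot_class
    (singlet/doublet). Validates the singlet/doublet invariants.
    """
    df = _read_table(
        path,
        required={"spot_id", "first_type", "second_type", "first_prop", "spot_class"},
    )
    df["spot_id"] = df["spot_id"].astype(str)
    validate_deconvolution(df)
    return df.reset_index(drop=True)


def validate_deconvolution(df: pd.DataFrame) -> None:
    classes = set(df["spot_class"].unique())
    bad = classes - {"singlet", "doublet"}
    if bad:
        raise ParseError(
            f"unsupported spot classes {sorted(bad)}; this model handles spots "
            "composed of one or two cell types (singlet/doublet deconvolution)"
        )
    singles = df[df["spot_class"] == "singlet"]
    if not ((singles["first_prop"] == 1.0).all()):
        raise ParseError("singlet spots must have first_prop == 1")
    doubles = df[df["spot_class"] == "doublet"]
    if (doubles["first_type"] == doubles["second_type"]).any():
        raise ParseError("doublet spots with identical first and second type")
    props = doubles["first_prop"].to_numpy(dtype=float)
    if len(props) and (np.any(props <= 0) or np.any(props >= 1)):
        raise ParseError("doublet first_prop must lie strictly in (0, 1)")


def load_markers(path: str | Path) -> list[MarkerSet]:
    """Read marker lists from a two-column table (cell_type, gene)."""
    df = _read_table(path, required={"cell_type", "gene"})
    return [
        MarkerSet(cell_type=str(ct), markers=tuple(sub["gene"].astype(str)))
        for ct, sub in df.groupby("cell_type", sort=True)
    ]


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
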