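"""End-to-end runs from a single YAML config, with a reproducible manifest.

Stage chain (image mode): preprocess -> neighbor graph -> niche categories
-> differential expression -> outputs. Stage chain (NGS mode): preprocess
-> spot classification -> (optional) marker/correlation validation of
heterotypic annotations -> differential expression + artificial-spot null
validation -> origin regression -> outputs.

Each stage writes its outputs under the run directory as plain TSV, and the
manifest records the config hash, per-file SHA256 hashes, derived seeds and
category summaries so two runs with the same config and seed can be
compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .de import DEThresholds, NeighborDE
from .graph import (
    categorize_cells,
    delaunay_neighbors,
    knn_neighbors,
    mutual_knn_neighbors,
    prune_by_radius,
    radial_neighbors,
)
from .io import (
    filter_low_quality,
    load_cell_map,
    load_deconvolution,
    load_expression,
    load_markers,
    log_normalize,
    select_features,
)
from .origin import OriginRegression
from .spots import classify_spots, validate_by_correlation, validate_by_markers

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "mode": None,  # image | ngs (required)
    "counts": None,  # required
    "format": "tsv",
    "cells": None,  # image mode
    "deconv": None,  # ngs mode
    "markers": None,
    "out_dir": "neighborex_run",
    "seed": 0,
    # preprocessing
    "min_features": 200,
    "scale": 10000.0,
    "top_n": 2000,
    # neighbor graph (image mode)
    "neighbor_method": "delaunay",  # delaunay | knn | radial
    "k": 6,
    "radius": None,
    "prune_radius": None,  # number, "auto", or null
    # grouping / testing
    "min_group": 10,
    "min_detect_frac": 0.1,
    "log_ratio": 0.4,
    "p": 0.01,
    "fdr": 0.05,
    "null_fdr": 0.01,
    "n_reps": 100,
    "use_normality": False,
    "pooled_homotypic": False,
    "null_merge_scale": "counts",
    "exclusive_nearest": False,
    "validate_markers": True,
    "validate_correlation": False,
    "origin_min_spots": 20,
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``DEFAULTS`` for keys)."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {**DEFAULTS, **self.values}
        if merged["mode"] not in ("image", "ngs"):
            raise ConfigError("mode must be 'image' or 'ngs'")
        if not merged["counts"]:
            raise ConfigError("counts path is required")
        if merged["mode"] == "image" and not merged["cells"]:
            raise ConfigError("image mode requires a cells table path")
        if merged["mode"] == "ngs" and not merged["deconv"]:
            raise ConfigError("ngs mode requires a deconvolution table path")
        for key in ("log_ratio", "p", "fdr", "null_fdr"):
            if merged[key] <= 0:
                raise ConfigError(f"threshold {key} must be positive")
        self.values = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls(data)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def hash(self) -> str:
        # out_dir is a location, not an analysis setting
        vals = {k: v for k, v in self.values.items() if k != "out_dir"}
        blob = json.dumps(vals, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the mode-appropriate stage chain; returns the manifest dict.

    All stage outputs land under ``cfg['out_dir']``; the manifest is also
    written there as ``manifest.json``.
    """
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: _stage_seed(cfg["seed"], s) for s in ("artificial", "correlation")}
    manifest: dict[str, Any] = {
        "config_hash": cfg.hash(),
        "version": __version__,
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "outputs": {},
        "categories": {},
    }
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

    # -- preprocess -------------------------------------------------------
    expr = load_expression(cfg["counts"], format=cfg["format"])
    expr = filter_low_quality(expr, min_features=cfg["min_features"])
    if expr.n_units == 0:
        raise RuntimeError("preprocess: no units survive the quality filter")
    expr = log_normalize(expr, scale=cfg["scale"])
    markers = load_markers(cfg["markers"]) if cfg["markers"] else []
    if cfg["top_n"] and cfg["top_n"] < expr.n_genes:
        expr = select_features(expr, top_n=cfg["top_n"], markers=markers)
    thresholds = DEThresholds(
        log_ratio=cfg["log_ratio"], p=cfg["p"], fdr=cfg["fdr"], null_fdr=cfg["null_fdr"]
    )

    if cfg["mode"] == "image":
        cells = load_cell_map(cfg["cells"])
        cells = cells[cells["cell_id"].isin(set(expr.units))].reset_index(drop=True)
        expr = expr.subset_units(cells["cell_id"].tolist())
        method = cfg["neighbor_method"]
        if method == "delaunay":
            g = delaunay_neighbors(cells)
        elif method == "knn":
            g = knn_neighbors(cells, k=int(cfg["k"]))
        elif method == "knn-mutual":
            g = mutual_knn_neighbors(cells, k=int(cfg["k"]))
        elif method == "radial":
            if cfg["radius"] is None:
                raise ConfigError("radial method requires a radius")
            g = radial_neighbors(cells, r=float(cfg["radius"]))
        else:
            raise ConfigError(f"unknown neighbor method {method!r}")
        if cfg["prune_radius"] is not None:
            r = None if cfg["prune_radius"] == "auto" else float(cfg["prune_radius"])
            g = prune_by_radius(g, cells, r=r)
        emit("edges.tsv", g.to_frame(cells))
        cats = categorize_cells(
            g, cells, min_members=cfg["min_group"],
            exclusive_nearest=cfg["exclusive_nearest"],
        )
        model = NeighborDE(
            expr, cats, mode="image", thresholds=thresholds,
            min_group=cfg["min_group"], min_detect_frac=cfg["min_detect_frac"],
            use_normality=cfg["use_normality"],
        )
        res = model.fit()
    else:
        deconv = load_deconvolution(cfg["deconv"])
        deconv = deconv[deconv["spot_id"].isin(set(expr.units))].reset_index(drop=True)
        cats = classify_spots(deconv, min_members=cfg["min_group"])
        if cfg["validate_markers"] and markers:
            emit("marker_validation.tsv", validate_by_markers(expr, cats, markers))
        if cfg["validate_correlation"]:
            emit(
                "correlation_validation.tsv",
                validate_by_correlation(
                    expr, deconv, cats, n_reps=cfg["n_reps"], seed=seeds["correlation"]
                ),
            )
        model = NeighborDE(
            expr, cats, mode="ngs", deconv=deconv, thresholds=thresholds,
            min_group=cfg["min_group"], min_detect_frac=cfg["min_detect_frac"],
            use_normality=cfg["use_normality"], pooled_homotypic=cfg["pooled_homotypic"],
            null_merge_scale=cfg["null_merge_scale"],
        )
        res = model.fit(n_reps=cfg["n_reps"], seed=seeds["artificial"])
        origin_frames = []
        for cat in cats:
            if cat.homotypic or len(cat) < cfg["origin_min_spots"]:
                continue
            genes = res.called[res.called["category"] == cat.label]["gene"]
            if genes.empty:
                continue
            orig = OriginRegression(
                expr, cat, deconv, min_spots=cfg["origin_min_spots"]
            ).fit(genes.tolist())
            origin_frames.append(orig.table)
        if origin_frames:
            emit("origin.tsv", pd.concat(origin_frames, ignore_index=True))

    cat_frame = pd.DataFrame(
        [
            {"category": c.label, "homotypic": c.homotypic, "n_members": len(c)}
            for c in cats
        ]
    )
    emit("categories.tsv", cat_frame)
    written += [Path(p) for p in res.to_tsv(out)]
    manifest["categories"] = {c.label: len(c) for c in cats}
    manifest["n_called"] = int(len(res.called))
    manifest["skipped_categories"] = res.skipped
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(set(written))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
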