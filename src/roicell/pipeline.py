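"""End-to-end pipeline orchestration from a single declarative config.

``run_pipeline`` executes the stages in order — crop → segment → features →
classify → cross-K → mixing groups → expression preprocessing → ligand–
target prediction — skipping the expression/RL stages when their inputs are
absent, and always writes a run manifest (effective config + tool version +
per-stage outputs) for reproducibility.  Config files are TOML; CLI flags
override file values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_typing import (
    annotate_snapshot,
    classify_cutoff,
    classify_gmm,
    classify_kmeans,
)
from .errors import ConfigurationError, RoiCellError
from .expression import preprocess
from .morphology import extract_features
from .rl import compare_groups, load_ligand_target_table, predict_rl_pairs
from .roi import detect_and_crop_roi, load_roi_tiff, save_roi
from .segmentation import SegmentationParams, segment_cells
from .spatial import classify_mixing, cross_k, pattern_from_cells

log = logging.getLogger("roicell")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration."""

    images_dir: str | None = None
    out_dir: str = "roicell_out"
    seed: int = 0
    # crop
    background_tol: int = 10
    roi_diameter_um: float | None = None
    # segmentation
    backend: str = "reference"
    diameter_px: float = 23.0
    flow_threshold: float = 0.4
    # typing
    typing_method: str = "gmm"  # gmm | kmeans | cutoff
    positive_channel: str = "G"
    cutoff: float = 20.0
    # cross-K
    r_max: float | None = None
    n_r: int = 100
    edge_correction: str = "translation"
    mixing_rule: dict | None = None  # {"top_n": k} or {"threshold": t}
    # expression
    probe_matrix: str | None = None
    probe_map: str | None = None
    min_gene_frac: float = 0.05
    min_roi_frac: float = 0.10
    # ligand-target
    rl_table: str | None = None
    r_threshold: float = 0.75

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        """Schema checks; raised before any work starts."""
        if self.images_dir is None and self.probe_matrix is None:
            raise ConfigurationError("config needs images_dir and/or probe_matrix")
        for name in ("images_dir", "probe_matrix", "probe_map", "rl_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name} does not exist: {value}")
        if self.typing_method not in ("gmm", "kmeans", "cutoff"):
            raise ConfigurationError(f"unknown typing_method {self.typing_method!r}")
        if self.rl_table is not None and self.probe_matrix is None:
            raise ConfigurationError(
                "rl stage requested (rl_table set) but probe_matrix is missing"
            )
        if self.probe_matrix is not None and self.probe_map is None:
            raise ConfigurationError("probe_matrix requires probe_map")
        if self.mixing_rule is not None and set(self.mixing_rule) not in (
            {"top_n"},
            {"threshold"},
        ):
            raise ConfigurationError(
                "mixing_rule must be {'top_n': k} or {'threshold': t}"
            )


def _classify(cells: pd.DataFrame, config: RunConfig):
    if config.typing_method == "cutoff":
        return classify_cutoff(cells, channel=config.positive_channel, cutoff=config.cutoff)
    if config.typing_method == "gmm":
        return classify_gmm(
            cells, channels=(config.positive_channel,), seed=config.seed
        )
    return classify_kmeans(cells, channels=(config.positive_channel,), seed=config.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "rois": {},
    }

    summary_rows = []
    crossk_results: dict[str, float] = {}
    if config.images_dir is not None:
        tiffs = sorted(Path(config.images_dir).glob("*.tif")) + sorted(
            Path(config.images_dir).glob("*.tiff")
        )
        params = SegmentationParams(
            diameter_px=config.diameter_px, flow_threshold=config.flow_threshold
        )
        all_cells = []
        for tiff in tiffs:
            roi_id = tiff.stem
            log.info("ROI %s: cropping", roi_id)
            try:
                img = detect_and_crop_roi(
                    load_roi_tiff(tiff),
                    background_tol=config.background_tol,
                    roi_diameter_um=config.roi_diameter_um,
                )
                save_roi(img, out / f"{roi_id}_cropped.tif")
                mask = segment_cells(img, params, backend=config.backend)
                cells = extract_features(img, mask, roi_id=roi_id)
                row = {"roi_id": roi_id, "n_total": int(mask.n_cells)}
                auc = float("nan")
                if len(cells) >= 4:
                    typing = _classify(cells, config)
                    cells["class_label"] = typing.labels
                    annotate_snapshot(img, mask, typing, out / f"{roi_id}_snapshot.png")
                    row.update(
                        n_positive=typing.n_positive,
                        positive_fraction=typing.positive_fraction,
                    )
                    counts = pd.Series(typing.labels).value_counts()
                    if counts.get("positive", 0) >= 2 and counts.get("negative", 0) >= 2:
                        pattern = pattern_from_cells(
                            cells, img.center, img.radius_px
                        )
                        ck = cross_k(
                            pattern,
                            r_max=config.r_max,
                            n_r=config.n_r,
                            edge_correction=config.edge_correction,
                        )
                        ck.to_frame().to_csv(out / f"{roi_id}_crossk.csv", index=False)
                        auc = ck.auc
                row["auc"] = auc
                crossk_results[roi_id] = auc
                cells.to_csv(out / f"{roi_id}_cells.csv", index=False)
                all_cells.append(cells)
                summary_rows.append(row)
                manifest["rois"][roi_id] = {"n_cells": row["n_total"]}
            except RoiCellError as exc:
                raise RoiCellError(f"ROI {roi_id!r} failed: {exc}") from exc

        summary = pd.DataFrame(summary_rows)
        groups: dict[str, str] = {}
        if config.mixing_rule is not None and len(summary):
            scored = {
                roi: auc
                for roi, auc in crossk_results.items()
                if np.isfinite(auc)
            }
            if scored:
                groups = classify_mixing(scored, config.mixing_rule)
                summary["group"] = summary["roi_id"].map(groups)
        summary.to_csv(out / "summary.csv", index=False)
        if all_cells:
            pd.concat(all_cells, ignore_index=True).to_csv(
                out / "cells_combined.csv", index=False
            )
        manifest["stages"]["imaging"] = {
            "n_rois": len(summary_rows),
            "summary": str(out / "summary.csv"),
        }
        manifest["groups"] = groups
    else:
        groups = {}

    if config.probe_matrix is not None:
        probe_df = pd.read_csv(config.probe_matrix, index_col=0)
        mapping = pd.read_csv(config.probe_map, sep="\t", index_col=0).iloc[:, 0]
        m = preprocess(
            probe_df,
            mapping,
            min_gene_frac=config.min_gene_frac,
            min_roi_frac=config.min_roi_frac,
        )
        m.values.to_csv(out / "expression_normalized.csv")
        manifest["stages"]["expression"] = {
            "n_genes": len(m.gene_ids),
            "n_segments": len(m.segment_ids),
            "history": m.history,
        }

        if config.rl_table is not None:
            table = load_ligand_target_table(config.rl_table)
            group_sets: dict[str, list[str]] = {}
            for seg in m.segment_ids:
                group_sets.setdefault(groups.get(seg, "all"), []).append(seg)
            results = {
                g: predict_rl_pairs(
                    m, segs, table, r_threshold=config.r_threshold, group=g
                )
                for g, segs in sorted(group_sets.items())
                if len(segs) >= 3
            }
            for g, res in results.items():
                res.pairs.to_csv(out / f"rl_pairs_{g}.csv", index=False)
            manifest["stages"]["rl"] = {
                g: len(res.pairs) for g, res in results.items()
            }
            if len(results) == 2:
                a, b = list(results.values())
                report = compare_groups(a, b)
                report.table.to_csv(out / "rl_comparison.csv", index=False)
                manifest["stages"]["rl_comparison"] = {
                    "shared": report.n_shared,
                    "unique_a": report.n_unique_a,
                    "unique_b": report.n_unique_b,
                }

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
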