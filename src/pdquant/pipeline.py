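"""End-to-end orchestration: single-image and batch analysis.

``analyze_image`` runs the full chain on an in-memory image:
walls → skeleton → junctions → wall segments → cells → puncta → relational
graph → quantification, returning the validated graph and the
:class:`AnalysisRecord`. ``analyze_single`` adds file I/O around it;
``analyze_batch`` maps it over a directory with per-image failure isolation
and a pooled per-condition summary.

Every run is a pure function of (image, config): rerunning with the same
inputs produces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .image_io import (AnalysisRecord, TissueImage, read_tissue_image,
                       write_outputs)
from .puncta_detect import (auto_threshold, detect_local_maxima,
                            measure_intensity, preprocess_puncta)
from .quantify import per_cell_table, per_wall_table
from .relational_graph import build_graph
from .wall_network import (find_junctions, label_cells, measure_length,
                           preprocess_walls, skeletonize_walls, split_walls)

logger = logging.getLogger("pdquant")


class StageError(RuntimeError):
    """Failure wrapped with the pipeline stage where it occurred."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r}: {original}")
        self.stage = stage
        self.original = original


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc


def analyze_image(image: TissueImage,
                  config: Optional[PipelineConfig] = None) -> tuple:
    """Run the full analysis on an in-memory image.

    Returns ``(graph, record, tables)`` where ``tables`` is a dict with the
    per-wall and per-cell DataFrames.
    """
    config = config or PipelineConfig()
    px = image.pixel_size

    mask = _stage("preprocess_walls", preprocess_walls,
                  image.wall_channel,
                  smoothing_sigma=config.wall_smoothing_sigma,
                  threshold_method=config.wall_threshold_method,
                  threshold_value=config.wall_threshold_value,
                  invert=config.wall_invert)
    skel = _stage("skeletonize", skeletonize_walls, mask,
                  prune_length_px=config.prune_length_px)
    junctions = _stage("find_junctions", find_junctions, skel,
                       merge_gap_px=config.junction_merge_gap_px)
    walls = _stage("split_walls", split_walls, skel, junctions)
    for w in walls:
        w.length_um = measure_length(w, px)
    cells, cell_label_img = _stage("label_cells", label_cells, skel,
                                   image.shape, px)
    logger.info("segmentation: %d cells, %d walls, %d junctions",
                len(cells), len(walls), len(junctions))

    prepped = _stage("preprocess_puncta", preprocess_puncta,
                     image.puncta_channel,
                     smoothing_sigma=config.puncta_smoothing_sigma,
                     background_radius=config.background_radius_px)
    thr = config.min_peak_intensity
    if thr is None:
        thr = auto_threshold(prepped, k=config.auto_threshold_k)
    puncta = _stage("detect_puncta", detect_local_maxima, prepped,
                    min_intensity=thr,
                    min_separation=config.min_separation_px)
    for p in puncta:
        measure_intensity(image.puncta_channel, p,
                          radius=config.integration_radius_px)
    logger.info("detection: %d puncta (threshold %.2f)", len(puncta), thr)

    graph = _stage("build_graph", build_graph, cells, walls, junctions,
                   puncta, px, cell_label_img,
                   parent_search_tolerance_um=config.parent_search_tolerance_um)
    logger.info("graph: %d assigned puncta, %d orphans",
                len(graph.assigned_puncta), len(graph.orphans))

    wall_rows = _stage("quantify_walls", per_wall_table, graph,
                       image.puncta_channel)
    cell_rows = _stage("quantify_cells", per_cell_table, graph, wall_rows)

    record = _build_record(image, config, graph, wall_rows, cell_rows)
    return graph, record, {"walls": wall_rows, "cells": cell_rows}


def _build_record(image, config, graph, wall_rows, cell_rows) -> AnalysisRecord:
    junction_rows = [{
        "junction_id": j.junction_id,
        "row": round(j.position[0], 3),
        "col": round(j.position[1], 3),
        "wall_ids": ";".join(str(w) for w in sorted(j.wall_ids)),
    } for j in graph.junctions]
    punctum_rows = [{
        "punctum_id": p.punctum_id,
        "row": round(p.position[0], 3),
        "col": round(p.position[1], 3),
        "peak_intensity": p.peak_intensity,
        "integrated_intensity": p.integrated_intensity,
        "wall_id": p.wall_id,
        "distance_to_wall_um": (round(p.distance_to_wall_um, 6)
                                if np.isfinite(p.distance_to_wall_um) else ""),
    } for p in graph.puncta]
    return AnalysisRecord(
        config=config.to_dict(),
        metadata={
            "source_id": image.source_id,
            "condition_label": image.condition_label,
            "shape_rows": image.shape[0],
            "shape_cols": image.shape[1],
            "pixel_size_um": image.pixel_size,
        },
        cells=cell_rows.to_dict("records"),
        walls=wall_rows.round(6).to_dict("records"),
        junctions=junction_rows,
        puncta=punctum_rows,
        version=__version__,
    )


def analyze_single(image_path: str | Path, config: Optional[PipelineConfig] = None,
                   out_dir: Optional[str | Path] = None,
                   condition_label: str = "") -> tuple:
    """Read an image file, analyze it, write all outputs.

    Returns ``(record, written_paths)``.
    """
    config = config or PipelineConfig()
    image = _stage("read", read_tissue_image, image_path,
                   pixel_size_override=config.pixel_size_override)
    if condition_label:
        image.condition_label = condition_label
    graph, record, _ = analyze_image(image, config)
    paths = []
    if out_dir is not None:
        paths = _stage("write", write_outputs, record, out_dir,
                       image=image, graph=graph)
    return record, paths


def analyze_batch(input_dir: str | Path, config: Optional[PipelineConfig] = None,
                  out_dir: Optional[str | Path] = None,
                  manifest: Optional[str | Path] = None) -> tuple:
    """Analyze every TIFF in a directory; isolate per-image failures.

    Condition labels come from an optional manifest CSV with columns
    ``filename, condition``; unlisted files get the label ``""``. Returns
    ``(records, failures, summary)`` where ``summary`` is the pooled
    per-condition table (cell-weighted mean per-cell callose, PD density).
    """
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    files = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise ValueError(f"no TIFF images in {input_dir}")

    labels = {}
    if manifest is not None:
        mdf = pd.read_csv(manifest, dtype=str)
        labels = dict(zip(mdf["filename"], mdf["condition"]))

    records, failures = [], []
    for f in files:
        sub = Path(out_dir) / f.stem if out_dir is not None else None
        try:
            record, _ = analyze_single(f, config, out_dir=sub,
                                       condition_label=labels.get(f.name, ""))
            records.append(record)
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            logger.error("image %s failed: %s", f.name, exc)
            failures.append({"filename": f.name, "error": str(exc)})

    summary = pool_summary(records)
    if out_dir is not None and records:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        summary.to_csv(Path(out_dir) / "summary.csv", index=False)
        if failures:
            pd.DataFrame(failures).to_csv(Path(out_dir) / "failures.csv",
                                          index=False)
    return records, failures, summary


def pool_summary(records: list) -> pd.DataFrame:
    """Pool per-cell statistics over images, grouped by condition label.

    The pooled per-cell callose mean equals the mean over all cells of all
    images in the condition (i.e. per-image means weighted by cell counts).
    """
    rows = []
    for rec in records:
        cond = rec.metadata.get("condition_label", "")
        for c in rec.cells:
            rows.append({"condition": cond, "source": rec.metadata["source_id"],
                         "periphery_callose_sum": c["periphery_callose_sum"],
                         "n_pd": c["n_pd"], "pd_per_um": c["pd_per_um"]})
    if not rows:
        return pd.DataFrame(columns=["condition", "n_images", "n_cells",
                                     "mean_periphery_callose", "mean_pd_per_um",
                                     "total_pd"])
    df = pd.DataFrame(rows)
    out = df.groupby("condition", sort=True).agg(
        n_images=("source", "nunique"),
        n_cells=("periphery_callose_sum", "size"),
        mean_periphery_callose=("periphery_callose_sum", "mean"),
        mean_pd_per_um=("pd_per_um", "mean"),
        total_pd=("n_pd", "sum"),
    ).reset_index()
    return out


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
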