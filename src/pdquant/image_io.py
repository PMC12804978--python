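"""Image input and output artifacts.

Reads two-channel tissue images (multi-page TIFF: page 1 = cell-wall stain,
page 2 = callose/PD immunofluorescence) and writes the full set of analysis
outputs: four CSV tables (cells, walls, junctions, puncta), a comprehensive
``analysis.json`` holding tables + parameters + image metadata, per-channel
PNGs, a composite overlay PNG and a zip archive.

Conventions (stated in every CSV header comment):

* coordinates are 0-based ``(row, col)`` pixel centers;
* lengths and areas are in µm / µm² using the image pixel size;
* channel order is fixed: wall channel first, puncta channel second;
* the sentinel ``BORDER`` marks a wall side facing the image border region,
  ``ORPHAN`` marks a punctum with no parent wall within tolerance.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from . import __version__

BORDER = "BORDER"
ORPHAN = "ORPHAN"

CELL_COLUMNS = [
    "cell_id", "centroid_row", "centroid_col", "area_um2", "n_walls",
    "periphery_callose_sum", "n_pd", "pd_per_um",
]
WALL_COLUMNS = [
    "wall_id", "junction_id_a", "junction_id_b", "cell_id_1", "cell_id_2",
    "length_um", "mean_callose_intensity", "n_pd", "pd_total_intensity",
    "pd_per_um",
]
JUNCTION_COLUMNS = ["junction_id", "row", "col", "wall_ids"]
PUNCTUM_COLUMNS = [
    "punctum_id", "row", "col", "peak_intensity", "integrated_intensity",
    "wall_id", "distance_to_wall_um",
]


@dataclass
class TissueImage:
    """Two registered intensity channels plus pixel size and provenance."""

    wall_channel: np.ndarray
    puncta_channel: np.ndarray
    pixel_size: float  # µm per pixel, isotropic
    source_id: str = ""
    condition_label: str = ""

    def __post_init__(self):
        self.wall_channel = np.asarray(self.wall_channel, dtype=float)
        self.puncta_channel = np.asarray(self.puncta_channel, dtype=float)
        if self.wall_channel.shape != self.puncta_channel.shape:
            raise ValueError(
                "channel shapes differ: "
                f"{self.wall_channel.shape} vs {self.puncta_channel.shape}"
            )
        if self.wall_channel.ndim != 2:
            raise ValueError("channels must be 2-D")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        for name, ch in (("wall", self.wall_channel), ("puncta", self.puncta_channel)):
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"{name} channel contains non-finite values")
            if ch.min() < 0:
                raise ValueError(f"{name} channel contains negative intensities")

    @property
    def shape(self) -> tuple:
        return self.wall_channel.shape


@dataclass
class AnalysisRecord:
    """Everything one analysis produced: tables, parameters, metadata.

    Round-trips losslessly through the JSON writer/reader; every id referenced
    in any table must exist in its own table (checked by :meth:`validate`).
    """

    config: dict
    metadata: dict
    cells: list = field(default_factory=list)
    walls: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    puncta: list = field(default_factory=list)
    version: str = __version__

    def validate(self) -> None:
        cell_ids = {c["cell_id"] for c in self.cells}
        wall_ids = {w["wall_id"] for w in self.walls}
        junction_ids = {j["junction_id"] for j in self.junctions}
        for w in self.walls:
            for key in ("cell_id_1", "cell_id_2"):
                cid = w[key]
                if cid not in (BORDER, "", None) and cid not in cell_ids:
                    raise ValueError(f"wall {w['wall_id']}: unknown cell id {cid!r}")
            for key in ("junction_id_a", "junction_id_b"):
                jid = w[key]
                if jid not in ("", None) and jid not in junction_ids:
                    raise ValueError(f"wall {w['wall_id']}: unknown junction id {jid!r}")
        for p in self.puncta:
            wid = p["wall_id"]
            if wid != ORPHAN and wid not in wall_ids:
                raise ValueError(f"punctum {p['punctum_id']}: unknown wall id {wid!r}")
        for j in self.junctions:
            for wid in str(j["wall_ids"]).split(";") if j["wall_ids"] else []:
                if int(wid) not in wall_ids:
                    raise ValueError(f"junction {j['junction_id']}: unknown wall id {wid}")

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "metadata": self.metadata,
            "cells": self.cells,
            "walls": self.walls,
            "junctions": self.junctions,
            "puncta": self.puncta,
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisRecord":
        return cls(
            config=d["config"], metadata=d["metadata"], cells=d["cells"],
            walls=d["walls"], junctions=d["junctions"], puncta=d["puncta"],
            version=d["version"],
        )


def read_tissue_image(path: str | Path,
                      pixel_size_override: Optional[float] = None) -> TissueImage:
    """Read a two-channel multi-page TIFF into a :class:`TissueImage`.

    Page/channel 1 is mapped to the wall channel and page/channel 2 to the
    puncta channel. The pixel size is taken from the TIFF resolution tags
    (unit assumed µm) unless ``pixel_size_override`` is given. A missing
    pixel size with no override is an explicit error, never a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        pixel_size = _pixel_size_from_tags(tf)
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        raise ValueError("puncta channel missing: file has a single page/channel")
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-channel 2-D image, got shape {arr.shape}")
    # channels-first (pages) is the written convention; accept channels-last
    if arr.shape[0] > 4 and arr.shape[-1] <= 4:
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] < 2:
        raise ValueError("puncta channel missing: file has a single page/channel")
    if pixel_size_override is not None:
        pixel_size = float(pixel_size_override)
    if pixel_size is None:
        raise ValueError(
            "pixel size absent from TIFF metadata; pass pixel_size_override"
        )
    return TissueImage(
        wall_channel=arr[0].astype(float),
        puncta_channel=arr[1].astype(float),
        pixel_size=pixel_size,
        source_id=path.name,
    )


def _pixel_size_from_tags(tf: "tifffile.TiffFile") -> Optional[float]:
    page = tf.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0 or (num, den) == (1, 1):
        return None  # writers emit 1 px/unit when no resolution was set
    return den / num  # resolution stored as pixels per µm


def write_tissue_image(img: TissueImage, path: str | Path) -> Path:
    """Write a :class:`TissueImage` as a two-page TIFF with µm pixel size."""
    path = Path(path)
    stack = np.stack([img.wall_channel, img.puncta_channel]).astype(np.float32)
    res = 1.0 / img.pixel_size
    tifffile.imwrite(path, stack, imagej=True, resolution=(res, res),
                     metadata={"unit": "um", "axes": "CYX"})
    return path


def _table(rows: list, columns: list) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=columns)
    return df.fillna("")


def write_outputs(record: AnalysisRecord, out_dir: str | Path,
                  image: Optional[TissueImage] = None,
                  graph=None) -> list:
    """Write all output artifacts for one analysis; return the file paths.

    Always writes ``cells.csv``, ``walls.csv``, ``junctions.csv``,
    ``puncta.csv`` (fixed column order, header-only when empty) and
    ``analysis.json``. When ``image`` is given, additionally writes one PNG
    per channel and a composite overlay PNG (detections marked; the skeleton
    trace is included when ``graph`` is given).
    """
    record.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    for name, rows, cols in (
        ("cells.csv", record.cells, CELL_COLUMNS),
        ("walls.csv", record.walls, WALL_COLUMNS),
        ("junctions.csv", record.junctions, JUNCTION_COLUMNS),
        ("puncta.csv", record.puncta, PUNCTUM_COLUMNS),
    ):
        p = out_dir / name
        _table(rows, cols).to_csv(p, index=False)
        paths.append(p)

    jp = out_dir / "analysis.json"
    with open(jp, "w") as fh:
        json.dump(record.to_dict(), fh, indent=1)
    paths.append(jp)

    if image is not None:
        import imageio.v3 as iio
        from .visualize import render_overlay

        for name, ch in (("wall_channel.png", image.wall_channel),
                         ("puncta_channel.png", image.puncta_channel)):
            p = out_dir / name
            iio.imwrite(p, _to_uint8(ch))
            paths.append(p)
        p = out_dir / "overlay.png"
        iio.imwrite(p, render_overlay(image, graph=graph, record=record))
        paths.append(p)
    return paths


def _to_uint8(channel: np.ndarray) -> np.ndarray:
    lo, hi = float(channel.min()), float(channel.max())
    if hi <= lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    return np.round(255 * (channel - lo) / (hi - lo)).astype(np.uint8)


def read_analysis_json(path: str | Path) -> AnalysisRecord:
    with open(path) as fh:
        return AnalysisRecord.from_dict(json.load(fh))


def pack_archive(out_dir: str | Path, zip_path: Optional[str | Path] = None) -> Path:
    """Zip every file in ``out_dir`` (paths relative to it) into one archive."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*") if p.is_file()
                   and p.suffix != ".zip")
    if not files:
        raise ValueError(f"no output files in {out_dir}")
    if zip_path is None:
        zip_path = out_dir / f"{out_dir.name}.zip"
    zip_path = Path(zip_path)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for f in files:
            zf.write(f, f.relative_to(out_dir))
    return zip_path
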