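"""Visual outputs: per-cell heat maps, interface maps, detection overlays,
timing histograms.

All functions are pure reads of the analysis results — they never modify the
record or the graph. Color mapping is monotone in the plotted metric, and a
fixed scale (``vmin``/``vmax``) can be supplied so that images from different
conditions share one legend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps

from .image_io import BORDER, ORPHAN, TissueImage


@dataclass
class HeatmapSpec:
    """What to plot and how to scale it."""

    metric: str
    vmin: Optional[float] = None      # None = auto from the data
    vmax: Optional[float] = None
    colormap: str = "viridis"
    legend_label: str = ""


def _scale(values: np.ndarray, spec: HeatmapSpec) -> tuple:
    vmin = spec.vmin if spec.vmin is not None else float(np.min(values))
    vmax = spec.vmax if spec.vmax is not None else float(np.max(values))
    degenerate = vmax <= vmin
    if degenerate:
        vmax = vmin + 1.0
    return vmin, vmax, degenerate


def render_cell_heatmap(graph, cell_table, spec: HeatmapSpec,
                        out_path: Optional[str | Path] = None) -> np.ndarray:
    """Fill each cell region with the colormap value of its metric.

    Walls stay black as boundaries; a legend bar shows the scale. Returns the
    RGB array; also writes a PNG with a color bar when ``out_path`` is given.
    """
    if spec.metric not in cell_table.columns:
        raise ValueError(f"unknown metric {spec.metric!r}")
    values = cell_table.set_index("cell_id")[spec.metric].astype(float)
    vmin, vmax, degenerate = _scale(values.to_numpy(), spec)
    cmap = colormaps[spec.colormap]

    label_img = graph.cell_label_img
    rgb = np.zeros(label_img.shape + (3,), dtype=float)
    for cid, val in values.items():
        t = (val - vmin) / (vmax - vmin)
        rgb[label_img == cid + 1] = cmap(float(np.clip(t, 0, 1)))[:3]
    out = np.round(rgb * 255).astype(np.uint8)

    if out_path is not None:
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(out)
        ax.set_axis_off()
        sm = plt.cm.ScalarMappable(
            cmap=cmap, norm=plt.Normalize(vmin=vmin, vmax=vmax))
        label = spec.legend_label or spec.metric
        if degenerate:
            label += " (uniform value)"
        fig.colorbar(sm, ax=ax, label=label, shrink=0.8)
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return out


def render_interface_map(graph, interfaces, spec: Optional[HeatmapSpec] = None,
                         out_path: Optional[str | Path] = None) -> np.ndarray:
    """Draw each shared wall in the colormap value of its interface PD count.

    ``interfaces`` is the validated per-interface table (``cell_id_1,
    cell_id_2, pd_count``); an interface whose cell pair shares no wall in
    the graph is an error.
    """
    spec = spec or HeatmapSpec(metric="pd_count", legend_label="PD per interface")
    cmap = colormaps[spec.colormap]
    pair_to_wall = {}
    for w in graph.walls:
        a, b = w.cell_ids
        if BORDER not in (a, b):
            pair_to_wall[tuple(sorted((a, b)))] = w

    counts = {}
    for row in interfaces.itertuples(index=False):
        key = tuple(sorted((row.cell_id_1, row.cell_id_2)))
        if key not in pair_to_wall:
            raise ValueError(f"interface {key} has no shared wall in the graph")
        counts[key] = float(row.pd_count)

    vals = np.array(list(counts.values())) if counts else np.array([0.0])
    vmin, vmax, _ = _scale(vals, spec)

    shape = graph.cell_label_img.shape
    rgb = np.zeros(shape + (3,), dtype=float)
    # context: all walls in dim gray
    for w in graph.walls:
        for r, c in w.path:
            rgb[r, c] = (0.3, 0.3, 0.3)
    for key, n in counts.items():
        t = float(np.clip((n - vmin) / (vmax - vmin), 0, 1))
        color = cmap(t)[:3]
        for r, c in pair_to_wall[key].path:
            rgb[r, c] = color
    out = (rgb * 255).astype(np.uint8)

    if out_path is not None:
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(out)
        ax.set_axis_off()
        sm = plt.cm.ScalarMappable(
            cmap=cmap, norm=plt.Normalize(vmin=vmin, vmax=vmax))
        fig.colorbar(sm, ax=ax, label=spec.legend_label or spec.metric,
                     shrink=0.8)
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return out


def render_overlay(image: TissueImage, graph=None, record=None) -> np.ndarray:
    """Composite for visual inspection of detections.

    Wall channel in gray, skeleton trace in green, junction markers in blue,
    punctum markers in red (assigned) or yellow (orphan). Marker sources come
    from ``graph`` when given, else from the ``record`` tables. Output has
    the input image dimensions.
    """
    ch = image.wall_channel
    lo, hi = float(ch.min()), float(ch.max())
    gray = (ch - lo) / (hi - lo) if hi > lo else np.zeros_like(ch)
    rgb = np.stack([gray, gray, gray], axis=-1)

    junction_pts = []
    puncta_pts = []
    if graph is not None:
        for w in graph.walls:
            for r, c in w.path:
                rgb[r, c] = (0.1, 0.9, 0.1)
        junction_pts = [(j.position, False) for j in graph.junctions]
        puncta_pts = [(p.position, p.wall_id == ORPHAN) for p in graph.puncta]
    elif record is not None:
        junction_pts = [((j["row"], j["col"]), False) for j in record.junctions]
        puncta_pts = [((p["row"], p["col"]), p["wall_id"] == ORPHAN)
                      for p in record.puncta]

    for (r, c), _ in junction_pts:
        _mark(rgb, r, c, (0.2, 0.4, 1.0), size=2)
    for (r, c), orphan in puncta_pts:
        _mark(rgb, r, c, (1.0, 1.0, 0.2) if orphan else (1.0, 0.15, 0.15),
              size=1)
    return (rgb * 255).astype(np.uint8)


def _mark(rgb: np.ndarray, r: float, c: float, color: tuple, size: int) -> None:
    ri, ci = int(round(r)), int(round(c))
    r0, r1 = max(0, ri - size), min(rgb.shape[0], ri + size + 1)
    c0, c1 = max(0, ci - size), min(rgb.shape[1], ci + size + 1)
    rgb[r0:r1, c0:c1] = color


def plot_timing_histogram(histogram, label: str, out_path: str | Path) -> None:
    """Bar plot of a bud-break timing histogram table."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    widths = histogram["bin_right"] - histogram["bin_left"]
    ax.bar(histogram["bin_left"], histogram["count"], width=widths,
           align="edge", edgecolor="black")
    ax.set_xlabel("days to bud break")
    ax.set_ylabel("plants")
    ax.set_title(label)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
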