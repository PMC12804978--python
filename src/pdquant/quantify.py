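"""Quantitative read-outs of the relational model.

Granularities:

* per wall — segment length (µm), PD count, PD per µm, total PD intensity,
  and the mean callose-channel intensity over the wall path dilated by 1 px;
* per cell — area, wall count, periphery callose sum (the sum over the
  cell's walls of their mean callose intensity), PD on the periphery and PD
  per µm of periphery. A wall shared by two cells contributes fully to both
  (a plasmodesma is a channel of both cells), so summing ``n_pd`` over cells
  double-counts interior-wall puncta by convention.
* immunogold density — gold-particle count normalized by a standard window
  (default 0.025 µm²), for TEM callose quantification;
* per interface — manually counted PD per cell–cell interface (TEM mapping)
  with per-cell aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import BORDER, ORPHAN
from .relational_graph import IntegrityError, WallGraph

#: standard normalization window for immunogold counting, µm²
DEFAULT_GOLD_WINDOW_UM2 = 0.025


@dataclass
class GoldDensity:
    particle_count: int
    window_area_um2: float
    density_per_um2: float


def wall_mean_intensity(wall, channel: np.ndarray) -> float:
    """Mean channel intensity over the wall path dilated by 1 px (3×3)."""
    shape = channel.shape
    pixels = set()
    for r, c in wall.path:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                    pixels.add((rr, cc))
    if not pixels:
        return 0.0
    idx = np.array(sorted(pixels))
    return float(channel[idx[:, 0], idx[:, 1]].mean())


def per_wall_table(graph: WallGraph, puncta_channel: np.ndarray) -> pd.DataFrame:
    """One row per wall segment.

    Density is ``n_pd / length``; a zero-length wall gets density 0 and a
    ``zero_length`` flag rather than a division error.
    """
    by_wall: dict = {w.wall_id: [] for w in graph.walls}
    for p in graph.puncta:
        if p.wall_id != ORPHAN:
            by_wall[p.wall_id].append(p)

    rows = []
    for w in graph.walls:
        pd_list = by_wall[w.wall_id]
        length = w.length_um
        if length > 0:
            density = len(pd_list) / length
            flags = ";".join(w.flags)
        else:
            density = 0.0
            flags = ";".join(sorted(set(w.flags) | {"zero_length"}))
        jids = list(w.junction_ids) + ["", ""]
        cids = list(w.cell_ids) + [BORDER, BORDER]
        rows.append({
            "wall_id": w.wall_id,
            "junction_id_a": jids[0],
            "junction_id_b": jids[1],
            "cell_id_1": cids[0],
            "cell_id_2": cids[1],
            "length_um": length,
            "mean_callose_intensity": wall_mean_intensity(w, puncta_channel),
            "n_pd": len(pd_list),
            "pd_total_intensity": float(sum(p.integrated_intensity
                                            for p in pd_list)),
            "pd_per_um": density,
            "flags": flags,
        })
    return pd.DataFrame(
        rows, columns=["wall_id", "junction_id_a", "junction_id_b",
                       "cell_id_1", "cell_id_2", "length_um",
                       "mean_callose_intensity", "n_pd",
                       "pd_total_intensity", "pd_per_um", "flags"])


def per_cell_table(graph: WallGraph, wall_rows: pd.DataFrame) -> pd.DataFrame:
    """One row per cell, aggregating over its bounding walls.

    ``periphery_callose_sum`` is the sum of the cell's walls' mean callose
    intensities; each shared wall contributes fully to both of its cells.
    """
    wall_idx = wall_rows.set_index("wall_id")
    rows = []
    for c in graph.cells:
        if not c.wall_ids:
            raise IntegrityError(f"cell {c.cell_id} has no bounding walls")
        sub = wall_idx.loc[c.wall_ids]
        periphery_len = float(sub["length_um"].sum())
        n_pd = int(sub["n_pd"].sum())
        rows.append({
            "cell_id": c.cell_id,
            "centroid_row": c.centroid[0],
            "centroid_col": c.centroid[1],
            "area_um2": c.area_um2,
            "n_walls": len(c.wall_ids),
            "periphery_callose_sum": float(sub["mean_callose_intensity"].sum()),
            "n_pd": n_pd,
            "pd_per_um": n_pd / periphery_len if periphery_len > 0 else 0.0,
        })
    return pd.DataFrame(
        rows, columns=["cell_id", "centroid_row", "centroid_col", "area_um2",
                       "n_walls", "periphery_callose_sum", "n_pd",
                       "pd_per_um"])


def gold_density(count: int, window_area_um2: float = DEFAULT_GOLD_WINDOW_UM2
                 ) -> GoldDensity:
    """Normalize a gold-particle count to particles/µm² of window."""
    if count < 0:
        raise ValueError("particle count must be >= 0")
    if not window_area_um2 > 0:
        raise ValueError("window area must be > 0")
    return GoldDensity(particle_count=int(count),
                       window_area_um2=float(window_area_um2),
                       density_per_um2=count / window_area_um2)


def interface_table(counts, cells=None) -> tuple:
    """Per-interface PD counts plus per-cell aggregates.

    ``counts`` is an iterable of ``(cell_id_1, cell_id_2, pd_count)`` (or a
    DataFrame with those columns) keyed by *unordered* pair: (A, B) and
    (B, A) are the same interface and a duplicate raises. When ``cells`` is
    given, unknown cell ids raise.

    Returns ``(interfaces, per_cell)`` DataFrames; a cell's aggregate is the
    sum of counts over every interface touching it.
    """
    if isinstance(counts, pd.DataFrame):
        counts = counts[["cell_id_1", "cell_id_2", "pd_count"]].itertuples(
            index=False)
    known = None
    if cells is not None:
        known = {c.cell_id for c in cells} if not isinstance(cells, (set, list)) \
            else set(c.cell_id if hasattr(c, "cell_id") else c for c in cells)

    seen = {}
    for a, b, n in counts:
        if n < 0:
            raise ValueError(f"negative PD count for interface ({a}, {b})")
        key = (a, b) if str(a) <= str(b) else (b, a)
        if key in seen:
            raise ValueError(f"duplicate interface {key}")
        if known is not None:
            for cid in key:
                if cid not in known:
                    raise ValueError(f"unknown cell id {cid!r} in interface {key}")
        seen[key] = int(n)

    interfaces = pd.DataFrame(
        [{"cell_id_1": a, "cell_id_2": b, "pd_count": n}
         for (a, b), n in sorted(seen.items(), key=lambda kv: kv[0])],
        columns=["cell_id_1", "cell_id_2", "pd_count"])
    agg: dict = {}
    for (a, b), n in seen.items():
        agg[a] = agg.get(a, 0) + n
        agg[b] = agg.get(b, 0) + n
    per_cell = pd.DataFrame(
        [{"cell_id": cid, "pd_total": n} for cid, n in sorted(agg.items())],
        columns=["cell_id", "pd_total"])
    return interfaces, per_cell
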