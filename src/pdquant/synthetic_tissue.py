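"""Synthetic ground-truth tissue: tessellation, puncta placement, rendering.

Real meristem-surface images have no deposited ground truth, so every
pipeline stage is validated against simulated tissue with exact labels:

* a Voronoi tessellation of a jittered rectangular lattice emulates the
  polygonal cell packing of the meristem surface (generic Voronoi guarantees
  tri-junctions; jitter 0 degenerates to the exact square lattice whose
  interior crossings are degree-4 stress cases);
* puncta are placed along wall polylines by a hard-core renewal process
  with an exact linear rate, so each punctum's parent wall and the true
  density are known by construction;
* rendering draws walls as ridges of configurable width, blurs with a
  Gaussian PSF, adds Gaussian spots for the puncta, plus background and
  additive Gaussian read noise.

Identical seeds produce identical ground truth and identical renders.
Geometry is kept in µm with the convention ``col = x / pixel_size``,
``row = y / pixel_size`` (pixel centers on the integer grid).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Polygon, box
from shapely.ops import linemerge, unary_union
from skimage.draw import line as draw_line
from skimage.filters import gaussian
from skimage.morphology import dilation, disk

from .image_io import BORDER, TissueImage

_COORD_DECIMALS = 6  # snap grid for exact planar noding


@dataclass
class GroundTruth:
    """Exact tessellation + puncta labels used as the test oracle."""

    cells: list          # {cell_id, polygon [(x, y) µm], area_um2, wall_ids}
    walls: list          # {wall_id, polyline, junction_ids, cell_ids, length_um}
    junctions: list      # {junction_id, x, y, wall_ids}
    puncta: list = field(default_factory=list)
    # {punctum_id, x, y, wall_id, amplitude}
    pixel_size: float = 0.25          # µm/px
    shape: tuple = (0, 0)             # (rows, cols)
    wall_width_px: int = 3
    psf_sigma_px: float = 1.0
    spot_sigma_px: float = 1.2
    wall_amplitude: float = 150.0
    puncta_amplitude: float = 200.0
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_walls(self) -> int:
        return len(self.walls)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    def punctum_pixels(self) -> np.ndarray:
        """True punctum positions as (row, col) pixel coordinates."""
        if not self.puncta:
            return np.zeros((0, 2))
        return np.array([[p["y"] / self.pixel_size, p["x"] / self.pixel_size]
                         for p in self.puncta])

    def junction_pixels(self) -> np.ndarray:
        if not self.junctions:
            return np.zeros((0, 2))
        return np.array([[j["y"] / self.pixel_size, j["x"] / self.pixel_size]
                         for j in self.junctions])

    def total_wall_length_um(self) -> float:
        return float(sum(w["length_um"] for w in self.walls))

    def replace(self, **kw) -> "GroundTruth":
        return dataclasses.replace(self, **kw)


def _snap(poly: Polygon) -> Polygon:
    return Polygon(np.round(np.asarray(poly.exterior.coords), _COORD_DECIMALS))


def _voronoi_cells(nx: int, ny: int, jitter: float, pitch: float,
                   rng: np.random.Generator, vertex_merge: float) -> list:
    """Voronoi polygons of the nx·ny core points of a jittered lattice.

    Voronoi vertices closer than ``vertex_merge`` µm are snapped to their
    cluster centroid before polygons are built: a jittered lattice is close
    to the degenerate square lattice, so quads of nearly cocircular points
    produce pairs of tri-junction vertices separated by tiny edges. Snapping
    collapses those pairs into single (degree-4) junctions, which the
    downstream graph admits explicitly.
    """
    pad = 3  # rings of padding points so every core region is finite
    idx = {}
    pts = []
    for j in range(-pad, ny + pad):
        for i in range(-pad, nx + pad):
            x = (i + 0.5) * pitch + rng.uniform(-jitter, jitter) * pitch
            y = (j + 0.5) * pitch + rng.uniform(-jitter, jitter) * pitch
            idx[(i, j)] = len(pts)
            pts.append((x, y))
    vor = Voronoi(np.asarray(pts))
    verts = _merge_close_vertices(vor.vertices, vertex_merge)
    cells = []
    for j in range(ny):
        for i in range(nx):
            region = vor.regions[vor.point_region[idx[(i, j)]]]
            if -1 in region or len(region) < 3:
                raise RuntimeError("unbounded core Voronoi region")
            coords = [tuple(verts[v]) for v in region]
            coords = [c for k, c in enumerate(coords)
                      if c != coords[(k - 1) % len(coords)]]
            if len(coords) < 3:
                raise ValueError("unresolvable tessellation: degenerate cell")
            cells.append(_snap(Polygon(coords)))
    return cells


def _merge_close_vertices(vertices: np.ndarray, tol: float) -> np.ndarray:
    """Snap vertices closer than ``tol`` to their cluster centroid."""
    from scipy.spatial import cKDTree

    out = vertices.copy()
    if tol <= 0 or len(vertices) < 2:
        return out
    pairs = cKDTree(vertices).query_pairs(tol)
    parent = list(range(len(vertices)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    clusters: dict = {}
    for v in range(len(vertices)):
        clusters.setdefault(find(v), []).append(v)
    for members in clusters.values():
        if len(members) > 1:
            centroid = vertices[members].mean(axis=0)
            out[members] = centroid
    return out


def make_tessellation(nx: int, ny: int, jitter: float = 0.2,
                      cell_pitch: float = 8.0, pixel_size: float = 0.25,
                      seed: int = 0, margin_um: float = 2.0,
                      **render_params) -> GroundTruth:
    """Build a ground-truth tessellation of ``nx × ny`` cells.

    ``jitter`` is the uniform lattice perturbation as a fraction of the cell
    pitch (µm); ``jitter = 0`` gives the exact square lattice. The frame is
    the outer boundary of the union of the core cells; its corners are
    degree-2 points absorbed into border walls, while points where interior
    walls meet the frame are T-junctions.

    Raises ``ValueError("unresolvable tessellation")`` when the geometry
    could not be resolved at the requested pixel size (a wall segment
    shorter than 8 px, or a cell too thin to survive wall rendering).
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if not (0 <= jitter < 0.5):
        raise ValueError("jitter must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    vertex_merge = 8 * pixel_size

    last_err: Exception | None = None
    for _attempt in range(40 if jitter > 0 else 1):
        if jitter == 0:
            polys = [box(i * cell_pitch, j * cell_pitch,
                         (i + 1) * cell_pitch, (j + 1) * cell_pitch)
                     for j in range(ny) for i in range(nx)]
        else:
            polys = _voronoi_cells(nx, ny, jitter, cell_pitch, rng,
                                   vertex_merge)
        try:
            return _assemble(polys, pixel_size, margin_um, seed, render_params)
        except ValueError as err:
            if "unresolvable tessellation" not in str(err):
                raise
            last_err = err  # redraw the jitter and try again
    raise last_err


def _assemble(polys: list, pixel_size: float, margin_um: float, seed: int,
              render_params: dict) -> GroundTruth:
    # shift the tessellation so the frame sits margin_um inside the image
    minx = min(p.bounds[0] for p in polys)
    miny = min(p.bounds[1] for p in polys)
    shift = (margin_um - minx, margin_um - miny)
    polys = [_snap(Polygon([(x + shift[0], y + shift[1])
                            for x, y in p.exterior.coords])) for p in polys]

    maxx = max(p.bounds[2] for p in polys)
    maxy = max(p.bounds[3] for p in polys)
    shape = (int(np.ceil((maxy + margin_um) / pixel_size)) + 1,
             int(np.ceil((maxx + margin_um) / pixel_size)) + 1)

    # node the shared boundaries, then merge through degree-2 points
    noded = unary_union([p.exterior for p in polys])
    if noded.geom_type in ("LineString", "LinearRing"):
        lines = [LineString(noded)]
    else:
        merged = linemerge(noded)
        lines = list(merged.geoms) if merged.geom_type == "MultiLineString" \
            else [merged]

    # junctions = endpoints shared by >= 3 merged lines
    endpoint_count: dict = {}
    for ln in lines:
        coords = list(ln.coords)
        if coords[0] == coords[-1]:
            continue  # closed ring: no junction endpoints
        for pt in (coords[0], coords[-1]):
            endpoint_count[pt] = endpoint_count.get(pt, 0) + 1
    junction_coords = sorted(pt for pt, n in endpoint_count.items() if n >= 3)
    jid_of = {pt: i for i, pt in enumerate(junction_coords)}
    junctions = [{"junction_id": i, "x": pt[0], "y": pt[1], "wall_ids": []}
                 for i, pt in enumerate(junction_coords)]

    cells = [{"cell_id": i, "polygon": list(p.exterior.coords),
              "area_um2": p.area, "wall_ids": []}
             for i, p in enumerate(polys)]

    walls = []
    for wid, ln in enumerate(sorted(lines, key=lambda l: tuple(l.coords[0]))):
        coords = list(ln.coords)
        jids = tuple(jid_of[pt] for pt in (coords[0], coords[-1])
                     if pt in jid_of) if coords[0] != coords[-1] else ()
        mid = ln.interpolate(0.5, normalized=True)
        adjacent = [c["cell_id"] for c, p in zip(cells, polys)
                    if p.exterior.distance(mid) < 1e-7]
        if len(adjacent) == 2:
            cell_ids = tuple(adjacent)
        elif len(adjacent) == 1:
            cell_ids = (adjacent[0], BORDER)
        else:
            raise RuntimeError(f"wall {wid} adjacent to {len(adjacent)} cells")
        walls.append({"wall_id": wid, "polyline": coords,
                      "junction_ids": jids, "cell_ids": cell_ids,
                      "length_um": ln.length})
        for jid in jids:
            junctions[jid]["wall_ids"].append(wid)
        for cid in cell_ids:
            if cid != BORDER:
                cells[cid]["wall_ids"].append(wid)

    gt = GroundTruth(cells=cells, walls=walls, junctions=junctions,
                     pixel_size=pixel_size, shape=shape, seed=seed,
                     **render_params)

    min_len = min(w["length_um"] for w in walls)
    if min_len < 8 * pixel_size:
        raise ValueError(
            f"unresolvable tessellation: wall of {min_len:.3f} µm "
            f"< 8 px at {pixel_size} µm/px")
    # every cell must survive erosion by the rendered wall half-width in one
    # piece, and re-dilation must recover it up to corner nibbles: a wedge or
    # neck thinner than the drawn walls would bridge in the rendered mask
    inset = (gt.wall_width_px / 2 + 2) * pixel_size
    for c, p in zip(cells, polys):
        eroded = p.buffer(-inset)
        if eroded.is_empty or eroded.geom_type != "Polygon":
            raise ValueError(
                f"unresolvable tessellation: cell {c['cell_id']} thinner "
                f"than the rendered wall width")
        opened = eroded.buffer(inset)
        allowance = 4 * inset ** 2 * max(len(p.exterior.coords) - 1, 3)
        if p.area - opened.area > allowance:
            raise ValueError(
                f"unresolvable tessellation: cell {c['cell_id']} has a "
                f"region thinner than the rendered wall width")
    min_angle = _min_junction_angle(gt)
    if min_angle < _MIN_JUNCTION_ANGLE_DEG:
        raise ValueError(
            f"unresolvable tessellation: walls meet at {min_angle:.1f}° "
            f"(rendered ridges would merge beyond the junction)")
    return gt


#: minimum angle between walls incident to one junction. Below this the
#: rendered ridges (wall width + PSF) stay merged for several pixels past
#: the junction, i.e. two walls run closer than ~3 px and cannot be told
#: apart at the rendering resolution.
_MIN_JUNCTION_ANGLE_DEG = 45.0


def _min_junction_angle(gt: GroundTruth) -> float:
    """Smallest angular gap between walls incident to any junction."""
    best = 180.0
    wmap = {w["wall_id"]: w for w in gt.walls}
    for j in gt.junctions:
        dirs = []
        for wid in j["wall_ids"]:
            pl = wmap[wid]["polyline"]
            a = np.array([j["x"], j["y"]])
            first = np.allclose(pl[0], a, atol=1e-5)
            other = pl[1] if first else pl[-2]
            v = np.asarray(other) - a
            dirs.append(np.arctan2(v[1], v[0]))
        if len(dirs) < 2:
            continue
        d = np.sort(np.array(dirs))
        gaps = np.diff(np.concatenate([d, [d[0] + 2 * np.pi]]))
        best = min(best, float(np.degrees(gaps.min())))
    # interior polyline vertices (e.g. frame corners inside border arcs)
    # form wedges too: an acute turn merges in the render like an acute
    # junction does
    for w in gt.walls:
        pl = np.asarray(w["polyline"])
        for k in range(1, len(pl) - 1):
            v1 = pl[k - 1] - pl[k]
            v2 = pl[k + 1] - pl[k]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1)
            best = min(best, float(np.degrees(np.arccos(cosang))))
    return best


def place_puncta(gt: GroundTruth, rate: float, min_gap: float = 1.0,
                 seed: int = 0) -> GroundTruth:
    """Place puncta along wall polylines at the requested linear rate.

    ``rate`` is puncta per µm of wall. Along each wall, puncta follow a
    stationary hard-core renewal process: inter-punctum gaps are
    ``min_gap + Exponential`` with the exponential rate chosen so the mean
    gap is exactly ``1 / rate``, and the first punctum is drawn from the
    equilibrium forward-recurrence distribution, so the expected count per
    wall is exactly ``rate · length`` while no two puncta on one wall are
    closer than ``min_gap`` µm. (A homogeneous Poisson process thinned to the
    same hard core would systematically under-shoot the requested rate.)
    A final global greedy pass also enforces ``min_gap`` across walls, which
    removes a small number of puncta near junctions. Every punctum lies
    exactly on its parent polyline.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate > 0 and min_gap >= 1.0 / rate:
        raise ValueError("min_gap must be below the mean spacing 1/rate")
    rng = np.random.default_rng([seed, 1])
    candidates = []
    if rate > 0:
        mean_gap = 1.0 / rate
        exp_scale = mean_gap - min_gap  # mean of the exponential tail
        for w in gt.walls:
            ln = LineString(w["polyline"])
            length = w["length_um"]
            # equilibrium delay of a renewal process with gap = g + Exp:
            # uniform over the hard core with probability g/mean, else
            # hard core + exponential tail
            if rng.uniform() < min_gap / mean_gap:
                t = rng.uniform(0, min_gap)
            else:
                t = min_gap + rng.exponential(exp_scale)
            while t < length:
                pt = ln.interpolate(t)
                candidates.append((pt.x, pt.y, w["wall_id"]))
                t += min_gap + rng.exponential(exp_scale)
    kept = []
    for x, y, wid in candidates:
        if all((x - kx) ** 2 + (y - ky) ** 2 >= min_gap ** 2
               for kx, ky, _ in kept):
            kept.append((x, y, wid))
    puncta = [{"punctum_id": i, "x": x, "y": y, "wall_id": wid,
               "amplitude": gt.puncta_amplitude}
              for i, (x, y, wid) in enumerate(kept)]
    return gt.replace(puncta=puncta)


def render(gt: GroundTruth) -> TissueImage:
    """Render the two channels of a :class:`GroundTruth` as a TissueImage."""
    rows, cols = gt.shape
    px = gt.pixel_size

    wall_mask = np.zeros(gt.shape, dtype=bool)
    for w in gt.walls:
        pts = [(int(round(y / px)), int(round(x / px)))
               for x, y in w["polyline"]]
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
            wall_mask[rr[ok], cc[ok]] = True
    half = gt.wall_width_px // 2
    if half > 0:
        wall_mask = dilation(wall_mask, disk(half))
    wall = wall_mask.astype(float)
    if gt.psf_sigma_px > 0:
        wall = gaussian(wall, sigma=gt.psf_sigma_px, preserve_range=True)
    wall = gt.wall_amplitude * wall + gt.background

    puncta = np.full(gt.shape, gt.background, dtype=float)
    sigma = gt.spot_sigma_px
    for p in gt.puncta:
        r0 = p["y"] / px
        c0 = p["x"] / px
        if sigma > 0:
            w = int(np.ceil(4 * sigma)) + 1
            rlo, rhi = max(0, int(r0) - w), min(rows, int(r0) + w + 1)
            clo, chi = max(0, int(c0) - w), min(cols, int(c0) + w + 1)
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            puncta[rlo:rhi, clo:chi] += p["amplitude"] * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))
        else:
            puncta[int(round(r0)), int(round(c0))] += p["amplitude"]

    if gt.noise_sd > 0:
        rng = np.random.default_rng([gt.seed, 2])
        wall = wall + rng.normal(0, gt.noise_sd, gt.shape)
        puncta = puncta + rng.normal(0, gt.noise_sd, gt.shape)
    return TissueImage(
        wall_channel=np.clip(wall, 0, None),
        puncta_channel=np.clip(puncta, 0, None),
        pixel_size=px,
        source_id=f"synthetic(seed={gt.seed})",
        condition_label="synthetic",
    )


def ground_truth_tables(gt: GroundTruth) -> dict:
    """Ground truth in the analysis-record table schema (pixel coordinates)."""
    px = gt.pixel_size
    cells = [{"cell_id": c["cell_id"],
              "centroid_row": float(Polygon(c["polygon"]).centroid.y / px),
              "centroid_col": float(Polygon(c["polygon"]).centroid.x / px),
              "area_um2": c["area_um2"], "n_walls": len(c["wall_ids"]),
              "periphery_callose_sum": "", "n_pd": "", "pd_per_um": ""}
             for c in gt.cells]
    walls = []
    for w in gt.walls:
        jids = list(w["junction_ids"]) + ["", ""]
        n_pd = sum(1 for p in gt.puncta if p["wall_id"] == w["wall_id"])
        walls.append({
            "wall_id": w["wall_id"], "junction_id_a": jids[0],
            "junction_id_b": jids[1], "cell_id_1": w["cell_ids"][0],
            "cell_id_2": w["cell_ids"][1], "length_um": w["length_um"],
            "mean_callose_intensity": "", "n_pd": n_pd,
            "pd_total_intensity": "",
            "pd_per_um": n_pd / w["length_um"] if w["length_um"] else 0.0})
    junctions = [{"junction_id": j["junction_id"], "row": j["y"] / px,
                  "col": j["x"] / px,
                  "wall_ids": ";".join(str(w) for w in sorted(j["wall_ids"]))}
                 for j in gt.junctions]
    puncta = [{"punctum_id": p["punctum_id"], "row": p["y"] / px,
               "col": p["x"] / px, "peak_intensity": p["amplitude"],
               "integrated_intensity": "", "wall_id": p["wall_id"],
               "distance_to_wall_um": 0.0}
              for p in gt.puncta]
    return {"cells": cells, "walls": walls, "junctions": junctions,
            "puncta": puncta}
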