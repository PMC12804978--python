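"""Wall-channel segmentation: skeleton, junctions, wall segments, cells.

The wall stain of a meristem surface forms a connected network of bright
ridges that tessellates the tissue into polygonal cells. This module turns
that channel into a relational description:

1. smooth + threshold the channel into a binary wall mask;
2. thin the mask to a one-pixel-wide, topology-preserving skeleton and prune
   short spurs (thinning artifacts);
3. find junction points — clusters of skeleton pixels with ≥ 3 neighbours —
   where three (occasionally four) walls converge;
4. cut the skeleton at the junctions into individual wall segments;
5. label cells as the connected areas enclosed by walls (components of the
   skeleton complement, excluding the border-touching region).

Connectivity convention: the skeleton uses 8-connectivity, cell regions use
4-connectivity, so cells cannot leak diagonally through a one-pixel wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import skeletonize

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Skeleton:
    """One-pixel-wide wall skeleton with per-pixel neighbour counts."""

    mask: np.ndarray            # boolean grid of skeleton pixels
    degree: np.ndarray          # number of 8-connected skeleton neighbours

    @property
    def pixels(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class JunctionPoint:
    junction_id: int
    position: tuple              # (row, col) cluster centroid, float
    pixels: list = field(default_factory=list)   # absorbed skeleton pixels
    wall_ids: list = field(default_factory=list)
    flags: list = field(default_factory=list)


@dataclass
class WallSegment:
    wall_id: int
    path: list                   # ordered (row, col) pixel chain
    junction_ids: tuple = ()     # 0 (closed loop), 1 (dead end) or 2 ids
    length_um: float = 0.0
    cell_ids: tuple = ()         # filled by relational_graph
    flags: list = field(default_factory=list)

    @property
    def closed_loop(self) -> bool:
        return len(self.junction_ids) == 0


@dataclass
class Cell:
    cell_id: int
    area_um2: float
    centroid: tuple              # (row, col)
    n_pixels: int
    wall_ids: list = field(default_factory=list)


def preprocess_walls(channel: np.ndarray, smoothing_sigma: float = 1.0,
                     threshold_method: str = "otsu",
                     threshold_value: Optional[float] = None,
                     invert: bool = False) -> np.ndarray:
    """Smooth and threshold the wall channel into a boolean wall mask."""
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    channel = np.asarray(channel, dtype=float)
    if invert:
        channel = channel.max() - channel
    if channel.max() == channel.min():
        raise ValueError("no wall signal: image has zero dynamic range")
    smoothed = gaussian(channel, sigma=smoothing_sigma, preserve_range=True) \
        if smoothing_sigma > 0 else channel
    if threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold method requires a threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    return smoothed > thr


def _degree_map(mask: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    counts = ndi.convolve(mask.astype(int), kernel, mode="constant")
    return np.where(mask, counts, 0)


def skeletonize_walls(mask: np.ndarray, prune_length_px: int = 5) -> Skeleton:
    """Thin the wall mask to one pixel width and prune short spurs.

    Spurs — dead-end chains strictly shorter than ``prune_length_px`` hanging
    off a branch point — are thinning artifacts and are removed iteratively.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty wall mask")
    skel = skeletonize(mask)
    for _ in range(3):
        before = skel.sum()
        skel = _remove_redundant_pixels(skel)
        skel = _prune_spurs(skel, prune_length_px)
        if skel.sum() == before:
            break
    return Skeleton(mask=skel, degree=_degree_map(skel))


def _remove_redundant_pixels(skel: np.ndarray) -> np.ndarray:
    """Strictify the skeleton: drop staircase/triangle corner pixels.

    Parallel thinning can leave a pixel whose skeleton neighbours are all
    mutually 8-connected without it (e.g. a 3-pixel triangle at a sharp
    corner). Such a pixel carries no connectivity and would masquerade as a
    branch point, so it is removed; the pass is sequential in row-major
    order, hence deterministic.
    """
    skel = skel.copy()
    rows, cols = skel.shape
    # candidate pre-filter: a redundant pixel always sits in a 2×2 block
    # with >= 3 skeleton pixels, so straight runs are skipped wholesale
    blocks = (skel[:-1, :-1].astype(int) + skel[:-1, 1:]
              + skel[1:, :-1] + skel[1:, 1:])
    dense = np.zeros_like(skel)
    hit = blocks >= 3
    dense[:-1, :-1] |= hit
    dense[:-1, 1:] |= hit
    dense[1:, :-1] |= hit
    dense[1:, 1:] |= hit
    for r, c in map(tuple, np.argwhere(skel & dense)):
        if not skel[r, c]:
            continue
        nbrs = [(r + dr, c + dc) for dr, dc in _NEIGHBOURS
                if 0 <= r + dr < rows and 0 <= c + dc < cols
                and skel[r + dr, c + dc]]
        if len(nbrs) < 2:
            continue
        if _neighbour_components(nbrs) != 1:
            continue  # removal would disconnect the skeleton
        # removal must not open a hole: the local background must form one
        # 4-connected component that touches an edge-neighbour of the pixel
        bg = [(r + dr, c + dc) for dr, dc in _NEIGHBOURS
              if not (0 <= r + dr < rows and 0 <= c + dc < cols
                      and skel[r + dr, c + dc])]
        bg_comps = _ring_components_4(bg)
        edge_nbrs = {(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)}
        touching = [comp for comp in bg_comps if comp & edge_nbrs]
        if len(touching) == 1:
            skel[r, c] = False
    return skel


def _neighbour_components(nbrs: list) -> int:
    """Number of 8-connected components among a pixel's neighbours."""
    rest = set(nbrs)
    n = 0
    while rest:
        n += 1
        frontier = [rest.pop()]
        while frontier:
            p = frontier.pop()
            for q in list(rest):
                if max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1:
                    rest.discard(q)
                    frontier.append(q)
    return n


def _ring_components_4(cells: list) -> list:
    """4-connected components of background cells in a 3×3 ring."""
    rest = set(cells)
    comps = []
    while rest:
        comp = set()
        frontier = [rest.pop()]
        while frontier:
            p = frontier.pop()
            comp.add(p)
            for q in list(rest):
                if abs(p[0] - q[0]) + abs(p[1] - q[1]) == 1:
                    rest.discard(q)
                    frontier.append(q)
        comps.append(comp)
    return comps


def _prune_spurs(skel: np.ndarray, prune_length_px: int) -> np.ndarray:
    if prune_length_px <= 0:
        return skel
    skel = skel.copy()
    for _ in range(8):  # converges in one or two passes in practice
        deg = _degree_map(skel)
        endpoints = np.argwhere((deg == 1))
        removed_any = False
        for r, c in endpoints:
            if not skel[r, c]:
                continue
            chain = [(r, c)]
            prev = None
            cur = (r, c)
            while len(chain) < prune_length_px:
                nbrs = [(cur[0] + dr, cur[1] + dc) for dr, dc in _NEIGHBOURS
                        if 0 <= cur[0] + dr < skel.shape[0]
                        and 0 <= cur[1] + dc < skel.shape[1]
                        and skel[cur[0] + dr, cur[1] + dc]
                        and (cur[0] + dr, cur[1] + dc) != prev]
                if len(nbrs) != 1:
                    break  # reached a branch point or isolated pixel
                prev = cur
                cur = nbrs[0]
                if deg[cur] >= 3:
                    break
                chain.append(cur)
            else:
                continue  # chain reached prune length: genuine wall, keep
            # chain ended at a branch point (or died out) within the prune
            # length: drop it unless it is the whole component
            end_nbrs = [
                (chain[-1][0] + dr, chain[-1][1] + dc) for dr, dc in _NEIGHBOURS
                if 0 <= chain[-1][0] + dr < skel.shape[0]
                and 0 <= chain[-1][1] + dc < skel.shape[1]
                and skel[chain[-1][0] + dr, chain[-1][1] + dc]
                and (chain[-1][0] + dr, chain[-1][1] + dc) not in chain
            ]
            if end_nbrs:
                for px in chain:
                    skel[px] = False
                removed_any = True
        if not removed_any:
            break
    return skel


def find_junctions(skel: Skeleton, merge_gap_px: int = 3) -> list:
    """Cluster branch pixels (degree ≥ 3) into junction points.

    Branch pixels are grouped by 8-connectivity; topology-preserving thinning
    of one biological junction can additionally leave two branch pixels
    separated by a short degree-2 chain, so clusters joined by skeleton
    chains of at most ``merge_gap_px`` pixels are merged, with the connecting
    pixels absorbed into the junction. Degree-4 crossings are admitted as
    single junctions.
    """
    branch = skel.degree >= 3
    if not branch.any():
        return []
    labels, n = ndi.label(branch, structure=np.ones((3, 3), dtype=int))
    members = {i: [tuple(p) for p in np.argwhere(labels == i)]
               for i in range(1, n + 1)}

    if merge_gap_px > 0 and n > 1:
        _merge_close_clusters(skel, labels, members, merge_gap_px)

    junctions = []
    for jid, (key, pixels) in enumerate(sorted(members.items())):
        arr = np.array(pixels, dtype=float)
        junctions.append(JunctionPoint(
            junction_id=jid,
            position=(float(arr[:, 0].mean()), float(arr[:, 1].mean())),
            pixels=sorted(pixels),
        ))
    return junctions


def _merge_close_clusters(skel: Skeleton, labels: np.ndarray,
                          members: dict, merge_gap_px: int) -> None:
    """Merge branch clusters connected by ≤ merge_gap_px non-branch pixels."""
    chain_mask = skel.mask & (labels == 0)
    chain_labels, n_chains = ndi.label(chain_mask, structure=np.ones((3, 3), int))
    # union-find over cluster keys
    parent = {k: k for k in members}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for ci in range(1, n_chains + 1):
        pix = np.argwhere(chain_labels == ci)
        if len(pix) > merge_gap_px:
            continue
        touched = set()
        for r, c in pix:
            for dr, dc in _NEIGHBOURS:
                rr, cc = r + dr, c + dc
                if (0 <= rr < labels.shape[0] and 0 <= cc < labels.shape[1]
                        and labels[rr, cc] > 0):
                    touched.add(labels[rr, cc])
        if len(touched) >= 2:
            ks = sorted(touched)
            root = find(ks[0])
            for k in ks[1:]:
                parent[find(k)] = root
            members.setdefault(root, [])
            members[root] = members[root] + [tuple(p) for p in pix]

    merged: dict = {}
    for k in list(members):
        root = find(k)
        merged.setdefault(root, [])
        merged[root].extend(members[k] if k == root else members[k])
    # rebuild without duplicates
    members.clear()
    for k, v in merged.items():
        members[k] = sorted(set(v))


def split_walls(skel: Skeleton, junctions: list) -> list:
    """Cut the skeleton at junction clusters into individual wall segments.

    Removing the junction pixels disconnects the skeleton; each remaining
    8-connected chain becomes one :class:`WallSegment`, re-attached to the
    junction ids its endpoints touch. A junction-free loop becomes a single
    closed-loop segment.
    """
    junction_pixel_owner = {}
    for j in junctions:
        for px in j.pixels:
            junction_pixel_owner[px] = j.junction_id

    remaining = skel.mask.copy()
    for px in junction_pixel_owner:
        remaining[px] = False

    chain_labels, n_chains = ndi.label(remaining, structure=np.ones((3, 3), int))
    walls = []
    for ci in range(1, n_chains + 1):
        pixels = [tuple(p) for p in np.argwhere(chain_labels == ci)]
        path = _order_chain(pixels)
        if len(path) == 1:
            owners = set()
            for dr, dc in _NEIGHBOURS:
                px = (path[0][0] + dr, path[0][1] + dc)
                if px in junction_pixel_owner:
                    owners.add(junction_pixel_owner[px])
            jids = sorted(owners)[:2]
        else:
            jids = []
            for end in (path[0], path[-1]):
                owners = set()
                for dr, dc in _NEIGHBOURS:
                    px = (end[0] + dr, end[1] + dc)
                    if px in junction_pixel_owner:
                        owners.add(junction_pixel_owner[px])
                jids.extend(sorted(owners)[:1])  # nearest cluster per endpoint
        wall = WallSegment(wall_id=len(walls), path=path,
                           junction_ids=tuple(jids))
        if len(path) == 1:
            wall.flags.append("single_pixel")
        walls.append(wall)
    # attach wall ids back onto junctions
    jmap = {j.junction_id: j for j in junctions}
    for j in junctions:
        j.wall_ids = []
    for w in walls:
        for jid in w.junction_ids:
            if w.wall_id not in jmap[jid].wall_ids:
                jmap[jid].wall_ids.append(w.wall_id)
    return walls


def _order_chain(pixels: list) -> list:
    """Order an 8-connected one-pixel-wide chain from one end to the other."""
    if len(pixels) <= 2:
        return sorted(pixels)
    pixset = set(pixels)
    nbrs = {p: [q for dr, dc in _NEIGHBOURS
                if (q := (p[0] + dr, p[1] + dc)) in pixset] for p in pixels}
    ends = sorted(p for p, ns in nbrs.items() if len(ns) == 1)
    start = ends[0] if ends else min(pixels)  # closed loop: deterministic start
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [q for q in nbrs[cur] if q not in visited]
        if not nxt:
            break
        # prefer 4-connected continuation to avoid skipping corner pixels
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        path.append(cur)
        visited.add(cur)
    if len(path) != len(pixels):
        # fall back: chain had a small thickness artifact; append leftovers
        for p in sorted(pixset - visited):
            path.append(p)
    return path


def measure_length(segment: WallSegment, pixel_size: float) -> float:
    """Chain length in µm: 1·px per orthogonal, √2·px per diagonal step."""
    path = segment.path
    if len(path) == 1:
        if "single_pixel" not in segment.flags:
            segment.flags.append("single_pixel")
        return 0.0
    steps = np.diff(np.asarray(path, dtype=float), axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    length = float(lengths.sum() * pixel_size)
    if segment.closed_loop and len(path) > 2:
        # close the ring
        d = np.hypot(path[0][0] - path[-1][0], path[0][1] - path[-1][1])
        if d <= np.sqrt(2) + 1e-9:
            length += float(d * pixel_size)
    return length


def label_cells(skel: Skeleton, shape: tuple, pixel_size: float) -> tuple:
    """Label enclosed cells in the skeleton complement.

    4-connected components of the complement, excluding every component that
    touches the image border (background and clipped cells are not
    measurable). Returns ``(cells, label_image)`` where ``label_image`` maps
    each pixel to a cell id + 1 (0 = wall or excluded region).
    """
    complement = ~skel.mask
    labels, n = ndi.label(complement, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int))
    border_labels = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])))
    border_labels.discard(0)

    cells = []
    cell_label_img = np.zeros(shape, dtype=int)
    for lab in range(1, n + 1):
        if lab in border_labels:
            continue
        region = labels == lab
        n_px = int(region.sum())
        rows, cols = np.nonzero(region)
        cid = len(cells)
        cells.append(Cell(
            cell_id=cid,
            area_um2=n_px * pixel_size ** 2,
            centroid=(float(rows.mean()), float(cols.mean())),
            n_pixels=n_px,
        ))
        cell_label_img[region] = cid + 1
    return cells, cell_label_img
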