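"""Assembly of the relational cell–wall–junction–punctum model.

Each punctum is associated with a wall (or orphaned beyond the parent-search
tolerance), each wall segment with its two adjacent cells (or the BORDER
sentinel), and each junction point with its connected walls. The assembled
:class:`WallGraph` is validated for global consistency before any
quantification runs on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .image_io import BORDER, ORPHAN

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


class IntegrityError(ValueError):
    """A relational invariant is violated; names the offending ids."""


@dataclass
class WallGraph:
    """The full relational model for one image."""

    cells: list
    walls: list
    junctions: list
    puncta: list
    pixel_size: float
    cell_label_img: np.ndarray = None
    orphans: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def assigned_puncta(self) -> list:
        return [p for p in self.puncta if p.wall_id != ORPHAN]


def assign_walls_to_cells(walls: list, cells: list,
                          cell_label_img: np.ndarray) -> dict:
    """Map each wall to its (≤ 2) adjacent cells.

    For every wall pixel the distinct cell labels among its 8-neighbours are
    accumulated as votes; the two labels with most votes are the adjacent
    cells. A wall with a single adjacent interior cell faces the image-border
    region and gets the ``BORDER`` sentinel as its second side. A third label
    with substantial support (votes on more than 25% of the wall's pixels)
    indicates a segmentation failure and raises :class:`IntegrityError`.
    """
    shape = cell_label_img.shape
    mapping = {}
    for wall in walls:
        votes: dict = {}
        for r, c in wall.path:
            seen = set()
            for dr, dc in _NEIGHBOURS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                    lab = cell_label_img[rr, cc]
                    if lab > 0:
                        seen.add(lab - 1)
            for cid in seen:
                votes[cid] = votes.get(cid, 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        n_px = max(len(wall.path), 1)
        strong = [cid for cid, v in ranked if v > 0.25 * n_px]
        if len(strong) >= 3:
            raise IntegrityError(
                f"wall {wall.wall_id} adjacent to >= 3 cells: {strong[:4]}")
        adj = [cid for cid, _ in ranked[:2]]
        if len(adj) == 2:
            mapping[wall.wall_id] = (min(adj), max(adj))
        elif len(adj) == 1:
            mapping[wall.wall_id] = (adj[0], BORDER)
        else:
            mapping[wall.wall_id] = (BORDER, BORDER)
        wall.cell_ids = mapping[wall.wall_id]
    # inverse map onto cells
    for cell in cells:
        cell.wall_ids = []
    by_id = {c.cell_id: c for c in cells}
    for wall in walls:
        for cid in wall.cell_ids:
            if cid != BORDER and wall.wall_id not in by_id[cid].wall_ids:
                by_id[cid].wall_ids.append(wall.wall_id)
    return mapping


def assign_puncta_to_walls(puncta: list, walls: list, pixel_size: float,
                           tolerance_um: float = 0.5) -> tuple:
    """Assign each punctum to the wall with the nearest path pixel.

    Distance is Euclidean, punctum (sub-pixel) position to wall pixel center,
    converted to µm. Puncta farther than ``tolerance_um`` from every wall are
    orphans. Equidistant candidates resolve to the lower wall id.

    Returns ``(assigned, orphans)``; with no walls at all, every punctum is
    orphaned (a warning condition, not an error).
    """
    if tolerance_um <= 0:
        raise ValueError("tolerance must be > 0")
    orphans = []
    if not walls:
        for p in puncta:
            p.wall_id = ORPHAN
            p.distance_to_wall_um = np.inf
            orphans.append(p)
        return [], orphans

    pts = []
    owner = []
    for w in walls:
        for px in w.path:
            pts.append(px)
            owner.append(w.wall_id)
    pts = np.asarray(pts, dtype=float)
    owner = np.asarray(owner)
    tree = cKDTree(pts)

    assigned = []
    for p in puncta:
        pos = np.asarray(p.position, dtype=float)
        d, idx = tree.query(pos)
        # deterministic tie-break: all pixels at the minimal distance,
        # lowest wall id wins
        ties = tree.query_ball_point(pos, d + 1e-9)
        wid = int(owner[ties].min()) if ties else int(owner[idx])
        d_um = float(d * pixel_size)
        if d_um > tolerance_um:
            p.wall_id = ORPHAN
            p.distance_to_wall_um = d_um
            orphans.append(p)
        else:
            p.wall_id = wid
            p.distance_to_wall_um = d_um
            assigned.append(p)
    return assigned, orphans


def assign_junction_walls(junctions: list, walls: list) -> dict:
    """Junction → connected wall ids, the inverse of the wall endpoint map.

    An interior junction should connect ≥ 3 walls (tri-junction or a
    degree-4 crossing); one left with fewer after pruning is retained but
    flagged with an integrity warning.
    """
    mapping = {j.junction_id: [] for j in junctions}
    for w in walls:
        for jid in w.junction_ids:
            if w.wall_id not in mapping[jid]:
                mapping[jid].append(w.wall_id)
    warnings = []
    for j in junctions:
        j.wall_ids = sorted(mapping[j.junction_id])
        if len(j.wall_ids) < 3:
            j.flags.append("degree_deficient")
            warnings.append(
                f"junction {j.junction_id} connects only "
                f"{len(j.wall_ids)} wall(s)")
    return mapping, warnings


def build_graph(cells: list, walls: list, junctions: list, puncta: list,
                pixel_size: float, cell_label_img: np.ndarray,
                parent_search_tolerance_um: float = 0.5) -> WallGraph:
    """Run all three assignments and validate every graph invariant."""
    assign_walls_to_cells(walls, cells, cell_label_img)
    assigned, orphans = assign_puncta_to_walls(
        puncta, walls, pixel_size, parent_search_tolerance_um)
    _, warnings = assign_junction_walls(junctions, walls)

    graph = WallGraph(cells=cells, walls=walls, junctions=junctions,
                      puncta=puncta, pixel_size=pixel_size,
                      cell_label_img=cell_label_img, orphans=orphans,
                      warnings=warnings)
    validate_graph(graph)
    return graph


def validate_graph(graph: WallGraph) -> None:
    """Check mutual consistency of all association maps."""
    wall_ids = {w.wall_id for w in graph.walls}
    cell_by_id = {c.cell_id: c for c in graph.cells}
    junction_by_id = {j.junction_id: j for j in graph.junctions}

    n_orphans = len(graph.orphans)
    n_assigned = sum(1 for p in graph.puncta if p.wall_id != ORPHAN)
    if n_assigned + n_orphans != len(graph.puncta):
        raise IntegrityError(
            f"punctum conservation violated: {n_assigned} assigned + "
            f"{n_orphans} orphans != {len(graph.puncta)} detected")

    for w in graph.walls:
        interior = [cid for cid in w.cell_ids if cid != BORDER]
        if len(interior) == 2 and interior[0] == interior[1]:
            raise IntegrityError(
                f"wall {w.wall_id} lists cell {interior[0]} twice")
        for cid in interior:
            if cid not in cell_by_id:
                raise IntegrityError(f"wall {w.wall_id}: unknown cell {cid}")
            if w.wall_id not in cell_by_id[cid].wall_ids:
                raise IntegrityError(
                    f"wall {w.wall_id} not listed by its cell {cid}")
        for jid in w.junction_ids:
            if jid not in junction_by_id:
                raise IntegrityError(f"wall {w.wall_id}: unknown junction {jid}")
            if w.wall_id not in junction_by_id[jid].wall_ids:
                raise IntegrityError(
                    f"wall {w.wall_id} not listed by its junction {jid}")
    for c in graph.cells:
        for wid in c.wall_ids:
            if wid not in wall_ids:
                raise IntegrityError(f"cell {c.cell_id}: unknown wall {wid}")
    for p in graph.puncta:
        if p.wall_id != ORPHAN and p.wall_id not in wall_ids:
            raise IntegrityError(
                f"punctum {p.punctum_id}: unknown wall {p.wall_id}")
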