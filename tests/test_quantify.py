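"""Quantification: per-wall / per-cell tables, gold density, interfaces."""

import numpy as np
import pandas as pd
import pytest

from pdquant.image_io import BORDER
from pdquant.puncta_detect import Punctum
from pdquant.quantify import (gold_density, interface_table,
                              per_cell_table, per_wall_table)
from pdquant.relational_graph import IntegrityError, WallGraph
from pdquant.wall_network import Cell, WallSegment


def _stub_graph(walls, puncta, cells=()):
    return WallGraph(cells=list(cells), walls=walls, junctions=[],
                     puncta=puncta, pixel_size=0.25,
                     cell_label_img=np.zeros((8, 8), int))


class TestPerWall:
    def test_density_is_count_over_length(self):
        wall = WallSegment(0, path=[(2, c) for c in range(5)],
                           junction_ids=(), cell_ids=(0, BORDER))
        wall.length_um = 2.0
        puncta = [Punctum(i, (2.0, float(i)), wall_id=0,
                          integrated_intensity=10.0) for i in range(4)]
        rows = per_wall_table(_stub_graph([wall], puncta), np.zeros((8, 8)))
        assert rows.loc[0, "pd_per_um"] == pytest.approx(2.0)
        assert rows.loc[0, "n_pd"] == 4
        assert rows.loc[0, "pd_total_intensity"] == pytest.approx(40.0)

    def test_wall_without_puncta_is_zero(self):
        wall = WallSegment(0, path=[(2, 2), (2, 3)], cell_ids=(0, BORDER))
        wall.length_um = 0.5
        rows = per_wall_table(_stub_graph([wall], []), np.zeros((8, 8)))
        assert rows.loc[0, "n_pd"] == 0
        assert rows.loc[0, "pd_per_um"] == 0.0
        assert rows.loc[0, "pd_total_intensity"] == 0.0

    def test_zero_length_wall_flagged_not_divided(self):
        wall = WallSegment(0, path=[(2, 2)], cell_ids=(0, BORDER))
        wall.length_um = 0.0
        rows = per_wall_table(_stub_graph([wall], []), np.zeros((8, 8)))
        assert rows.loc[0, "pd_per_um"] == 0.0
        assert "zero_length" in rows.loc[0, "flags"]

    def test_density_times_length_recovers_count(self, analyzed_6x6):
        _, _, _, _, tables = analyzed_6x6
        walls = tables["walls"]
        ok = walls["length_um"] > 0
        np.testing.assert_allclose(
            walls.loc[ok, "pd_per_um"] * walls.loc[ok, "length_um"],
            walls.loc[ok, "n_pd"], atol=1e-9)


class TestPerCell:
    def _graph_with_means(self, means):
        walls = []
        for i, _ in enumerate(means):
            w = WallSegment(i, path=[(0, 0)], cell_ids=(0, BORDER))
            w.length_um = 1.0
            walls.append(w)
        cell = Cell(cell_id=0, area_um2=4.0, centroid=(1.0, 1.0), n_pixels=64)
        cell.wall_ids = [w.wall_id for w in walls]
        graph = _stub_graph(walls, [], cells=[cell])
        rows = per_wall_table(graph, np.zeros((8, 8)))
        rows["mean_callose_intensity"] = means
        return graph, rows

    def test_periphery_sum_is_sum_of_wall_means(self):
        graph, wall_rows = self._graph_with_means([10.0, 20.0, 30.0])
        cells = per_cell_table(graph, wall_rows)
        assert cells.loc[0, "periphery_callose_sum"] == pytest.approx(60.0)
        assert cells.loc[0, "n_walls"] == 3

    def test_uniform_intensity_scales_with_wall_count(self):
        graph, wall_rows = self._graph_with_means([7.5] * 5)
        cells = per_cell_table(graph, wall_rows)
        assert cells.loc[0, "periphery_callose_sum"] == pytest.approx(5 * 7.5)

    def test_shared_wall_counts_fully_for_both_cells(self, analyzed_6x6):
        _, _, graph, _, tables = analyzed_6x6
        walls, cells = tables["walls"], tables["cells"]
        shared = walls[(walls["cell_id_1"] != BORDER)
                       & (walls["cell_id_2"] != BORDER)].iloc[0]
        for cid in (shared["cell_id_1"], shared["cell_id_2"]):
            cell_wall_ids = next(c.wall_ids for c in graph.cells
                                 if c.cell_id == cid)
            assert shared["wall_id"] in cell_wall_ids

    def test_cell_pd_double_counts_interior_walls(self, analyzed_6x6):
        _, _, graph, _, tables = analyzed_6x6
        walls, cells = tables["walls"], tables["cells"]
        interior = (walls["cell_id_1"] != BORDER) & (walls["cell_id_2"] != BORDER)
        expected = 2 * walls.loc[interior, "n_pd"].sum() \
            + walls.loc[~interior, "n_pd"].sum()
        assert cells["n_pd"].sum() == expected

    def test_periphery_sum_equals_recomputed_sum(self, analyzed_6x6):
        _, _, graph, _, tables = analyzed_6x6
        wall_means = tables["walls"].set_index("wall_id")[
            "mean_callose_intensity"]
        for _, row in tables["cells"].iterrows():
            cell = next(c for c in graph.cells
                        if c.cell_id == row["cell_id"])
            assert row["periphery_callose_sum"] == pytest.approx(
                float(wall_means.loc[cell.wall_ids].sum()), abs=1e-12)

    def test_cell_without_walls_is_integrity_error(self):
        cell = Cell(cell_id=0, area_um2=1.0, centroid=(1, 1), n_pixels=16)
        graph = _stub_graph([], [], cells=[cell])
        with pytest.raises(IntegrityError):
            per_cell_table(graph, per_wall_table(graph, np.zeros((8, 8))))


class TestGoldDensity:
    def test_paper_standard_window(self):
        gd = gold_density(5)
        assert gd.window_area_um2 == 0.025
        assert gd.density_per_um2 == pytest.approx(200.0)

    def test_zero_particles(self):
        assert gold_density(0).density_per_um2 == 0.0

    def test_scale_invariance(self):
        a = gold_density(4, 0.025)
        b = gold_density(8, 0.05)
        assert a.density_per_um2 == pytest.approx(b.density_per_um2)

    @pytest.mark.parametrize("count,area", [(-1, 0.025), (3, 0.0), (3, -1.0)])
    def test_invalid_inputs(self, count, area):
        with pytest.raises(ValueError):
            gold_density(count, area)


class TestInterfaceTable:
    def test_per_cell_aggregate_sums_touching_interfaces(self):
        interfaces, per_cell = interface_table(
            [("A", "B", 3), ("B", "C", 2)])
        agg = per_cell.set_index("cell_id")["pd_total"]
        assert agg["B"] == 5 and agg["A"] == 3 and agg["C"] == 2

    def test_unordered_duplicate_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            interface_table([("A", "B", 3), ("B", "A", 1)])

    def test_star_aggregate_is_interface_count(self):
        k = 6
        counts = [("hub", f"n{i}", 1) for i in range(k)]
        _, per_cell = interface_table(counts)
        assert per_cell.set_index("cell_id")["pd_total"]["hub"] == k

    def test_unknown_cell_rejected_when_cells_given(self):
        with pytest.raises(ValueError, match="unknown cell"):
            interface_table([("A", "Z", 1)], cells={"A", "B"})

    def test_dataframe_input_accepted(self):
        df = pd.DataFrame({"cell_id_1": ["A"], "cell_id_2": ["B"],
                           "pd_count": [4]})
        interfaces, _ = interface_table(df)
        assert interfaces.loc[0, "pd_count"] == 4
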