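"""Wall segmentation: mask, skeleton, junctions, wall cutting, cell labels."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from pdquant.wall_network import (WallSegment, find_junctions, label_cells,
                                  measure_length, preprocess_walls,
                                  skeletonize_walls, split_walls)


def _skel_from(mask):
    return skeletonize_walls(mask, prune_length_px=3)


class TestPreprocess:
    def test_constant_image_is_an_error(self):
        with pytest.raises(ValueError, match="no wall signal"):
            preprocess_walls(np.zeros((32, 32)))

    def test_polarity_flag_recovers_inverted_contrast(self):
        img = np.full((40, 40), 100.0)
        img[18:22, :] = 200.0
        normal = preprocess_walls(img, smoothing_sigma=0)
        flipped = preprocess_walls(img.max() - img, smoothing_sigma=0,
                                   invert=True)
        assert np.array_equal(normal, flipped)

    def test_mask_covers_wall_centerline(self, lattice_2x2):
        gt, img = lattice_2x2
        mask = preprocess_walls(img.wall_channel)
        px = gt.pixel_size
        for w in gt.walls:
            for x, y in w["polyline"]:
                assert mask[int(round(y / px)), int(round(x / px))]

    def test_fixed_threshold_requires_value(self):
        img = np.zeros((16, 16))
        img[8] = 10.0
        with pytest.raises(ValueError, match="threshold_value"):
            preprocess_walls(img, threshold_method="fixed")


class TestSkeletonize:
    def test_thick_bar_thins_to_simple_chain(self):
        mask = np.zeros((21, 40), dtype=bool)
        mask[8:13, 2:38] = True  # 5 px thick straight bar
        skel = _skel_from(mask)
        assert skel.degree.max() <= 2
        labels, n = ndi.label(skel.mask, structure=np.ones((3, 3), int))
        assert n == 1

    def test_thick_ring_preserves_loop_topology(self):
        rr, cc = np.mgrid[0:60, 0:60]
        radius = np.hypot(rr - 30, cc - 30)
        mask = (radius > 15) & (radius < 22)
        skel = _skel_from(mask)
        assert np.all(skel.degree[skel.mask] == 2)
        # complement: inside + outside
        comp, n = ndi.label(~skel.mask)
        assert n == 2

    def test_lattice_complement_has_cells_plus_background(self, lattice_2x2):
        _, img = lattice_2x2
        skel = skeletonize_walls(preprocess_walls(img.wall_channel))
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        _, n = ndi.label(~skel.mask, structure=structure)
        assert n == 5  # 4 cells + outer background

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            skeletonize_walls(np.zeros((8, 8), dtype=bool))

    def test_spurs_shorter_than_prune_length_removed(self):
        mask = np.zeros((21, 41), dtype=bool)
        mask[10, 2:39] = True
        mask[8:10, 20] = True  # 2 px spur
        skel = skeletonize_walls(mask, prune_length_px=3)
        assert skel.degree.max() <= 2


def _plus_skeleton():
    mask = np.zeros((21, 21), dtype=bool)
    mask[10, 2:19] = True
    mask[2:19, 10] = True
    return skeletonize_walls(mask, prune_length_px=0)


class TestJunctions:
    def test_plus_sign_has_one_junction(self):
        junctions = find_junctions(_plus_skeleton())
        assert len(junctions) == 1
        r, c = junctions[0].position
        assert abs(r - 10) <= 1 and abs(c - 10) <= 1

    def test_closed_loop_has_no_junctions(self):
        rr, cc = np.mgrid[0:40, 0:40]
        ring = (np.hypot(rr - 20, cc - 20) > 10) & \
               (np.hypot(rr - 20, cc - 20) < 14)
        skel = _skel_from(ring)
        assert find_junctions(skel) == []

    def test_lattice_junction_count(self, lattice_2x2):
        _, img = lattice_2x2
        skel = skeletonize_walls(preprocess_walls(img.wall_channel))
        assert len(find_junctions(skel)) == 5


class TestSplitWalls:
    def test_plus_decomposes_into_four_arms(self):
        skel = _plus_skeleton()
        junctions = find_junctions(skel)
        walls = split_walls(skel, junctions)
        assert len(walls) == 4
        assert all(len(w.junction_ids) == 1 for w in walls)
        assert sorted(junctions[0].wall_ids) == [w.wall_id for w in walls]

    def test_lattice_has_eight_segments(self, lattice_2x2):
        _, img = lattice_2x2
        skel = skeletonize_walls(preprocess_walls(img.wall_channel))
        walls = split_walls(skel, find_junctions(skel))
        assert len(walls) == 8

    def test_loop_becomes_single_closed_segment(self):
        rr, cc = np.mgrid[0:40, 0:40]
        ring = (np.hypot(rr - 20, cc - 20) > 10) & \
               (np.hypot(rr - 20, cc - 20) < 14)
        skel = _skel_from(ring)
        walls = split_walls(skel, find_junctions(skel))
        assert len(walls) == 1
        assert walls[0].closed_loop


class TestLabelCells:
    def test_ring_encloses_one_cell(self):
        rr, cc = np.mgrid[0:40, 0:40]
        ring = (np.hypot(rr - 20, cc - 20) > 10) & \
               (np.hypot(rr - 20, cc - 20) < 14)
        skel = _skel_from(ring)
        cells, _ = label_cells(skel, (40, 40), pixel_size=0.1)
        assert len(cells) == 1

    def test_lattice_has_four_cells(self, lattice_2x2):
        gt, img = lattice_2x2
        skel = skeletonize_walls(preprocess_walls(img.wall_channel))
        cells, label_img = label_cells(skel, img.shape, img.pixel_size)
        assert len(cells) == 4
        # areas close to the ground-truth polygon areas
        for cell, gt_cell in zip(
                sorted(cells, key=lambda c: c.centroid),
                sorted(gt.cells, key=lambda c: (c["polygon"][0]))):
            assert cell.area_um2 == pytest.approx(64.0, rel=0.15)

    def test_open_shape_encloses_nothing(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5] = True
        mask[24, 5:25] = True
        mask[5:25, 24] = True  # "U"
        skel = _skel_from(mask)
        cells, _ = label_cells(skel, (30, 30), pixel_size=0.1)
        assert cells == []


class TestMeasureLength:
    @pytest.mark.parametrize("path,expected", [
        ([(5, c) for c in range(2, 13)], 1.0),                   # 11 px row
        ([(i, i) for i in range(11)], 10 * np.sqrt(2) * 0.1),    # 45° chain
        ([(0, c) for c in range(5)] + [(r, 4) for r in range(1, 5)], 0.8),
    ])
    def test_step_sum(self, path, expected):
        seg = WallSegment(wall_id=0, path=path)
        assert measure_length(seg, pixel_size=0.1) == pytest.approx(expected)

    def test_single_pixel_path_is_zero_with_flag(self):
        seg = WallSegment(wall_id=0, path=[(3, 3)])
        assert measure_length(seg, pixel_size=0.1) == 0.0
        assert "single_pixel" in seg.flags
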