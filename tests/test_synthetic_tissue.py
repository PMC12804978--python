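"""Ground-truth generator: geometry, puncta placement, rendering."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from pdquant.pipeline import analyze_image
from pdquant.synthetic_tissue import (make_tessellation, place_puncta,
                                      render)

from conftest import match_points


class TestTessellation:
    def test_square_lattice_counts(self, lattice_2x2):
        gt, _ = lattice_2x2
        assert (gt.n_cells, gt.n_walls, gt.n_junctions) == (4, 8, 5)

    def test_single_cell_is_one_closed_loop(self):
        gt = make_tessellation(1, 1, jitter=0.0, seed=0)
        assert (gt.n_cells, gt.n_walls, gt.n_junctions) == (1, 1, 0)
        assert gt.walls[0]["junction_ids"] == ()

    @pytest.mark.parametrize("nx,ny,jitter,seed",
                             [(2, 2, 0.0, 1), (3, 4, 0.2, 7), (5, 5, 0.4, 3)])
    def test_euler_relation(self, nx, ny, jitter, seed):
        gt = make_tessellation(nx, ny, jitter=jitter, seed=seed)
        loops = sum(1 for w in gt.walls if w["junction_ids"] == ())
        v = gt.n_junctions + loops  # one virtual node per closed loop
        assert v - gt.n_walls + (gt.n_cells + 1) == 2

    def test_same_seed_bitwise_identical(self):
        a = make_tessellation(4, 4, jitter=0.3, seed=9)
        b = make_tessellation(4, 4, jitter=0.3, seed=9)
        assert a.cells == b.cells and a.walls == b.walls \
            and a.junctions == b.junctions

    def test_unresolvable_parameters_raise(self):
        with pytest.raises(ValueError, match="unresolvable tessellation"):
            make_tessellation(4, 4, jitter=0.0, seed=1, cell_pitch=1.5)

    def test_wall_cell_adjacency_cross_links(self):
        gt = make_tessellation(3, 3, jitter=0.2, seed=2)
        for w in gt.walls:
            for cid in w["cell_ids"]:
                if cid != "BORDER":
                    assert w["wall_id"] in gt.cells[cid]["wall_ids"]
        for j in gt.junctions:
            assert len(j["wall_ids"]) >= 3


class TestPlacePuncta:
    def test_zero_rate_places_nothing(self):
        gt = place_puncta(make_tessellation(3, 3, seed=1), rate=0.0, seed=1)
        assert gt.puncta == []

    def test_rate_recovered_within_poisson_error(self):
        # 2×2 at 8 µm pitch gives ≈ 96 µm of wall: expected count ≈ 48,
        # checked per seed against the 3·√N Poisson band
        for seed in range(6):
            gt = make_tessellation(2, 2, jitter=0.2, seed=seed)
            gt = place_puncta(gt, rate=0.5, seed=seed)
            expected = 0.5 * gt.total_wall_length_um()
            assert abs(len(gt.puncta) - expected) <= 3 * np.sqrt(expected)

    def test_every_punctum_lies_on_its_parent_wall(self, jittered_6x6):
        gt, _ = jittered_6x6
        lines = {w["wall_id"]: LineString(w["polyline"]) for w in gt.walls}
        for p in gt.puncta:
            assert lines[p["wall_id"]].distance(
                Point(p["x"], p["y"])) < 1e-8

    def test_min_gap_enforced(self, jittered_6x6):
        gt, _ = jittered_6x6
        pts = np.array([[p["x"], p["y"]] for p in gt.puncta])
        from scipy.spatial.distance import pdist
        assert pdist(pts).min() >= 1.0 - 1e-9


class TestRender:
    def test_no_degradation_wall_maximum_on_walls(self):
        gt = make_tessellation(2, 2, jitter=0.0, seed=1,
                               psf_sigma_px=0.0, noise_sd=0.0)
        img = render(gt)
        peak = img.wall_channel.max()
        px = gt.pixel_size
        for x, y in gt.walls[0]["polyline"]:
            assert img.wall_channel[int(round(y / px)),
                                    int(round(x / px))] == peak

    def test_spot_peak_matches_amplitude(self, jittered_6x6):
        gt, img = jittered_6x6
        p = gt.puncta[0]
        r = int(round(p["y"] / gt.pixel_size))
        c = int(round(p["x"] / gt.pixel_size))
        assert img.puncta_channel[r, c] == pytest.approx(
            gt.puncta_amplitude + gt.background, rel=0.15)

    def test_same_seed_identical_render(self):
        gt = place_puncta(make_tessellation(3, 3, seed=4, noise_sd=25.0),
                          rate=0.4, seed=4)
        a, b = render(gt), render(gt)
        assert np.array_equal(a.wall_channel, b.wall_channel)
        assert np.array_equal(a.puncta_channel, b.puncta_channel)


class TestEndToEnd:
    def test_zero_noise_full_recovery(self, analyzed_6x6, config):
        gt, _, graph, _, _ = analyzed_6x6
        assert len(graph.cells) == gt.n_cells
        assert len(graph.walls) == gt.n_walls
        assert len(graph.junctions) == gt.n_junctions
        det = np.array([p.position for p in graph.puncta])
        n_match, _ = match_points(gt.punctum_pixels(), det)
        assert n_match == len(gt.puncta) == len(graph.puncta)

    def test_detection_degrades_gracefully_with_noise(self, config):
        from pdquant.puncta_detect import (auto_threshold,
                                           detect_local_maxima,
                                           preprocess_puncta)
        recalls = []
        for noise in (0.0, 40.0, 150.0):
            gt = make_tessellation(5, 5, jitter=0.2, seed=6, noise_sd=noise)
            gt = place_puncta(gt, rate=0.4, seed=6)
            channel = render(gt).puncta_channel
            prepped = preprocess_puncta(channel,
                                        config.puncta_smoothing_sigma,
                                        config.background_radius_px)
            puncta = detect_local_maxima(
                prepped, auto_threshold(prepped, config.auto_threshold_k),
                config.min_separation_px)
            det = np.array([p.position for p in puncta]) \
                if puncta else np.zeros((0, 2))
            n_match, _ = match_points(gt.punctum_pixels(), det)
            recalls.append(n_match / len(gt.puncta))
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]
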