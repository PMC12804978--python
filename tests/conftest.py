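import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from pdquant.config import PipelineConfig
from pdquant.pipeline import analyze_image
from pdquant.synthetic_tissue import make_tessellation, place_puncta, render


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def lattice_2x2():
    """Exact 2×2 square lattice: 4 cells, 8 walls, 5 junctions."""
    gt = make_tessellation(2, 2, jitter=0.0, seed=1)
    return gt, render(gt)


@pytest.fixture(scope="session")
def jittered_6x6():
    """Jittered 6×6 tessellation with puncta, zero noise."""
    gt = place_puncta(make_tessellation(6, 6, jitter=0.2, seed=5),
                      rate=0.4, seed=5)
    return gt, render(gt)


@pytest.fixture(scope="session")
def analyzed_6x6(jittered_6x6, config):
    gt, img = jittered_6x6
    graph, record, tables = analyze_image(img, config)
    return gt, img, graph, record, tables


def match_points(truth: np.ndarray, detected: np.ndarray, tol: float = 2.0):
    """Optimal one-to-one matching; returns (n_matched, match distances)."""
    if len(truth) == 0 or len(detected) == 0:
        return 0, np.zeros(0)
    dist = cdist(truth, detected)
    ri, ci = linear_sum_assignment(dist)
    hits = dist[ri, ci] <= tol
    return int(hits.sum()), dist[ri, ci][hits]
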