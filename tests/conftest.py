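import numpy as np
import pytest

from larvatrack import contour as ct
from larvatrack import landmarks as lmk
from larvatrack import simulate as sim


@pytest.fixture(scope="session")
def small_scene():
    """One larva crawling for 5 s on a 30 mm plate, with ground truth."""
    cfg = sim.SceneConfig(plate_size_mm=(30.0, 30.0), n_larvae=1, seed=5)
    frames, gt = sim.generate_scene(cfg, script="crawl", duration_s=5.0)
    return cfg, frames, gt


def pose_contour(bend_deg: float = 0.0, curl_frac: float = 0.0,
                 heading=(1.0, 0.0), tail=(0.0, 0.0), n_points: int = 100):
    """Ground-truth pose -> (RegularContour in mm, LandmarkSet in mm).

    Bypasses rendering/tracing so feature- and classifier-level tests see
    exact geometry.
    """
    spine = sim.build_spine(np.asarray(tail, float), np.asarray(heading, float),
                            sim.DEFAULT_BODY_LENGTH_MM / 10.0,
                            bend_angle=np.deg2rad(bend_deg),
                            curl=curl_frac * 2 * np.pi * 0.95 / 10.0)
    poly = sim.spine_to_contour(spine, sim.default_half_width_profile())
    reg = ct.regularize_contour(poly, n_out=n_points, harmonics=12)
    lm = lmk.LandmarkSet(
        head=spine[0], neck_top=spine[3], neck=spine[5], neck_down=spine[7],
        tail=spine[10], centroid=lmk.polygon_centroid(reg.points), spine=spine)
    return reg, lm


@pytest.fixture
def straight_pose():
    return pose_contour(0.0)


@pytest.fixture
def left_bend_pose():
    return pose_contour(40.0)
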