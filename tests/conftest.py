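"""Shared fixtures: a small-frame rig and scene builders for fast tests.

Unit and integration tests run on a scaled-down 160 x 280 rig so that a full
180-s assay renders and analyses in seconds; the acceptance tests exercise
the full 540 x 960 standard format.
"""

from __future__ import annotations

import numpy as np
import pytest

from conetrack.geometry import RegionGeometry
from conetrack.synthetic import SyntheticScene, TrajectorySpec
from conetrack.synthetic import _rect_loop_waypoints  # noqa: F401  (reused by tests)

SMALL_DIMS = (160, 280)  # (width, height)


@pytest.fixture(scope="session")
def small_geometry() -> RegionGeometry:
    poly = np.array([(15.0, 20.0), (145.0, 20.0), (155.0, 260.0), (5.0, 260.0)])
    return RegionGeometry(poly, split_line_y=140.0, frame_dims=SMALL_DIMS)


def make_small_scene(
    geometry: RegionGeometry,
    *,
    duration: float = 20.0,
    noise_sd: float = 0.0,
    n_upper: int = 2,
    n_lower: int = 2,
    seed: int = 0,
    rest_from: float | None = None,
) -> SyntheticScene:
    """Scene with rectangular-loop flyers in well-separated cells.

    Cells keep blobs >= 3 diameters apart and >= 3 radii away from the
    split line, so detections and truth agree region-for-region.
    """
    upper_rows = [60.0, 100.0]
    lower_rows = [190.0, 235.0]
    trajectories = []
    rows = [(y, "u") for y in upper_rows[:n_upper]] + [
        (y, "l") for y in lower_rows[:n_lower]
    ]
    for i, (cy, tag) in enumerate(rows):
        speed = 28.0 + 4.0 * i
        stop = duration if rest_from is None else rest_from
        wps = _rect_loop_waypoints(80.0, cy, 40.0, 8.0, speed, stop, s0=31.0 * i)
        rests = ()
        if rest_from is not None:
            last = wps[-1]
            wps.append((duration, last[1], last[2]))
            rests = ((rest_from, duration),)
        trajectories.append(
            TrajectorySpec(f"{tag}{i}", tuple(wps), resting_intervals=rests,
                           blob_diameter=7.0)
        )
    return SyntheticScene(
        trajectories=tuple(trajectories),
        duration=duration,
        noise_sd=noise_sd,
        seed=seed,
        geometry=geometry,
    )


@pytest.fixture(scope="session")
def small_scene(small_geometry) -> SyntheticScene:
    return make_small_scene(small_geometry)


@pytest.fixture(scope="session")
def rendered_small(small_scene, tmp_path_factory):
    """A rendered 20-s noise-free small scene with its ground truth."""
    from conetrack.synthetic import generate_scene

    path = tmp_path_factory.mktemp("video") / "small.tif"
    asset, truth = generate_scene(small_scene, path)
    return asset, truth


@pytest.fixture(scope="session")
def detected_small(rendered_small, small_geometry):
    """Detection samples for the rendered small scene."""
    from conetrack.segmentation import SegmenterConfig, detect_assay

    asset, truth = rendered_small
    cfg = SegmenterConfig(min_area=10, max_area=500)
    samples = detect_assay(asset, cfg, small_geometry)
    return samples, truth, cfg
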