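"""Background-subtraction detection of moving mosquitoes."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from conetrack.geometry import RegionGeometry
from conetrack.segmentation import (
    BackgroundModel,
    DetectionSample,
    SegmenterConfig,
    detect_assay,
    detections_to_table,
    extract_movers,
    preprocess,
)
from conetrack.video import TimedFrame


@pytest.fixture()
def tiny_geometry():
    poly = np.array([(2.0, 2.0), (58.0, 2.0), (58.0, 98.0), (2.0, 98.0)])
    return RegionGeometry(poly, split_line_y=50.0, frame_dims=(60, 100))


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SegmenterConfig(history=80, min_area=12)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert SegmenterConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_area": 50, "max_area": 20},
            {"history": 0},
            {"max_movers": 0},
            {"open_kernel": 0},
            {"learning_rate": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmenterConfig(**kwargs)


class TestPreprocess:
    def test_constant_frame_is_a_fixed_point(self):
        frame = TimedFrame(0.0, np.full((40, 30), 77, np.uint8), 0)
        out = preprocess(frame, SegmenterConfig())
        np.testing.assert_array_equal(out.pixels, frame.pixels)

    def test_median_agrees_with_reference_filter(self):
        rng = np.random.default_rng(3)
        frame = TimedFrame(0.0, rng.integers(0, 255, (50, 40), dtype=np.uint8), 0)
        out = preprocess(frame, SegmenterConfig())
        ref = ndi.median_filter(frame.pixels.astype(np.float32), size=3,
                                mode="nearest")
        np.testing.assert_array_equal(out.pixels, ref.astype(np.uint8))

    def test_rejects_multichannel_frames(self):
        frame = TimedFrame(0.0, np.zeros((10, 10, 3), np.uint8), 0)
        with pytest.raises(ValueError):
            preprocess(frame, SegmenterConfig())


class TestBackgroundModel:
    def test_static_noisy_scene_converges_to_all_background(self):
        # median smoothing + background adaptation, as in the pipeline
        cfg = SegmenterConfig(history=20)
        model = BackgroundModel((50, 40), cfg)
        rng = np.random.default_rng(0)
        for k in range(40):
            raw = (200 + rng.normal(0, 3, (50, 40))).clip(0, 255).astype(np.uint8)
            frame = preprocess(TimedFrame(k * 0.1, raw, k), cfg)
            mask = model.apply(frame.pixels)
        assert mask.sum() == 0

    def test_displaced_dark_blob_is_foreground(self):
        cfg = SegmenterConfig(history=20)
        model = BackgroundModel((50, 40), cfg)
        base = np.full((50, 40), 200, np.uint8)
        for _ in range(30):
            model.apply(base)
        frame = base.copy()
        frame[10:16, 10:16] = 30
        mask = model.apply(frame)
        assert mask[10:16, 10:16].all()
        assert mask.sum() == 36

    def test_wrong_shape_is_a_usage_error(self):
        model = BackgroundModel((50, 40), SegmenterConfig())
        with pytest.raises(ValueError):
            model.apply(np.zeros((10, 10), np.uint8))


class TestExtractMovers:
    def test_empty_mask_yields_no_blobs(self, tiny_geometry):
        cfg = SegmenterConfig(min_area=4, max_area=400)
        mask = np.zeros((100, 60), bool)
        assert extract_movers(mask, cfg, tiny_geometry) == []

    def test_single_pixel_speck_removed_by_opening(self, tiny_geometry):
        cfg = SegmenterConfig(min_area=1, max_area=400, close_kernel=1)
        mask = np.zeros((100, 60), bool)
        mask[20, 20] = True
        assert extract_movers(mask, cfg, tiny_geometry) == []

    def test_blob_larger_than_element_survives_opening(self, tiny_geometry):
        cfg = SegmenterConfig(min_area=4, max_area=400, close_kernel=1)
        mask = np.zeros((100, 60), bool)
        mask[20:28, 20:28] = True  # 8 px across vs 3 px element
        blobs = extract_movers(mask, cfg, tiny_geometry)
        assert len(blobs) == 1
        assert blobs[0].area == pytest.approx(64, rel=0.2)

    def test_cap_keeps_the_largest_movers(self, tiny_geometry):
        cfg = SegmenterConfig(min_area=2, max_area=500, open_kernel=1, close_kernel=1)
        mask = np.zeros((100, 60), bool)
        sizes = [3, 4, 5, 6, 7, 8, 9]  # 7 qualifying components
        for i, s in enumerate(sizes):
            r, c = 5 + 12 * i, 10
            mask[r : r + 2, c : c + s] = True
        blobs = extract_movers(mask, cfg, tiny_geometry)
        assert len(blobs) == 5
        assert [b.area for b in blobs] == [18, 16, 14, 12, 10]
        assert all(a >= b for a, b in zip([b.area for b in blobs],
                                          [b.area for b in blobs][1:]))

    def test_component_kept_iff_centroid_inside_roi(self, tiny_geometry):
        cfg = SegmenterConfig(min_area=2, max_area=500, open_kernel=1, close_kernel=1)
        mask = np.zeros((100, 60), bool)
        mask[40:44, 0:3] = True   # centroid x=1, outside ROI (starts at x=2)
        mask[60:64, 1:6] = True   # centroid x=3, inside
        blobs = extract_movers(mask, cfg, tiny_geometry)
        assert len(blobs) == 1
        assert blobs[0].centroid[1] == pytest.approx(61.5)

    def test_mask_geometry_dims_mismatch_rejected(self, tiny_geometry):
        with pytest.raises(ValueError):
            extract_movers(np.zeros((10, 10), bool), SegmenterConfig(), tiny_geometry)


class TestDetectAssay:
    def test_counts_match_ground_truth_after_acclimatisation(self, detected_small):
        samples, truth, _ = detected_small
        det = np.array([s.n_moving for s in samples])
        tru = truth.n_moving().reindex(range(len(samples)), fill_value=0).to_numpy()
        post = slice(50, None)
        agreement = (det[post] == tru[post]).mean()
        assert agreement >= 0.95

    def test_centroid_error_within_blob_radius(self, detected_small, small_scene):
        samples, truth, _ = detected_small
        radius = small_scene.trajectories[0].blob_diameter / 2
        table = truth.table
        for k in range(60, len(samples), 25):
            det = samples[k]
            tru = table[table["sample"] == k]
            for blob in det.blobs:
                d = np.hypot(tru["x"] - blob.centroid[0], tru["y"] - blob.centroid[1])
                assert d.min() <= radius

    def test_all_static_scene_detects_nothing_after_acclimatisation(
        self, small_geometry, tmp_path
    ):
        from conetrack.synthetic import SyntheticScene, TrajectorySpec, generate_scene

        still = SyntheticScene(
            trajectories=tuple(
                TrajectorySpec(f"m{i}", ((0.0, 40.0 + 18.0 * i, 120.0),))
                for i in range(4)
            ),
            duration=10.0, noise_sd=0.0, geometry=small_geometry,
        )
        asset, _ = generate_scene(still, tmp_path / "still.tif")
        samples = detect_assay(asset, SegmenterConfig(min_area=10, max_area=500),
                               small_geometry)
        assert all(s.n_moving == 0 for s in samples[50:])

    def test_detection_log_is_deterministic(self, rendered_small, small_geometry):
        asset, _ = rendered_small
        cfg = SegmenterConfig(min_area=10, max_area=500)
        a = detect_assay(asset, cfg, small_geometry)
        b = detect_assay(asset, cfg, small_geometry)
        log_a = detections_to_table(a, small_geometry, "x").to_csv(index=False)
        log_b = detections_to_table(b, small_geometry, "x").to_csv(index=False)
        assert log_a == log_b

    def test_raising_min_area_never_increases_counts(self, rendered_small,
                                                     small_geometry):
        asset, _ = rendered_small
        lo = detect_assay(asset, SegmenterConfig(min_area=10, max_area=500),
                          small_geometry)
        hi = detect_assay(asset, SegmenterConfig(min_area=40, max_area=500),
                          small_geometry)
        assert all(h.n_moving <= l.n_moving for l, h in zip(lo, hi))

    def test_n_moving_never_exceeds_max_movers(self, detected_small):
        samples, _, cfg = detected_small
        assert all(s.n_moving <= cfg.max_movers for s in samples)
        assert all(len(s.blobs) <= cfg.max_movers for s in samples)


class TestDetectionTable:
    def test_every_sample_is_represented(self, detected_small, small_geometry):
        samples, _, _ = detected_small
        table = detections_to_table(samples, small_geometry, "a1")
        assert table["t"].nunique() == len(samples)
        assert set(table["assay_id"]) == {"a1"}

    def test_invalid_sample_carries_no_blobs(self):
        s = DetectionSample.make(1.0, [], 5, valid=False)
        assert s.blobs == () and s.n_moving == 0 and not s.valid
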