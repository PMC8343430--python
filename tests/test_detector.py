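"""Detector construction, initialization, training smoke, tiled inference."""

from dataclasses import replace

import numpy as np
import pytest

from snap import metrics
from snap.anchors import AnchorConfig, default_anchors, percentile_anchors
from snap.detector import (
    DetectorTrainConfig,
    build_detector,
    detect_nodules,
    load_detector,
    nms,
    save_detector,
    tile_grid,
    train_detector,
    _assign,
    _decode,
    _encode,
)
from snap.synthetic import generate_scenes
from snap.types import BoundingBox, Detection


@pytest.fixture(scope="module")
def tiny_model():
    return build_detector(arch="tiny", seed=0)


class TestBuildDetector:
    def test_classification_bias_gives_prior_probability(self, tiny_model):
        pi = 0.01
        bias = tiny_model.cls_head.final.b.value
        assert 1 / (1 + np.exp(-bias[0])) == pytest.approx(pi, rel=1e-6)

    def test_untrained_model_silent_on_blank_image(self, tiny_model):
        blank = np.full((256, 256, 3), 90, dtype=np.uint8)
        dets = detect_nodules(tiny_model, blank, score_threshold=0.5)
        assert dets == []

    def test_full_variant_head_shape(self):
        model = build_detector(arch="full", seed=0)
        # four 3x3 hidden conv layers of width 256 in each subnetwork
        convs = [l for l in model.cls_head.body.layers
                 if hasattr(l, "c_out")]
        assert len(convs) == 4
        assert all(c.c_out == 256 and c.k == 3 for c in convs)
        # single-class sigmoid head: anchors-per-location outputs
        assert model.cls_head.final.c_out == model.anchor_config.anchors_per_location
        assert model.reg_head.final.c_out == 4 * model.anchor_config.anchors_per_location
        assert model.parameter_count > 30_000_000

    def test_tiny_rejects_multilevel_anchors(self):
        with pytest.raises(ValueError):
            build_detector(default_anchors(), arch="tiny")

    def test_anchor_grid_matches_feature_map(self, tiny_model):
        x = np.zeros((1, 64, 64, 3), dtype=np.float32)
        feats = tiny_model.backbone.forward(x)
        fh, fw = feats[0].shape[1:3]
        anchors = tiny_model.anchors_for((64, 64), [(fh, fw)])
        assert anchors.shape == (fh * fw * 9, 4)
        # anchor centers lie on the stride-8 grid, offset by half a stride
        cx = (anchors[:, 0] + anchors[:, 2]) / 2
        assert set(np.round(np.unique(cx), 4)) <= {4.0 + 8 * i for i in range(8)}


class TestBoxCoding:
    def test_encode_decode_roundtrip(self, rng):
        anchors = np.array([[0, 0, 16, 16], [8, 8, 40, 24]], dtype=float)
        gt = np.array([[2, 3, 20, 19], [10, 9, 35, 27]], dtype=float)
        deltas = _encode(anchors, gt)
        back = _decode(anchors, deltas)
        assert np.allclose(back, gt, atol=1e-9)

    def test_assignment_thresholds(self):
        anchors = np.array([[0, 0, 10, 10], [100, 100, 110, 110],
                            [3, 3, 13, 13]], dtype=float)
        gt = np.array([[0, 0, 10, 10]], dtype=float)
        labels, matched = _assign(anchors, gt, pos_iou=0.5, neg_iou=0.4)
        assert labels[0] == 1 and matched[0] == 0
        assert labels[1] == 0
        # IoU(anchor2, gt) = 49/151 ~ 0.32 -> negative
        assert labels[2] == 0

    def test_best_anchor_force_matched(self):
        # no anchor reaches the positive threshold, yet the best one is matched
        anchors = np.array([[0, 0, 8, 8], [20, 20, 28, 28]], dtype=float)
        gt = np.array([[0, 4, 8, 16]], dtype=float)
        labels, matched = _assign(anchors, gt, pos_iou=0.5, neg_iou=0.4)
        assert labels[0] == 1 and matched[0] == 0


class TestNms:
    def test_duplicates_removed(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10], [50, 50, 60, 60]],
                         dtype=float)
        scores = np.array([0.9, 0.8, 0.7])
        keep = nms(boxes, scores, 0.5)
        assert keep == [0, 2]

    def test_idempotent(self):
        boxes = np.array([[0, 0, 10, 10], [40, 0, 50, 10]], dtype=float)
        scores = np.array([0.9, 0.8])
        once = nms(boxes, scores, 0.5)
        assert nms(boxes[once], scores[once], 0.5) == [0, 1]


class TestTiling:
    def test_512_image_four_tiles(self):
        assert len(tile_grid((512, 512))) == 4

    def test_300_image_padded_to_four_tiles(self):
        assert len(tile_grid((300, 300))) == 4

    def test_detections_clipped_to_original_bounds(self, scene_batch):
        """On a padded image no detection may extend past the original raster."""
        model = _overfit_model_cache()
        im = scene_batch[0].annotated
        # embed in a 300x300 canvas -> padded internally to 512x512
        canvas = np.full((300, 300, 3), im.pixels[0, 0], dtype=np.uint8)
        canvas[:im.shape[0], :im.shape[1]] = im.pixels
        dets = detect_nodules(model, canvas, score_threshold=0.2)
        for d in dets:
            assert d.box.x_max <= 300 and d.box.y_max <= 300
            assert d.box.x_min >= 0 and d.box.y_min >= 0


_CACHE = {}


def _overfit_model_cache():
    """A detector overfit to one small scene (shared across tests)."""
    if "model" not in _CACHE:
        from snap.synthetic import SceneParams, generate_scene
        p = SceneParams.for_canvas(144, 192, nodule_count_mean=6.0,
                                   nodule_radius_median=6.0,
                                   n_laterals=2, n_distractors=0, seed=31)
        scene = generate_scene(p)
        ac = percentile_anchors(scene.annotated.boxes, 3, 3,
                                base_sizes=(16.0,), strides=(8,))
        cfg = DetectorTrainConfig(anchor_config=ac, iterations=300, batch_size=2,
                                  split_fraction=0.5, flip_prob=0.0,
                                  rot_shear_rad=0.0, scale_translate=0.0, seed=0)
        model, _ = train_detector([scene.annotated, scene.annotated], cfg)
        _CACHE["model"] = model
        _CACHE["scene"] = scene
    return _CACHE["model"]


class TestTraining:
    def test_loss_decreases_on_synthetic_scenes(self, small_scene_params):
        scenes = generate_scenes(8, small_scene_params)
        imgs = [s.annotated for s in scenes]
        boxes = [b for im in imgs for b in im.boxes]
        ac = percentile_anchors(boxes, 3, 3, base_sizes=(16.0,), strides=(8,))
        cfg = DetectorTrainConfig(anchor_config=ac, iterations=60, batch_size=2,
                                  seed=0)
        model, info = train_detector(imgs, cfg)
        trace = info["loss_trace"]
        assert np.mean(trace[-10:]) < np.mean(trace[:10])

    def test_split_is_80_20_by_image_count(self, small_scene_params):
        scenes = generate_scenes(20, small_scene_params)
        imgs = [s.annotated for s in scenes]
        ac = percentile_anchors([b for im in imgs for b in im.boxes], 3, 3,
                                base_sizes=(16.0,), strides=(8,))
        cfg = DetectorTrainConfig(anchor_config=ac, iterations=1, batch_size=1,
                                  seed=0)
        _, info = train_detector(imgs, cfg)
        assert len(info["train_ids"]) == 16
        assert len(info["test_ids"]) == 4

    def test_overfit_single_scene_high_ap(self):
        """Standard detector sanity check: near-perfect AP on a memorized scene."""
        model = _overfit_model_cache()
        scene = _CACHE["scene"]
        dets = detect_nodules(model, scene.annotated.pixels, score_threshold=0.2)
        curve = metrics.average_precision(dets, scene.annotated.boxes, 0.5)
        assert curve.ap >= 0.9

    def test_too_few_images_rejected(self, small_scene_params):
        from snap.synthetic import generate_scene
        with pytest.raises(ValueError):
            train_detector([generate_scene(small_scene_params).annotated],
                           DetectorTrainConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectorTrainConfig(split_fraction=1.5)
        with pytest.raises(ValueError):
            DetectorTrainConfig(input_scale=100)


class TestSerialization:
    def test_save_load_preserves_outputs(self, tmp_path):
        model = _overfit_model_cache()
        scene = _CACHE["scene"]
        p = tmp_path / "det.npz"
        save_detector(model, p)
        back = load_detector(p)
        a = detect_nodules(model, scene.annotated.pixels, score_threshold=0.3)
        b = detect_nodules(back, scene.annotated.pixels, score_threshold=0.3)
        assert len(a) == len(b)
        for da, db in zip(a, b):
            assert da.box.as_tuple() == pytest.approx(db.box.as_tuple())
            assert da.score == pytest.approx(db.score)
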