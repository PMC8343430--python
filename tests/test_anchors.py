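"""Anchor strategies: default set, normal-percentile fit, DE search."""

import numpy as np
import pytest
from scipy.stats import norm

from snap.anchors import (
    AnchorConfig,
    BoxStats,
    anchor_box_overlap,
    default_anchors,
    optimize_anchors_de,
    percentile_anchors,
)
from snap.types import BoundingBox


def _boxes_from_sizes(sizes, aspect=1.0):
    out = []
    for s in sizes:
        w = s / np.sqrt(aspect)
        h = s * np.sqrt(aspect)
        out.append(BoundingBox(0, 0, w, h))
    return out


class TestDefaultAnchors:
    def test_scale_values(self):
        cfg = default_anchors()
        assert cfg.scales[0] == 1.0
        assert cfg.scales == pytest.approx((2 ** 0, 2 ** (1 / 3), 2 ** (2 / 3)))
        assert cfg.ratios == (0.5, 1.0, 2.0)

    def test_nine_anchors_per_location(self):
        assert default_anchors().anchors_per_location == 9

    def test_geometric_spacing(self):
        s = default_anchors().scales
        assert s[2] / s[1] == pytest.approx(s[1] / s[0])

    def test_five_level_pyramid(self):
        cfg = default_anchors()
        assert cfg.base_sizes == (32.0, 64.0, 128.0, 256.0, 512.0)
        assert cfg.strides == (8, 16, 32, 64, 128)


class TestPercentileAnchors:
    def test_identical_boxes_collapse_to_mean(self):
        boxes = _boxes_from_sizes([32.0] * 5)
        cfg = percentile_anchors(boxes, 3, 3)
        # all sizes 32, matched to base 32 -> every scale is 1
        assert cfg.scales == pytest.approx((1.0, 1.0, 1.0))
        assert cfg.ratios == pytest.approx((1.0, 1.0, 1.0))

    def test_quantile_function_oracle(self):
        # sizes whose fitted normal is exactly N(32, 8):
        sizes = np.array([24.0, 32.0, 40.0])  # mean 32, MLE sd = 8*sqrt(2/3)
        mu, sigma = sizes.mean(), sizes.std()
        boxes = _boxes_from_sizes(sizes)
        cfg = percentile_anchors(boxes, 3, 1, base_sizes=(32.0,), strides=(8,))
        z75 = norm.ppf(0.75)
        want = np.array([mu - sigma * z75, mu, mu + sigma * z75]) / 32.0
        assert cfg.scales == pytest.approx(tuple(want))

    def test_middle_percentile_is_mean_for_symmetric_input(self):
        sizes = [20.0, 30.0, 40.0, 50.0, 60.0]
        cfg = percentile_anchors(_boxes_from_sizes(sizes), 3, 3,
                                 base_sizes=(40.0,), strides=(8,))
        assert sorted(cfg.scales)[1] == pytest.approx(np.mean(sizes) / 40.0)

    def test_aspects_symmetric_on_log_scale(self):
        boxes = (_boxes_from_sizes([30.0] * 4, aspect=2.0)
                 + _boxes_from_sizes([30.0] * 4, aspect=0.5))
        cfg = percentile_anchors(boxes, 3, 3)
        assert cfg.ratios[0] * cfg.ratios[2] == pytest.approx(1.0)
        assert cfg.ratios[1] == pytest.approx(1.0)

    def test_percentile_positions_interleave_with_k(self):
        rng = np.random.default_rng(0)
        sizes = rng.normal(40, 6, 50)
        boxes = _boxes_from_sizes(np.abs(sizes) + 5)
        c3 = percentile_anchors(boxes, 3, 3, base_sizes=(32.0,), strides=(8,))
        c7 = percentile_anchors(boxes, 7, 7, base_sizes=(32.0,), strides=(8,))
        assert min(c7.scales) <= min(c3.scales)
        assert max(c7.scales) >= max(c3.scales)

    def test_needs_two_boxes(self):
        with pytest.raises(ValueError):
            percentile_anchors(_boxes_from_sizes([32.0]), 3, 3)


class TestAnchorBoxOverlap:
    def test_exact_match_is_one(self):
        cfg = AnchorConfig(scales=(1.0,), ratios=(1.0,), base_sizes=(10.0,),
                           strides=(8,))
        assert anchor_box_overlap(cfg, [BoundingBox(0, 0, 10, 10)]) == pytest.approx(1.0)

    def test_hand_geometry_half_overlap(self):
        # box 10x10 vs sole anchor 10x20 centered: IoU = 100 / 200
        cfg = AnchorConfig(scales=(1.0,), ratios=(2.0,),
                           base_sizes=(10.0 * np.sqrt(2),), strides=(8,))
        assert anchor_box_overlap(cfg, [BoundingBox(0, 0, 10, 10)]) == pytest.approx(0.5)

    def test_adding_anchor_never_decreases(self, rng):
        boxes = [BoundingBox(0, 0, float(rng.integers(5, 50)),
                             float(rng.integers(5, 50))) for _ in range(20)]
        small = AnchorConfig(scales=(1.0,), ratios=(1.0,), base_sizes=(16.0,),
                             strides=(8,))
        bigger = AnchorConfig(scales=(1.0, 2.0), ratios=(1.0,), base_sizes=(16.0,),
                              strides=(8,))
        assert (anchor_box_overlap(bigger, boxes)
                >= anchor_box_overlap(small, boxes) - 1e-12)


class TestDifferentialEvolution:
    def test_perfect_overlap_construction(self, rng):
        target = AnchorConfig(scales=(0.8, 1.0, 1.3), ratios=(1.0,),
                              base_sizes=(16.0,), strides=(8,))
        boxes = []
        for wh in target.shapes(16.0):
            for _ in range(4):
                boxes.append(BoundingBox(0, 0, wh[0], wh[1]))
        assert anchor_box_overlap(target, boxes) == pytest.approx(1.0)
        found = optimize_anchors_de(boxes, 3, 1, seed=0, generations=30,
                                    base_sizes=(16.0,), strides=(8,))
        assert (anchor_box_overlap(found, boxes)
                >= anchor_box_overlap(default_anchors((16.0,), (8,)), boxes))

    def test_optimized_never_below_default(self, rng):
        for trial in range(3):
            boxes = [BoundingBox(0, 0, float(rng.integers(4, 60)),
                                 float(rng.integers(4, 60))) for _ in range(15)]
            opt = optimize_anchors_de(boxes, 3, 3, seed=trial, generations=10,
                                      base_sizes=(16.0,), strides=(8,))
            dflt = default_anchors((16.0,), (8,))
            assert (anchor_box_overlap(opt, boxes)
                    >= anchor_box_overlap(dflt, boxes) - 1e-12)

    def test_deterministic_given_seed(self):
        boxes = [BoundingBox(0, 0, 10 + i, 12 + i) for i in range(12)]
        a = optimize_anchors_de(boxes, 3, 3, seed=5, generations=5,
                                base_sizes=(16.0,), strides=(8,))
        b = optimize_anchors_de(boxes, 3, 3, seed=5, generations=5,
                                base_sizes=(16.0,), strides=(8,))
        assert a.scales == b.scales and a.ratios == b.ratios

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            optimize_anchors_de([BoundingBox(0, 0, 5, 5)], 3, 3,
                                scale_bounds=(2.0, 2.0))


class TestSerialization:
    def test_yaml_roundtrip_for_all_strategies(self, tmp_path, rng):
        boxes = [BoundingBox(0, 0, float(rng.integers(5, 40)),
                             float(rng.integers(5, 40))) for _ in range(10)]
        configs = [
            default_anchors(),
            percentile_anchors(boxes, 3, 3),
            optimize_anchors_de(boxes, 3, 3, seed=0, generations=3,
                                base_sizes=(16.0,), strides=(8,)),
        ]
        for i, cfg in enumerate(configs):
            p = tmp_path / f"a{i}.yaml"
            cfg.to_yaml(p)
            back = AnchorConfig.from_yaml(p)
            assert back.scales == pytest.approx(cfg.scales)
            assert back.ratios == pytest.approx(cfg.ratios)
            assert back.base_sizes == cfg.base_sizes

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            AnchorConfig(scales=(2.0, 1.0), ratios=(1.0,))

    def test_box_stats(self):
        stats = BoxStats.from_boxes([BoundingBox(0, 0, 4, 9), BoundingBox(0, 0, 9, 4)])
        assert stats.sizes == pytest.approx([6.0, 6.0])
        assert stats.log_aspect_mu == pytest.approx(0.0)
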