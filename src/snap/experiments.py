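"""Desk-scale end-to-end study: train on synthetic scenes, evaluate held out.

This reproduces the pipeline's workflow at reduced resolution: generate
root scenes, fit percentile anchors to the training annotations, train the
tiny detector and tiny segmenter on the training scenes, choose the
detector operating threshold on training scenes only (maximizing the
balanced operating point), then measure sensitivity, precision, AP and
count agreement (R^2) on held-out scenes the models never saw.

Scene conditions: 256 x 192 px canvases (a ~1:20 downscale of the tray
photographs) with log-normal nodule radii (median 6 px at this scale),
negative-binomial counts (mean 10, dispersion 4), four lateral roots and
one cyst-like distractor per scene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .anchors import percentile_anchors
from .detector import DetectorTrainConfig, detect_nodules, train_detector
from .segmenter import SegmenterArch, SegmenterTrainConfig, segment_taproot, train_segmenter
from .spatial import QuantifyConfig, quantify
from .synthetic import SceneParams, generate_scenes
from .types import BoundingBox, Detection

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    n_train: int = 80
    n_test: int = 20
    image_size: tuple[int, int] = (192, 256)  # (height, width)
    nodule_radius_median: float = 6.0
    nodule_radius_log_sd: float = 0.25
    nodule_count_mean: float = 10.0
    nodule_count_dispersion: float = 4.0
    n_laterals: int = 4
    n_distractors: int = 1
    detector_iterations: int = 800
    detector_batch: int = 4
    # the tiny two-layer heads need a larger init scale than the full
    # model's 0.001 to break symmetry within a CPU-scale step budget
    detector_init_sigma: float = 0.01
    segmenter_iterations: int = 120
    segmenter_batch: int = 4
    segmenter_base_width: int = 8
    iou_threshold: float = 0.5
    threshold_candidates: tuple[float, ...] = (0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5)
    calibration_scenes: int = 20
    r_dilate: float = 3.0
    seed: int = 1


@dataclass
class StudyResult:
    sensitivity: float
    precision: float
    count_r2: float
    pooled_ap: float
    operating_threshold: float
    segmentation_iou: float
    zone_capture_rate: float
    per_scene_pred_counts: list[int] = field(default_factory=list)
    per_scene_true_counts: list[int] = field(default_factory=list)
    detector_loss_trace: list[float] = field(default_factory=list)
    segmenter_loss_trace: list[float] = field(default_factory=list)


def _evaluate(model, scenes, thr, iou):
    tp = fp = fn = 0
    pred_counts, true_counts = [], []
    all_dets = []
    for s in scenes:
        dets = detect_nodules(model, s.annotated.pixels, score_threshold=thr)
        m = metrics.match_detections(dets, s.annotated.boxes, iou)
        tp += m.tp
        fp += m.fp
        fn += m.fn
        pred_counts.append(len(dets))
        true_counts.append(len(s.annotated.boxes))
        all_dets.append(dets)
    sens = tp / max(tp + fn, 1)
    prec = tp / max(tp + fp, 1)
    return sens, prec, pred_counts, true_counts, all_dets


def select_operating_threshold(model, scenes, candidates, iou) -> float:
    """Pick the score threshold with the best balanced operating point
    (max of min(sensitivity, precision), F1 as tie-break) on TRAINING scenes."""
    best, best_key = candidates[0], (-1.0, -1.0)
    for thr in candidates:
        sens, prec, *_ = _evaluate(model, scenes, thr, iou)
        f1 = 2 * sens * prec / max(sens + prec, 1e-9)
        key = (min(sens, prec), f1)
        log.info("threshold %.2f: sens %.3f prec %.3f", thr, sens, prec)
        if key > best_key:
            best_key, best = key, thr
    return best


def run_scaled_study(cfg: StudyConfig | None = None) -> StudyResult:
    cfg = cfg or StudyConfig()
    h, w = cfg.image_size
    params = SceneParams.for_canvas(
        h, w,
        nodule_radius_median=cfg.nodule_radius_median,
        nodule_radius_log_sd=cfg.nodule_radius_log_sd,
        nodule_count_mean=cfg.nodule_count_mean,
        nodule_count_dispersion=cfg.nodule_count_dispersion,
        n_laterals=cfg.n_laterals,
        n_distractors=cfg.n_distractors,
        seed=cfg.seed,
    )
    scenes = generate_scenes(cfg.n_train + cfg.n_test, params)
    train_scenes = scenes[:cfg.n_train]
    test_scenes = scenes[cfg.n_train:]
    train_images = [s.annotated for s in train_scenes]

    boxes = [b for im in train_images for b in im.boxes]
    anchor_cfg = percentile_anchors(boxes, 3, 3, base_sizes=(16.0,), strides=(8,))
    log.info("percentile anchors: scales %s ratios %s",
             np.round(anchor_cfg.scales, 3), np.round(anchor_cfg.ratios, 3))

    det_cfg = DetectorTrainConfig(
        anchor_config=anchor_cfg, iterations=cfg.detector_iterations,
        batch_size=cfg.detector_batch, subnet_init_sigma=cfg.detector_init_sigma,
        seed=cfg.seed)
    detector, det_info = train_detector(train_images, det_cfg)

    seg_cfg = SegmenterTrainConfig(
        iterations=cfg.segmenter_iterations, batch_size=cfg.segmenter_batch,
        seed=cfg.seed)
    segmenter, seg_info = train_segmenter(
        train_images, seg_cfg, arch=SegmenterArch(base_width=cfg.segmenter_base_width))

    thr = select_operating_threshold(
        detector, train_scenes[:cfg.calibration_scenes],
        cfg.threshold_candidates, cfg.iou_threshold)
    log.info("operating threshold selected on training scenes: %.2f", thr)

    sens, prec, pred_counts, true_counts, all_dets = _evaluate(
        detector, test_scenes, thr, cfg.iou_threshold)
    r2 = metrics.count_r2(pred_counts, true_counts)

    # pooled PR curve over the held-out scenes (images separated spatially)
    pooled_preds, pooled_truths = [], []
    off = 0.0
    for s, dets in zip(test_scenes, all_dets):
        for d in dets:
            b = d.box
            pooled_preds.append(Detection(BoundingBox(
                b.x_min + off, b.y_min, b.x_max + off, b.y_max), d.score))
        for t in s.annotated.boxes:
            pooled_truths.append(BoundingBox(
                t.x_min + off, t.y_min, t.x_max + off, t.y_max))
        off += 1e6
    pooled_ap = metrics.average_precision(
        pooled_preds, pooled_truths, cfg.iou_threshold).ap if pooled_truths else 0.0

    # segmentation quality and taproot-zone capture on held-out scenes
    ious, captured, attached = [], 0, 0
    for s, dets in zip(test_scenes, all_dets):
        pred_mask = segment_taproot(segmenter, s.annotated.pixels)
        g = s.annotated.taproot_mask.astype(bool)
        d = pred_mask.astype(bool)
        ious.append((g & d).sum() / max((g | d).sum(), 1))
        if pred_mask.any():
            gt_dets = [Detection(b, 1.0) for b in s.annotated.boxes]
            rep = quantify(gt_dets, pred_mask, QuantifyConfig(r_dilate=cfg.r_dilate))
            for rec, on in zip(rep.records, s.on_taproot):
                attached += int(on)
                captured += int(bool(on and rec.on_taproot))
    seg_iou = float(np.mean(ious)) if ious else 0.0
    zone_capture = captured / attached if attached else float("nan")

    return StudyResult(
        sensitivity=float(sens), precision=float(prec), count_r2=float(r2),
        pooled_ap=float(pooled_ap), operating_threshold=float(thr),
        segmentation_iou=seg_iou, zone_capture_rate=float(zone_capture),
        per_scene_pred_counts=pred_counts, per_scene_true_counts=true_counts,
        detector_loss_trace=det_info["loss_trace"],
        segmenter_loss_trace=seg_info["loss_trace"],
    )
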