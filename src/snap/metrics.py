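"""Detection evaluation: greedy matching, sensitivity, precision, AP, count R^2.

A prediction matches the unmatched ground-truth box of highest IoU at or
above the threshold, consuming predictions in descending confidence.  A
prediction whose best overlap is with an already-matched truth is a false
positive (a twice-counted nodule); unmatched truths are false negatives.

    sensitivity = TP / (TP + FN)        precision = TP / (TP + FP)

AP is the area under the precision envelope over recall, with predictions
ranked by confidence (all-point interpolation of the integral of p(r)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import BoundingBox, Detection

UNDEFINED = float("nan")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pred_matched: list[bool]
    truth_covered: list[bool]

    def __post_init__(self):
        assert self.tp + self.fn == len(self.truth_covered)
        assert self.tp + self.fp == len(self.pred_matched)


@dataclass
class PRCurve:
    recalls: np.ndarray
    precisions: np.ndarray
    ap: float


def _sorted_preds(preds: list[Detection]) -> list[Detection]:
    # descending score; ties by ascending x_min for run-stable ordering
    return sorted(preds, key=lambda d: (-d.score, d.box.x_min))


def match_detections(preds: list[Detection], truths: list[BoundingBox],
                     iou_threshold: float = 0.5) -> MatchResult:
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = _sorted_preds(preds)
    covered = [False] * len(truths)
    matched_flags = {id(d): False for d in order}
    for d in order:
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if covered[j]:
                continue
            iou = d.box.iou(t)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            covered[best_j] = True
            matched_flags[id(d)] = True
    pred_matched = [matched_flags[id(d)] for d in preds]
    tp = sum(pred_matched)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp,
                       pred_matched=pred_matched, truth_covered=covered)


def sensitivity(m: MatchResult) -> float:
    if m.tp + m.fn == 0:
        return UNDEFINED
    return m.tp / (m.tp + m.fn)


def precision(m: MatchResult) -> float:
    if m.tp + m.fp == 0:
        return UNDEFINED
    return m.tp / (m.tp + m.fp)


def average_precision(preds: list[Detection], truths: list[BoundingBox],
                      iou_threshold: float = 0.5) -> PRCurve:
    """Envelope AP with predictions consumed in descending confidence."""
    if len(truths) < 1:
        raise ValueError("need at least one ground-truth box")
    if not preds:
        return PRCurve(recalls=np.array([]), precisions=np.array([]), ap=0.0)
    order = _sorted_preds(preds)
    covered = [False] * len(truths)
    tp_flags = np.zeros(len(order), dtype=bool)
    for i, d in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if covered[j]:
                continue
            iou = d.box.iou(t)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            covered[best_j] = True
            tp_flags[i] = True
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recalls = tp_cum / len(truths)
    precisions = tp_cum / (tp_cum + fp_cum)
    # precision envelope: at each point, the max precision at that recall or greater
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recalls, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return PRCurve(recalls=recalls, precisions=precisions, ap=float(ap))


def count_r2(pred_counts, true_counts) -> float:
    """Coefficient of determination of predicted vs. true per-image counts."""
    pred = np.asarray(pred_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("need equal-length count vectors of size >= 2")
    ss_tot = float(((true - true.mean()) ** 2).sum())
    if ss_tot == 0:
        return UNDEFINED
    ss_res = float(((true - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)
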