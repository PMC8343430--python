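"""Detection matching, sensitivity/precision, AP, and count R^2."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snap import metrics
from snap.types import BoundingBox, Detection


def _box(x, y, w=10, h=10):
    return BoundingBox(x, y, x + w, y + h)


def _random_instance(rng, n_pred, n_truth, grid=40):
    truths = []
    while len(truths) < n_truth:
        truths.append(_box(float(rng.integers(0, grid)), float(rng.integers(0, grid)),
                           float(rng.integers(4, 14)), float(rng.integers(4, 14))))
    preds = []
    for _ in range(n_pred):
        if truths and rng.random() < 0.6:
            t = truths[rng.integers(len(truths))]
            jx, jy = rng.normal(0, 2, 2)
            preds.append(Detection(BoundingBox(t.x_min + jx, t.y_min + jy,
                                               t.x_max + jx, t.y_max + jy),
                                   float(rng.random())))
        else:
            b = _box(float(rng.integers(0, grid)), float(rng.integers(0, grid)),
                     float(rng.integers(4, 14)), float(rng.integers(4, 14)))
            preds.append(Detection(b, float(rng.random())))
    return preds, truths


def _brute_force_max_matching(preds, truths, thr):
    """Maximum-cardinality assignment by exhaustive enumeration (<= 6 boxes)."""
    n, m = len(preds), len(truths)
    best = 0
    feasible = [[preds[i].box.iou(truths[j]) >= thr for j in range(m)] for i in range(n)]
    for k in range(min(n, m), 0, -1):
        for pi in itertools.permutations(range(m), k):
            for ci in itertools.combinations(range(n), k):
                if all(feasible[c][p] for c, p in zip(ci, pi)):
                    return k
    return best


class TestMatching:
    def test_perfect_predictions(self):
        truths = [_box(0, 0), _box(20, 20), _box(40, 0)]
        preds = [Detection(t, 1.0) for t in truths]
        m = metrics.match_detections(preds, truths, 0.5)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)

    def test_double_count_is_false_positive(self):
        t = [_box(0, 0)]
        preds = [Detection(t[0], 0.9), Detection(t[0], 0.8)]
        m = metrics.match_detections(preds, t, 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_invariants_on_random_instances(self, rng):
        for _ in range(50):
            preds, truths = _random_instance(rng, int(rng.integers(0, 7)),
                                             int(rng.integers(1, 6)))
            m = metrics.match_detections(preds, truths, 0.5)
            assert m.tp + m.fn == len(truths)
            assert m.tp + m.fp == len(preds)
            assert m.tp <= min(len(preds), len(truths))

    def test_greedy_equals_optimal_assignment_when_nondegenerate(self, rng):
        agree = 0
        total = 0
        for _ in range(80):
            preds, truths = _random_instance(rng, int(rng.integers(1, 6)),
                                             int(rng.integers(1, 6)))
            m = metrics.match_detections(preds, truths, 0.5)
            opt = _brute_force_max_matching(preds, truths, 0.5)
            total += 1
            # score-greedy matching is optimal whenever overlaps do not chain;
            # it can never exceed the optimum
            assert m.tp <= opt
            agree += int(m.tp == opt)
        assert agree / total >= 0.9


class TestRatios:
    @pytest.mark.parametrize("tp,fp,fn,sens,prec", [
        (9, 0, 1, 0.9, 1.0),
        (19, 1, 0, 1.0, 0.95),
        (5, 0, 0, 1.0, 1.0),
    ])
    def test_formula_plug_in(self, tp, fp, fn, sens, prec):
        m = metrics.MatchResult(tp=tp, fp=fp, fn=fn,
                                pred_matched=[True] * tp + [False] * fp,
                                truth_covered=[True] * tp + [False] * fn)
        assert metrics.sensitivity(m) == pytest.approx(sens)
        assert metrics.precision(m) == pytest.approx(prec)

    def test_zero_denominator_is_undefined_sentinel(self):
        m = metrics.MatchResult(tp=0, fp=0, fn=0, pred_matched=[], truth_covered=[])
        assert metrics.is_undefined(metrics.sensitivity(m))
        assert metrics.is_undefined(metrics.precision(m))

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(deadline=None, max_examples=50)
    def test_definitions_hold_for_any_counts(self, tp, fp, fn):
        m = metrics.MatchResult(tp=tp, fp=fp, fn=fn,
                                pred_matched=[True] * tp + [False] * fp,
                                truth_covered=[True] * tp + [False] * fn)
        if tp + fn:
            assert metrics.sensitivity(m) == pytest.approx(tp / (tp + fn))
        if tp + fp:
            assert metrics.precision(m) == pytest.approx(tp / (tp + fp))


def _brute_force_ap(preds, truths, thr):
    """Envelope AP recomputed from first principles (independent path)."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score,
                                                     preds[i].box.x_min))
    covered = [False] * len(truths)
    flags = []
    for i in order:
        best, bj = 0.0, -1
        for j, t in enumerate(truths):
            iou = preds[i].box.iou(t)
            if not covered[j] and iou >= thr and iou > best:
                best, bj = iou, j
        if bj >= 0:
            covered[bj] = True
            flags.append(1)
        else:
            flags.append(0)
    recs, precs = [], []
    tp = fp = 0
    for f in flags:
        tp += f
        fp += 1 - f
        recs.append(tp / len(truths))
        precs.append(tp / (tp + fp))
    ap = 0.0
    prev = 0.0
    for i, r in enumerate(recs):
        env = max(precs[i:])
        ap += (r - prev) * env
        prev = r
    return ap


class TestAveragePrecision:
    def test_single_correct_prediction(self):
        t = [_box(0, 0)]
        assert metrics.average_precision([Detection(t[0], 0.9)], t, 0.5).ap == 1.0

    def test_tp_fp_tp_worked_example(self):
        # ranked outcomes [TP, FP, TP] over 2 truths -> AP = 5/6
        truths = [_box(0, 0), _box(100, 100)]
        preds = [Detection(truths[0], 0.9),
                 Detection(_box(200, 200), 0.8),
                 Detection(truths[1], 0.7)]
        curve = metrics.average_precision(preds, truths, 0.5)
        assert curve.ap == pytest.approx(5 / 6, abs=1e-12)

    def test_no_predictions_gives_zero(self):
        assert metrics.average_precision([], [_box(0, 0)], 0.5).ap == 0.0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            preds, truths = _random_instance(rng, int(rng.integers(1, 11)),
                                             int(rng.integers(1, 11)))
            got = metrics.average_precision(preds, truths, 0.5).ap
            want = _brute_force_ap(preds, truths, 0.5)
            assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_monotone_score_rescaling(self, rng):
        preds, truths = _random_instance(rng, 8, 5)
        a = metrics.average_precision(preds, truths, 0.5).ap
        rescaled = [Detection(p.box, p.score ** 3) for p in preds]
        assert metrics.average_precision(rescaled, truths, 0.5).ap == pytest.approx(a)

    def test_appending_lowest_rank_fp_never_raises_ap(self, rng):
        for _ in range(20):
            preds, truths = _random_instance(rng, 5, 4)
            base = metrics.average_precision(preds, truths, 0.5).ap
            min_score = min(p.score for p in preds) if preds else 1.0
            worse = preds + [Detection(_box(500, 500), min_score * 0.5)]
            assert metrics.average_precision(worse, truths, 0.5).ap <= base + 1e-12


class TestCountR2:
    def test_perfect(self):
        assert metrics.count_r2([1, 2, 3], [1, 2, 3]) == 1.0

    def test_constant_mean_prediction_is_zero(self):
        true = [1.0, 2.0, 3.0, 4.0]
        pred = [2.5] * 4
        assert metrics.count_r2(pred, true) == pytest.approx(0.0)

    def test_worked_negative_example(self):
        assert metrics.count_r2([1, 2, 3, 8], [1, 2, 3, 4]) == pytest.approx(-2.2)

    def test_zero_variance_undefined(self):
        assert metrics.is_undefined(metrics.count_r2([1, 2], [3, 3]))
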