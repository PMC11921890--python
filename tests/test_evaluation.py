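"""Detection metrics against brute-force oracles."""

import itertools

import numpy as np
import pytest

from dbytk.evaluation import (
    average_precision,
    average_precision_11point,
    evaluate_detections,
    f1_score,
    match_detections,
    measure_fps,
)
from dbytk.pipeline import TrainConfig


def brute_force_greedy_match(pred_boxes, pred_scores, pred_cls, gt_boxes,
                             gt_cls, iou_thr):
    """Reference matcher: explicit loops, no vectorization."""
    from dbytk.evaluation import box_iou

    order = sorted(range(len(pred_boxes)), key=lambda i: -pred_scores[i])
    used = set()
    tp = 0
    for i in order:
        best, best_iou = None, iou_thr
        for j in range(len(gt_boxes)):
            if j in used or gt_cls[j] != pred_cls[i]:
                continue
            v = box_iou(pred_boxes[i], gt_boxes[j])[0, 0]
            if v >= best_iou:
                best, best_iou = j, v
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(pred_boxes) - tp, len(gt_boxes) - tp


def _random_instance(rng, n_pred, n_gt):
    def boxes(n):
        xy = rng.uniform(0, 80, size=(n, 2))
        wh = rng.uniform(5, 30, size=(n, 2))
        return np.concatenate([xy, xy + wh], axis=1)

    return (boxes(n_pred), rng.uniform(size=n_pred),
            rng.integers(0, 3, size=n_pred), boxes(n_gt),
            rng.integers(0, 3, size=n_gt))


class TestMatching:
    def test_perfect_single_match(self):
        b = np.array([[0.0, 0.0, 10.0, 10.0]])
        res = match_detections(b, np.array([0.9]), np.array([0]), b,
                               np.array([0]), 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_one_to_one_rule_double_detection(self):
        gt = np.array([[0.0, 0.0, 10.0, 10.0]])
        preds = np.array([[0.0, 0.0, 10.0, 10.0], [1.0, 1.0, 11.0, 11.0]])
        res = match_detections(preds, np.array([0.9, 0.8]), np.array([0, 0]),
                               gt, np.array([0]), 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_class_mismatch_is_fp(self):
        b = np.array([[0.0, 0.0, 10.0, 10.0]])
        res = match_detections(b, np.array([0.9]), np.array([1]), b,
                               np.array([0]), 0.5)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        inst = _random_instance(rng, rng.integers(0, 10), rng.integers(0, 10))
        res = match_detections(*inst, iou_thr=0.5)
        assert (res.tp, res.fp, res.fn) == \
            brute_force_greedy_match(*inst, iou_thr=0.5)


def sweep_ap_oracle(scores, matched, n_gt):
    """AP by exhaustive threshold sweep + trapezoid-free step integration."""
    pts = []
    for thr in sorted(set(scores)) + [np.inf]:
        keep = scores >= thr
        tp = int(matched[keep].sum())
        fp = int(keep.sum() - tp)
        r = tp / n_gt
        p = tp / max(tp + fp, 1)
        pts.append((r, p))
    pts.sort()
    recalls = np.array([0.0] + [r for r, _ in pts] + [1.0])
    precs = np.array([1.0] + [p for _, p in pts] + [0.0])
    precs = np.flip(np.maximum.accumulate(np.flip(precs)))
    idx = np.nonzero(np.diff(recalls))[0]
    return float(np.sum(np.diff(recalls)[idx] * precs[idx + 1]))


class TestAveragePrecision:
    def test_perfect_detector(self):
        assert average_precision([0.5, 1.0], [1.0, 1.0]) == 1.0

    def test_zero_tp_detector(self):
        assert average_precision([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_five_detection_toy_matches_sweep_oracle(self):
        # fixed confidences and hit flags; 4 ground truths
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        matched = np.array([True, False, True, True, False])
        n_gt = 4
        tp = np.cumsum(matched)
        fp = np.cumsum(~matched)
        ap = average_precision(tp / n_gt, tp / (tp + fp))
        assert ap == pytest.approx(sweep_ap_oracle(scores, matched, n_gt),
                                   abs=1e-12)

    def test_11point_bounded_by_allpoints_on_monotone_curve(self):
        r = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        p = np.array([1.0, 0.9, 0.8, 0.7, 0.6])
        assert 0 <= average_precision_11point(r, p) <= 1


class TestEvaluateDetections:
    def _toy(self, rng, n_images=4):
        preds, gts = [], []
        for _ in range(n_images):
            pb, ps, pc, gb, gc = _random_instance(
                rng, rng.integers(1, 8), rng.integers(1, 8)
            )
            preds.append({"boxes": pb, "scores": ps, "cls": pc})
            gts.append({"boxes": gb, "cls": gc})
        return preds, gts

    @pytest.mark.parametrize("seed", range(5))
    def test_map50_at_least_map50_95(self, seed):
        preds, gts = self._toy(np.random.default_rng(seed))
        res = evaluate_detections(preds, gts)
        assert res.map50 >= res.map50_95 - 1e-12

    def test_perfect_predictions_score_one(self):
        rng = np.random.default_rng(0)
        _, _, _, gb, gc = _random_instance(rng, 0, 6)
        preds = [{"boxes": gb, "scores": np.full(len(gb), 0.9), "cls": gc}]
        gts = [{"boxes": gb, "cls": gc}]
        res = evaluate_detections(preds, gts)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(1.0)
        assert res.f1 == pytest.approx(1.0)

    def test_absent_class_excluded_from_mean(self):
        gb = np.array([[0.0, 0.0, 10.0, 10.0]])
        preds = [{"boxes": gb, "scores": np.array([0.9]),
                  "cls": np.array([0])}]
        gts = [{"boxes": gb, "cls": np.array([0])}]
        res = evaluate_detections(preds, gts, n_classes=3)
        assert set(res.per_class_ap50) == {0}
        assert res.map50 == pytest.approx(1.0)


class TestF1:
    @pytest.mark.parametrize("p,r,expected", [
        (88.0, 82.9, 85.4),
        (90.5, 86.7, 88.6),
        (91.4, 84.2, 87.7),
        (91.7, 87.1, 89.3),
        (91.8, 87.6, 89.7),
    ])
    def test_published_pr_pairs_reproduce_f1(self, p, r, expected):
        assert round(f1_score(p, r), 1) == expected

    def test_symmetry_fixed_point(self):
        assert f1_score(77.7, 77.7) == pytest.approx(77.7)

    def test_zero_zero_defined_as_zero(self):
        assert f1_score(0.0, 0.0) == 0.0


class TestFPS:
    def test_zero_timed_iterations_rejected(self):
        from dbytk.detector import ModelSpec, build_model

        m = build_model(ModelSpec.tiny(dual=False))
        with pytest.raises(ValueError):
            measure_fps(m, 32, n_warmup=0, n_timed=0)

    def test_report_includes_context(self):
        from dbytk.detector import ModelSpec, build_model

        m = build_model(ModelSpec.tiny(dual=False))
        r = measure_fps(m, 32, n_warmup=1, n_timed=2)
        assert r["input_size"] == 32 and r["batch"] == 1
        assert r["fps"] > 0


def test_train_config_defaults_match_study():
    cfg = TrainConfig()
    assert (cfg.batch_size, cfg.epochs, cfg.patience, cfg.workers,
            cfg.input_size) == (16, 300, 50, 4, 640)
    assert cfg.pretrained is False
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
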