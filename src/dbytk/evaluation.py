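"""Detection metrics: greedy IoU matching, AP/mAP, F1 and an FPS harness.

Precision P = TP/(TP+FP), recall R = TP/(TP+FN); AP is the area under the
monotone (all-points interpolated) precision-recall curve; mAP averages AP
over classes, and mAP@50-95 additionally over IoU thresholds 0.50:0.05:0.95.
F1 = 2PR/(P+R).  Classes absent from the ground truth are excluded from the
class mean (0/0 is undefined, not zero).
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N,4) and (M,4) xyxy boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix = np.clip(np.minimum(a[:, None, 2], b[None, :, 2])
                 - np.maximum(a[:, None, 0], b[None, :, 0]), 0, None)
    iy = np.clip(np.minimum(a[:, None, 3], b[None, :, 3])
                 - np.maximum(a[:, None, 1], b[None, :, 1]), 0, None)
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter + 1e-12)


@dataclasses.dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched: np.ndarray  # (n_preds,) bool, in descending-confidence order


def match_detections(pred_boxes, pred_scores, pred_cls, gt_boxes, gt_cls,
                     iou_thr: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching for a single image.

    Predictions are processed in descending confidence; each matches the
    highest-IoU still-unmatched same-class ground truth with IoU >= the
    threshold.  Unmatched predictions are FP, unmatched ground truths FN.
    """
    pred_boxes = np.asarray(pred_boxes, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    pred_scores = np.asarray(pred_scores, dtype=np.float64)
    pred_cls = np.asarray(pred_cls, dtype=int)
    gt_cls = np.asarray(gt_cls, dtype=int)
    order = np.argsort(-pred_scores, kind="stable")
    used = np.zeros(len(gt_boxes), dtype=bool)
    matched = np.zeros(len(pred_boxes), dtype=bool)
    if len(gt_boxes) and len(pred_boxes):
        iou = box_iou(pred_boxes, gt_boxes)
        for rank, i in enumerate(order):
            cand = (~used) & (gt_cls == pred_cls[i]) & (iou[i] >= iou_thr)
            if cand.any():
                j = np.where(cand, iou[i], -1.0).argmax()
                used[j] = True
                matched[rank] = True
    tp = int(matched.sum())
    return MatchResult(tp, len(pred_boxes) - tp, len(gt_boxes) - tp, matched)


def average_precision(recall, precision) -> float:
    """Area under the monotone (all-points) interpolated PR curve."""
    r = np.concatenate([[0.0], np.asarray(recall, dtype=np.float64), [1.0]])
    p = np.concatenate([[1.0], np.asarray(precision, dtype=np.float64), [0.0]])
    p = np.flip(np.maximum.accumulate(np.flip(p)))
    idx = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def average_precision_11point(recall, precision) -> float:
    """Legacy 11-point interpolation variant."""
    r = np.asarray(recall, dtype=np.float64)
    p = np.asarray(precision, dtype=np.float64)
    ap = 0.0
    for t in np.linspace(0, 1, 11):
        mask = r >= t
        ap += (p[mask].max() if mask.any() else 0.0) / 11.0
    return float(ap)


def _class_ap(preds, gts, cls, iou_thr) -> float | None:
    """AP of one class over a whole dataset; None if the class has no gts."""
    n_gt = sum(int((np.asarray(g["cls"], dtype=int) == cls).sum()) for g in gts)
    if n_gt == 0:
        return None
    scores, flags = [], []
    for pr, gt in zip(preds, gts):
        sel = np.asarray(pr["cls"], dtype=int) == cls
        gsel = np.asarray(gt["cls"], dtype=int) == cls
        res = match_detections(
            np.asarray(pr["boxes"], dtype=np.float64).reshape(-1, 4)[sel],
            np.asarray(pr["scores"], dtype=np.float64)[sel],
            np.zeros(int(sel.sum()), dtype=int),
            np.asarray(gt["boxes"], dtype=np.float64).reshape(-1, 4)[gsel],
            np.zeros(int(gsel.sum()), dtype=int),
            iou_thr,
        )
        order = np.argsort(-np.asarray(pr["scores"], dtype=np.float64)[sel],
                           kind="stable")
        scores.append(np.asarray(pr["scores"], dtype=np.float64)[sel][order])
        flags.append(res.matched)
    scores = np.concatenate(scores) if scores else np.empty(0)
    flags = np.concatenate(flags) if flags else np.empty(0, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    return average_precision(recall, precision)


@dataclasses.dataclass
class EvalResult:
    """Aggregate detection metrics (fractions in [0,1]; x100 to report %)."""

    per_class_ap50: dict
    map50: float
    map50_95: float
    precision: float
    recall: float
    f1: float
    conf_threshold: float

    def row(self) -> dict:
        """Table-ready percentages, one decimal."""
        return {
            "P": round(100 * self.precision, 1),
            "R": round(100 * self.recall, 1),
            "mAP@50": round(100 * self.map50, 1),
            "mAP@50-95": round(100 * self.map50_95, 1),
            "F1": round(100 * self.f1, 1),
        }


def _pr_at_threshold(preds, gts, conf, iou_thr=0.5):
    tp = fp = fn = 0
    for pr, gt in zip(preds, gts):
        sel = np.asarray(pr["scores"], dtype=np.float64) >= conf
        res = match_detections(
            np.asarray(pr["boxes"], dtype=np.float64).reshape(-1, 4)[sel],
            np.asarray(pr["scores"], dtype=np.float64)[sel],
            np.asarray(pr["cls"], dtype=int)[sel],
            gt["boxes"], gt["cls"], iou_thr,
        )
        tp += res.tp
        fp += res.fp
        fn += res.fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def evaluate_detections(preds, gts, n_classes: int = 3,
                        conf_grid=None) -> EvalResult:
    """Full evaluation of per-image predictions against ground truth.

    ``preds``/``gts`` are parallel lists of dicts with keys ``boxes``
    (xyxy), ``scores`` (preds only) and ``cls``.  The reported P/R pair is
    taken at the confidence threshold maximizing F1 over ``conf_grid``.
    """
    aps50 = {}
    for c in range(n_classes):
        ap = _class_ap(preds, gts, c, 0.5)
        if ap is not None:
            aps50[c] = ap
    map50 = float(np.mean(list(aps50.values()))) if aps50 else 0.0
    maps = []
    for thr in np.arange(0.5, 0.96, 0.05):
        vals = [a for c in range(n_classes)
                if (a := _class_ap(preds, gts, c, thr)) is not None]
        maps.append(np.mean(vals) if vals else 0.0)
    map50_95 = float(np.mean(maps)) if maps else 0.0

    if conf_grid is None:
        conf_grid = np.arange(0.05, 0.96, 0.05)
    best = (0.0, 0.0, 0.0, 0.25)  # f1, p, r, conf
    for conf in conf_grid:
        p, r = _pr_at_threshold(preds, gts, conf)
        f1 = f1_score(p, r) if p + r else 0.0
        if f1 > best[0]:
            best = (f1, p, r, float(conf))
    return EvalResult(aps50, map50, map50_95, best[1], best[2], best[0], best[3])


def f1_score(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); accepts fractions or percentages (and
    returns the same scale).  Defined as 0 when P = R = 0."""
    if p == 0 and r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def measure_fps(model, input_size: int = 640, n_warmup: int = 3000,
                n_timed: int = 100, batch: int = 1) -> dict:
    """Median forward-pass throughput after warm-up.

    Returns frames/s with the measurement context (input size, batch,
    warm-up count).  Timing is hardware-dependent and is reported, never
    asserted.
    """
    if n_timed <= 0:
        raise ValueError("n_timed must be positive")
    from .nn.autograd import Tensor, no_grad

    model.eval()
    n_br = len(model.spec.branch_inputs)
    x = [Tensor(np.zeros((batch, 3, input_size, input_size), dtype=np.float32))
         for _ in range(n_br)]
    with no_grad():
        for _ in range(n_warmup):
            model(x)
        times = []
        for _ in range(n_timed):
            t0 = time.perf_counter()
            model(x)
            times.append(time.perf_counter() - t0)
    return {
        "fps": batch / float(np.median(times)),
        "input_size": input_size,
        "batch": batch,
        "n_warmup": n_warmup,
        "n_timed": n_timed,
    }
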