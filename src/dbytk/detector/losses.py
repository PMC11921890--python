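"""Detection losses: binary cross entropy, complete-IoU, distribution focal.

The composite objective is the weighted sum

    L = lambda_box * L_CIoU + lambda_cls * L_BCE + lambda_dfl * L_DFL

with default weights 7.5 / 0.5 / 1.5.  Logarithms default to base e (the
reference detector's convention); ``base=2`` evaluates the printed-formula
variant, which only rescales gradients by a constant.  Positive anchors are
chosen by task-aligned assignment (alignment metric s^alpha * IoU^beta over
anchors whose center lies inside a ground-truth box).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor

EPS_P = 1e-7  # probability clamp for the logarithms

DEFAULT_LOSS_WEIGHTS = {"box": 7.5, "cls": 0.5, "dfl": 1.5}


def _log(x, base):
    y = ag.log(x)
    return y * (1.0 / math.log(2.0)) if base == 2 else y


def loss_bce(p, q, base: str | int = "e"):
    """Elementwise binary cross entropy on probabilities.

    -(q log p + (1-q) log(1-p)); probabilities are clamped to
    [eps, 1-eps] with eps=1e-7.  ``base=2`` uses log2.
    """
    p = ag.clamp(p if isinstance(p, Tensor) else Tensor(p), EPS_P, 1.0 - EPS_P)
    q = q if isinstance(q, Tensor) else Tensor(q)
    out = -(q * _log(p, base) + (1.0 - q) * _log(1.0 - p, base))
    return out


def _pairwise_terms(pred, target):
    """Shared CIoU geometry for (N,4) xyxy boxes (autodiff on pred)."""
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx1, ty1, tx2, ty2 = target[:, 0], target[:, 1], target[:, 2], target[:, 3]
    eps = 1e-9
    pw, ph = px2 - px1, py2 - py1
    tw, th = tx2 - tx1, ty2 - ty1
    inter_w = ag.clamp(_minimum(px2, tx2) - _maximum(px1, tx1), 0.0, None)
    inter_h = ag.clamp(_minimum(py2, ty2) - _maximum(py1, ty1), 0.0, None)
    inter = inter_w * inter_h
    union = pw * ph + tw * th - inter + eps
    iou = inter / union
    # center distance over enclosing-box diagonal
    rho2 = ((px1 + px2) - (tx1 + tx2)) ** 2.0 / 4.0 \
        + ((py1 + py2) - (ty1 + ty2)) ** 2.0 / 4.0
    cw = _maximum(px2, tx2) - _minimum(px1, tx1)
    ch = _maximum(py2, ty2) - _minimum(py1, ty1)
    c2 = cw * cw + ch * ch + eps
    v = (4.0 / math.pi ** 2) * (
        ag.atan(tw / (th + eps)) - ag.atan(pw / (ph + eps))
    ) ** 2.0
    return iou, rho2, c2, v


def _maximum(a, b):
    # max(a,b) = a + relu(b - a), differentiable a.e.
    return a + ag.relu(b - a)


def _minimum(a, b):
    return a - ag.relu(a - b)


def ciou(pred, target):
    """Complete IoU of (N,4) xyxy boxes: IoU - rho^2/c^2 - alpha*v.

    ``alpha = v / ((1 - IoU) + v)`` is treated as a constant weight
    (evaluated on detached values), as in the reference implementation.
    """
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    target = target if isinstance(target, Tensor) else Tensor(target)
    iou, rho2, c2, v = _pairwise_terms(pred, target)
    alpha = v.data / ((1.0 - iou.data) + v.data + 1e-9)
    return iou - rho2 / c2 - Tensor(alpha) * v


def loss_ciou(pred, target):
    """1 - CIoU per box pair."""
    return 1.0 - ciou(pred, target)


def loss_dfl(dist_logits, target, base: str | int = "e"):
    """Distribution focal loss for one distance distribution.

    ``dist_logits``: Tensor (..., reg_max) of bin logits; ``target``:
    continuous values (...,) in bin units within [0, reg_max-1].  The two
    bins flanking each target are supervised with linear interpolation
    weights:  -((y_{i+1}-y) log S_i + (y-y_i) log S_{i+1}).
    """
    dist_logits = dist_logits if isinstance(dist_logits, Tensor) \
        else Tensor(dist_logits)
    reg_max = dist_logits.shape[-1]
    t = np.asarray(target, dtype=np.float64)
    tl = np.clip(np.floor(t), 0, reg_max - 2).astype(int)
    tr = tl + 1
    wl = (tr - t).astype(np.float32)
    wr = (t - tl).astype(np.float32)
    p = ag.softmax(dist_logits, axis=-1)
    logp = _log(ag.clamp(p, EPS_P, 1.0), base)
    idx = np.indices(tl.shape)
    left = logp[(*idx, tl)]
    right = logp[(*idx, tr)]
    return -(Tensor(wl) * left + Tensor(wr) * right)


def total_loss(box_loss, cls_loss, dfl_loss, weights=None):
    """Weighted sum of the three (already reduced) loss terms."""
    w = dict(DEFAULT_LOSS_WEIGHTS)
    if weights:
        w.update(weights)
    return w["box"] * box_loss + w["cls"] * cls_loss + w["dfl"] * dfl_loss


# ---------------------------------------------------------------------------
# task-aligned assignment (numpy; no gradients flow through the assignment)


def _pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (A,4) and (M,4) xyxy boxes."""
    ix = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2])
        - np.maximum(a[:, None, 0], b[None, :, 0]), 0.0, None
    )
    iy = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3])
        - np.maximum(a[:, None, 1], b[None, :, 1]), 0.0, None
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter + 1e-9)


@dataclasses.dataclass
class AssignResult:
    fg_mask: np.ndarray        # (A,) bool
    target_boxes: np.ndarray   # (A,4) xyxy (zeros at background)
    target_scores: np.ndarray  # (A, nc) soft labels
    assigned_gt: np.ndarray    # (A,) int, -1 at background


def assign_targets(scores, pred_boxes, anchors, gt_boxes, gt_cls,
                   topk: int = 10, alpha: float = 0.5,
                   beta: float = 6.0) -> AssignResult:
    """Task-aligned one-to-many assignment for one image.

    Candidates are anchors whose point lies inside a ground-truth box; per
    ground truth the ``topk`` candidates by alignment metric
    s^alpha * IoU^beta are kept; an anchor claimed by several ground truths
    goes to the one with the highest IoU.  Target class scores are the
    alignment metric normalized per ground truth and scaled by its best IoU.
    """
    A, nc = scores.shape
    M = len(gt_boxes)
    out = AssignResult(
        np.zeros(A, dtype=bool), np.zeros((A, 4), dtype=np.float32),
        np.zeros((A, nc), dtype=np.float32), np.full(A, -1, dtype=int),
    )
    if M == 0:
        return out
    inside = (
        (anchors[:, 0:1] > gt_boxes[None, :, 0])
        & (anchors[:, 0:1] < gt_boxes[None, :, 2])
        & (anchors[:, 1:2] > gt_boxes[None, :, 1])
        & (anchors[:, 1:2] < gt_boxes[None, :, 3])
    )  # (A, M)
    iou = _pairwise_iou(pred_boxes, gt_boxes)
    s = scores[:, gt_cls]  # (A, M)
    metric = (s ** alpha) * (iou ** beta) * inside
    cand = np.zeros_like(inside)
    k = min(topk, A)
    top = np.argsort(-metric, axis=0)[:k]  # (k, M)
    cand[top, np.arange(M)[None, :]] = True
    cand &= metric > 0
    # resolve conflicts by highest IoU
    claimed = cand.sum(axis=1)
    multi = claimed > 1
    if multi.any():
        best = iou.argmax(axis=1)
        fix = np.zeros_like(cand)
        fix[np.arange(A)[multi], best[multi]] = True
        cand[multi] = fix[multi]
    fg = cand.any(axis=1)
    gt_idx = cand.argmax(axis=1)
    out.fg_mask = fg
    out.assigned_gt[fg] = gt_idx[fg]
    out.target_boxes[fg] = gt_boxes[gt_idx[fg]]
    # normalized soft class targets
    metric_c = metric * cand
    max_metric = metric_c.max(axis=0) + 1e-9  # per gt
    max_iou = (iou * cand).max(axis=0)
    t = metric_c[fg, gt_idx[fg]] / max_metric[gt_idx[fg]] * max_iou[gt_idx[fg]]
    out.target_scores[fg, gt_cls[gt_idx[fg]]] = t.astype(np.float32)
    return out
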