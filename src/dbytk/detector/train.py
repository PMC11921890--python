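"""Training and inference for the detector.

Anchor-free decoding: every cell of the three feature maps is an anchor
point at its center; the head predicts, per point, a discrete distribution
over ``reg_max`` bins for each of the four box-edge distances (in stride
units) and independent per-class logits.  Training uses task-aligned
assignment and the composite CIoU + BCE + DFL objective; inference decodes
the distribution means and applies class-wise non-maximum suppression.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.optim import Adam
from . import losses as L
from .model import Detector

BRANCH_IMAGES = {"rgb": "rgb", "dcs": "dcs", "pcc": "pcc"}


def make_anchors(imgsz: tuple[int, int], strides) -> tuple[np.ndarray, np.ndarray]:
    """Anchor-point centers (pixels) and per-anchor strides for all scales."""
    h, w = imgsz
    pts, sts = [], []
    for s in strides:
        ys, xs = np.meshgrid(
            (np.arange(h // s) + 0.5) * s, (np.arange(w // s) + 0.5) * s,
            indexing="ij",
        )
        pts.append(np.stack([xs.ravel(), ys.ravel()], axis=1))
        sts.append(np.full(xs.size, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(sts)


def scene_inputs(scene, branch_inputs) -> list[np.ndarray]:
    """Stack the requested image modalities of a scene as NCHW float arrays."""
    out = []
    for name in branch_inputs:
        img = getattr(scene, BRANCH_IMAGES[name], None)
        if img is None:
            raise ValueError(f"scene {scene.scene_id!r} lacks a {name!r} image")
        out.append(np.transpose(img.astype(np.float32) / 255.0, (2, 0, 1)))
    return out


def scene_targets(scene) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (M,4) xyxy pixel boxes and (M,) class ids."""
    h, w = scene.height, scene.width
    boxes = np.array(
        [
            [b.cx * w - b.w * w / 2, b.cy * h - b.h * h / 2,
             b.cx * w + b.w * w / 2, b.cy * h + b.h * h / 2]
            for b in scene.boxes
        ],
        dtype=np.float64,
    ).reshape(-1, 4)
    cls = np.array([b.class_id for b in scene.boxes], dtype=int)
    return boxes, cls


def _flatten_head(outputs):
    """Concatenate per-scale head outputs to (N, 4*reg_max, A), (N, nc, A)."""
    box, cls = [], []
    for b, c in outputs:
        n, cb, h, w = b.shape
        box.append(ag.reshape(b, (n, cb, h * w)))
        cls.append(ag.reshape(c, (n, c.shape[1], h * w)))
    return ag.concat(box, axis=2), ag.concat(cls, axis=2)


@dataclasses.dataclass
class TrainLog:
    iterations: list = dataclasses.field(default_factory=list)
    total: list = dataclasses.field(default_factory=list)
    box: list = dataclasses.field(default_factory=list)
    cls: list = dataclasses.field(default_factory=list)
    dfl: list = dataclasses.field(default_factory=list)


class DetectionTrainer:
    """Minimal deterministic trainer (Adam, fixed learning rate)."""

    def __init__(self, model: Detector, lr: float = 3e-3,
                 loss_weights=None, seed: int = 0):
        self.model = model
        self.spec = model.spec
        self.base_lr = lr
        self.optimizer = Adam(model.parameters(), lr=lr)
        self.loss_weights = loss_weights
        self.rng = np.random.default_rng(seed)
        self.log = TrainLog()

    # -- loss ------------------------------------------------------------
    def compute_loss(self, scenes):
        """Composite loss over a batch of same-size scenes."""
        spec = self.spec
        xs = [np.stack(arrs) for arrs in zip(
            *[scene_inputs(s, spec.branch_inputs) for s in scenes]
        )]
        imgsz = xs[0].shape[2:]
        anchors, strides = make_anchors(imgsz, spec.strides)
        outputs = self.model([Tensor(x) for x in xs])
        box_logits, cls_logits = _flatten_head(outputs)
        n, _, A = box_logits.shape
        reg_max = spec.reg_max
        dist = self.model.head.dfl(box_logits)          # (N, 4, A) bin units
        cls_prob = ag.sigmoid(cls_logits)               # (N, nc, A)

        sx = Tensor(strides.astype(np.float32))
        ax = Tensor(anchors[:, 0].astype(np.float32))
        ay = Tensor(anchors[:, 1].astype(np.float32))

        box_terms, dfl_terms, weights = [], [], []
        cls_losses = []
        total_pos_score = 0.0
        for i in range(n):
            pb = _decode_boxes(dist.data[i], anchors, strides)
            res = L.assign_targets(
                np.ascontiguousarray(cls_prob.data[i].T), pb, anchors,
                *scene_targets(scenes[i]),
            )
            ts = Tensor(res.target_scores.T)            # (nc, A)
            cls_losses.append(ag.sum_(L.loss_bce(cls_prob[i], ts)))
            total_pos_score += float(res.target_scores.sum())
            fg = np.nonzero(res.fg_mask)[0]
            if fg.size == 0:
                continue
            w_i = res.target_scores[fg].sum(axis=1).astype(np.float32)
            tb = res.target_boxes[fg]
            # decoded predicted boxes for the positives (with gradients)
            l_, t_, r_, b_ = (dist[i, 0, fg], dist[i, 1, fg],
                              dist[i, 2, fg], dist[i, 3, fg])
            sfg, axf, ayf = sx[fg], ax[fg], ay[fg]
            pred = ag.stack(
                [axf - l_ * sfg, ayf - t_ * sfg, axf + r_ * sfg, ayf + b_ * sfg],
                axis=1,
            )
            box_terms.append(L.loss_ciou(pred, Tensor(tb)) * Tensor(w_i))
            # DFL on the four edge distances in bin units
            tgt = np.stack(
                [
                    (anchors[fg, 0] - tb[:, 0]) / strides[fg],
                    (anchors[fg, 1] - tb[:, 1]) / strides[fg],
                    (tb[:, 2] - anchors[fg, 0]) / strides[fg],
                    (tb[:, 3] - anchors[fg, 1]) / strides[fg],
                ],
                axis=1,
            ).clip(0, reg_max - 1 - 1e-3)
            logits_fg = ag.transpose(
                ag.reshape(box_logits[i][:, fg], (4, reg_max, fg.size)),
                (0, 2, 1),
            )  # (4, n_fg, reg_max)
            dfl_terms.append(
                ag.sum_(L.loss_dfl(logits_fg, tgt.T) * Tensor(w_i))
            )
            weights.append(w_i)

        denom = max(total_pos_score, 1.0)
        cls_loss = sum(cls_losses[1:], cls_losses[0]) * (1.0 / denom)
        if box_terms:
            box_loss = sum(
                (ag.sum_(t) for t in box_terms[1:]), ag.sum_(box_terms[0])
            ) * (1.0 / denom)
            dfl_loss = sum(dfl_terms[1:], dfl_terms[0]) * (1.0 / (denom * 4.0))
        else:
            box_loss = Tensor(0.0)
            dfl_loss = Tensor(0.0)
        total = L.total_loss(box_loss, cls_loss, dfl_loss, self.loss_weights)
        return total, {
            "box": float(box_loss.data),
            "cls": float(cls_loss.data),
            "dfl": float(dfl_loss.data),
        }

    # -- loop ------------------------------------------------------------
    def fit(self, scenes, iterations: int, batch_size: int = 4,
            schedule: str = "cosine", warmup: int = 20,
            verbose: bool = False):
        """Train for ``iterations`` optimizer steps.

        ``schedule="cosine"`` applies linear warm-up over ``warmup`` steps
        followed by cosine decay of the base learning rate to zero;
        ``schedule="constant"`` keeps the base rate.
        """
        import math as _math

        self.model.train()
        base_lr = self.base_lr
        scenes = list(scenes)
        for it in range(iterations):
            if schedule == "cosine":
                lr = base_lr * min(1.0, (it + 1) / max(warmup, 1))
                if it >= warmup:
                    lr *= 0.5 * (1 + _math.cos(_math.pi * it / iterations))
                self.optimizer.lr = lr
            idx = self.rng.choice(len(scenes), size=min(batch_size, len(scenes)),
                                  replace=False)
            batch = [scenes[i] for i in idx]
            self.optimizer.zero_grad()
            total, parts = self.compute_loss(batch)
            total.backward()
            self.optimizer.step()
            self.log.iterations.append(it)
            self.log.total.append(float(total.data))
            self.log.box.append(parts["box"])
            self.log.cls.append(parts["cls"])
            self.log.dfl.append(parts["dfl"])
            if verbose and (it % 10 == 0 or it == iterations - 1):
                print(f"iter {it:4d}  loss {float(total.data):.4f}  "
                      f"box {parts['box']:.3f} cls {parts['cls']:.3f} "
                      f"dfl {parts['dfl']:.3f}")
        return self.log


def _decode_boxes(dist: np.ndarray, anchors: np.ndarray,
                  strides: np.ndarray) -> np.ndarray:
    """(4, A) distances in stride units -> (A, 4) xyxy pixel boxes."""
    lt = anchors - (dist[:2] * strides).T
    rb = anchors + (dist[2:] * strides).T
    return np.concatenate([lt, rb], axis=1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.7) -> list[int]:
    """Greedy class-agnostic non-maximum suppression; returns kept indices."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        iou = L._pairwise_iou(boxes[rest], boxes[i:i + 1])[:, 0]
        order = rest[iou <= iou_thr]
    return keep


@dataclasses.dataclass
class Detection:
    box: np.ndarray   # xyxy pixels
    score: float
    class_id: int


def predict_scene(model: Detector, scene, conf: float = 0.25,
                  iou_thr: float = 0.7, max_det: int = 300) -> list[Detection]:
    """Run the detector on one scene and return NMS-filtered detections."""
    model.eval()
    xs = [x[None] for x in scene_inputs(scene, model.spec.branch_inputs)]
    with ag.no_grad():
        outputs = model([Tensor(x) for x in xs])
        box_logits, cls_logits = _flatten_head(outputs)
    anchors, strides = make_anchors(xs[0].shape[2:], model.spec.strides)
    dist = model.head.dfl.decode_numpy(box_logits.data)[0]
    boxes = _decode_boxes(dist, anchors, strides)
    probs = 1.0 / (1.0 + np.exp(-cls_logits.data[0]))  # (nc, A)
    cls_id = probs.argmax(axis=0)
    score = probs.max(axis=0)
    sel = score >= conf
    boxes, score, cls_id = boxes[sel], score[sel], cls_id[sel]
    dets: list[Detection] = []
    for c in np.unique(cls_id):
        m = cls_id == c
        for k in nms(boxes[m], score[m], iou_thr):
            dets.append(Detection(boxes[m][k], float(score[m][k]), int(c)))
    dets.sort(key=lambda d: -d.score)
    return dets[:max_det]
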