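"""Dataset augmentation: clockwise rotations, background-occlusion overlay,
and assembly of the x3 augmented dataset.

Each original scene is rotated clockwise by 90, 180 and 270 degrees; two of
the three rotated variants (chosen at random per scene, but identically for
all image modalities of that scene) are joined with the original, tripling
both the image and the box counts — 1,000 scenes with 4,203 boxes become
3,000 scenes with 12,609 boxes.  A background patch cut from a box-free
region may additionally be pasted over part of a box to emulate occlusion
by tobacco leaves; a box is dropped only if its visible fraction falls
below a threshold.  Augmentation is applied after the train/val/test split,
within each split, so no variant of a held-out scene can leak into training.
"""

from __future__ import annotations

import copy
import dataclasses
import logging

import numpy as np

from .cube import AnnotatedScene, BoundingBox, SpectralCube

logger = logging.getLogger(__name__)

_VALID_ANGLES = (90, 180, 270)


@dataclasses.dataclass
class AugmentationPlan:
    """How to augment each scene.

    ``pick`` augmented variants (default 2) join each original.  When
    ``overlay`` is on, each variant independently receives a background
    overlay with probability ``overlay_prob``; boxes whose visible fraction
    drops below ``keep_fraction_threshold`` are dropped.
    """

    rotations: tuple[int, ...] = _VALID_ANGLES
    overlay: bool = False
    overlay_prob: float = 0.5
    keep_fraction_threshold: float = 0.3
    pick: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a not in _VALID_ANGLES for a in self.rotations):
            raise ValueError(f"rotations must be from {_VALID_ANGLES}")
        if self.pick > len(self.rotations):
            raise ValueError("pick cannot exceed the number of rotations")


def _rot_box(box: BoundingBox, angle: int) -> BoundingBox:
    cx, cy, w, h = box.cx, box.cy, box.w, box.h
    if angle == 90:      # clockwise
        cx, cy, w, h = 1.0 - cy, cx, h, w
    elif angle == 180:
        cx, cy = 1.0 - cx, 1.0 - cy
    elif angle == 270:
        cx, cy, w, h = cy, 1.0 - cx, h, w
    else:
        raise ValueError(f"angle must be one of {_VALID_ANGLES}, got {angle}")
    return BoundingBox(box.class_id, cx, cy, w, h)


def _rot_plane(arr: np.ndarray, angle: int) -> np.ndarray:
    # np.rot90 with k=-1 is a clockwise quarter turn of axes (0, 1)
    k = {90: -1, 180: 2, 270: 1}[angle]
    return np.ascontiguousarray(np.rot90(arr, k=k, axes=(0, 1)))


def rotate_scene(scene: AnnotatedScene, angle: int) -> AnnotatedScene:
    """Rotate all image planes and boxes of a scene clockwise by ``angle``."""
    if angle not in _VALID_ANGLES:
        raise ValueError(f"angle must be one of {_VALID_ANGLES}, got {angle}")
    out = copy.copy(scene)
    out.rgb = _rot_plane(scene.rgb, angle)
    if scene.dcs is not None:
        out.dcs = _rot_plane(scene.dcs, angle)
    if getattr(scene, "pcc", None) is not None:
        out.pcc = _rot_plane(scene.pcc, angle)
    if scene.cube is not None:
        out.cube = SpectralCube(
            _rot_plane(scene.cube.data, angle), scene.cube.wavelengths.copy()
        )
    if scene.label_map is not None:
        out.label_map = _rot_plane(scene.label_map, angle)
    out.boxes = [_rot_box(b, angle) for b in scene.boxes]
    return out


def _boxes_px(scene: AnnotatedScene) -> list[tuple[int, int, int, int]]:
    return [b.to_pixels(scene.height, scene.width) for b in scene.boxes]


def _rect_overlap(a, b) -> int:
    ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    return ix * iy


def occlusion_overlay(
    scene: AnnotatedScene,
    rng: np.random.Generator,
    keep_fraction_threshold: float = 0.3,
    area_frac: tuple[float, float] = (0.2, 0.6),
    max_tries: int = 200,
) -> AnnotatedScene:
    """Paste a background patch over part of a random box.

    The patch is cut from a rectangular region free of any box (found by
    rejection sampling; if none is found in ``max_tries`` the scene is
    returned unmodified with a warning) and covers a random sub-rectangle of
    20-60% of the chosen box's area.  Boxes whose visible fraction drops
    below ``keep_fraction_threshold`` are dropped; all others keep their
    coordinates unchanged.
    """
    if not scene.boxes:
        raise ValueError("scene has no boxes to occlude")
    h, w = scene.height, scene.width
    boxes_px = _boxes_px(scene)

    # target: a sub-rectangle of a randomly chosen box
    bi = int(rng.integers(len(boxes_px)))
    x1, y1, x2, y2 = boxes_px[bi]
    bw, bh = max(x2 - x1, 1), max(y2 - y1, 1)
    frac = float(rng.uniform(*area_frac))
    # random aspect split of the area fraction between the two axes
    fx = float(np.sqrt(frac) * rng.uniform(0.8, 1.25))
    fx = min(fx, 1.0)
    fy = min(frac / fx, 1.0)
    pw, ph = max(1, int(round(bw * fx))), max(1, int(round(bh * fy)))
    px = int(rng.integers(x1, max(x1, x2 - pw) + 1))
    py = int(rng.integers(y1, max(y1, y2 - ph) + 1))

    # source: same-size patch from a box-free region
    src = None
    for _ in range(max_tries):
        sx = int(rng.integers(0, w - pw + 1))
        sy = int(rng.integers(0, h - ph + 1))
        rect = (sx, sy, sx + pw, sy + ph)
        if all(_rect_overlap(rect, b) == 0 for b in boxes_px):
            src = (sx, sy)
            break
    if src is None:
        logger.warning(
            "no box-free region of %dx%d found in %d tries; scene %s unmodified",
            pw, ph, max_tries, scene.scene_id,
        )
        return scene

    out = copy.copy(scene)
    sx, sy = src

    def paste(arr):
        arr = arr.copy()
        arr[py:py + ph, px:px + pw, ...] = arr[sy:sy + ph, sx:sx + pw, ...]
        return arr

    out.rgb = paste(scene.rgb)
    if scene.dcs is not None:
        out.dcs = paste(scene.dcs)
    if getattr(scene, "pcc", None) is not None:
        out.pcc = paste(scene.pcc)
    if scene.cube is not None:
        out.cube = SpectralCube(paste(scene.cube.data), scene.cube.wavelengths.copy())

    patch_rect = (px, py, px + pw, py + ph)
    kept = []
    for box, bpx in zip(scene.boxes, boxes_px):
        area = max((bpx[2] - bpx[0]) * (bpx[3] - bpx[1]), 1)
        visible = 1.0 - _rect_overlap(patch_rect, bpx) / area
        if visible >= keep_fraction_threshold:
            kept.append(box)
    out.boxes = kept
    return out


def build_tobacco3000(scenes, plan: AugmentationPlan) -> list[AnnotatedScene]:
    """Assemble the x(1 + pick) augmented dataset from pre-split scenes.

    Each scene contributes itself plus ``plan.pick`` rotated variants chosen
    at random with the plan seed.  With pick=2 and overlay disabled this
    exactly triples both scene and box counts per split.  Variants inherit
    ``source_id`` and ``split_tag`` from their original, and since rotation
    applies to every image modality stored on the scene, RGB/PCC/DCS stay
    paired under identical choices.
    """
    rng = np.random.default_rng(plan.seed)
    out: list[AnnotatedScene] = []
    for scene in scenes:
        out.append(scene)
        chosen = rng.choice(len(plan.rotations), size=plan.pick, replace=False)
        for j in sorted(int(c) for c in chosen):
            angle = plan.rotations[j]
            var = rotate_scene(scene, angle)
            var.scene_id = f"{scene.scene_id}_rot{angle}"
            var.source_id = scene.source_id or scene.scene_id
            if plan.overlay and var.boxes and rng.uniform() < plan.overlay_prob:
                var = occlusion_overlay(
                    var, rng, keep_fraction_threshold=plan.keep_fraction_threshold
                )
            out.append(var)
    return out


def count_boxes(scenes) -> int:
    return sum(len(s.boxes) for s in scenes)
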