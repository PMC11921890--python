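"""Rotations, occlusion overlay, and the x3 dataset assembly."""

import copy

import numpy as np
import pytest

from dbytk.augment import (
    AugmentationPlan,
    build_tobacco3000,
    count_boxes,
    occlusion_overlay,
    rotate_scene,
)
from dbytk.cube import AnnotatedScene, BoundingBox
from dbytk.synth import make_dataset


def _scene_with_boxes(boxes, size=32, split="train", sid="s0"):
    rng = np.random.default_rng(0)
    return AnnotatedScene(
        rgb=rng.integers(0, 255, size=(size, size, 3), dtype=np.uint8),
        boxes=boxes, split_tag=split, scene_id=sid,
    )


class TestRotation:
    def test_90cw_box_mapping(self):
        s = _scene_with_boxes([BoundingBox(0, 0.25, 0.5, 0.2, 0.1)])
        (b,) = rotate_scene(s, 90).boxes
        assert (b.cx, b.cy, b.w, b.h) == (0.5, 0.25, 0.1, 0.2)

    def test_180_fixes_centered_box(self):
        s = _scene_with_boxes([BoundingBox(1, 0.5, 0.5, 0.3, 0.12)])
        (b,) = rotate_scene(s, 180).boxes
        assert (b.cx, b.cy, b.w, b.h) == (0.5, 0.5, 0.3, 0.12)

    def test_four_quarter_turns_identity(self, small_scene):
        s = small_scene
        for _ in range(4):
            s = rotate_scene(s, 90)
        assert np.array_equal(s.rgb, small_scene.rgb)
        assert np.array_equal(s.cube.data, small_scene.cube.data)
        for a, b in zip(s.boxes, small_scene.boxes):
            np.testing.assert_allclose(
                [a.cx, a.cy, a.w, a.h], [b.cx, b.cy, b.w, b.h], atol=1e-12
            )

    def test_images_rotate_consistently_with_boxes(self, small_scene):
        rot = rotate_scene(small_scene, 90)
        h, w = small_scene.rgb.shape[:2]
        for obj, b in zip(small_scene.objects, rot.boxes):
            m = np.ascontiguousarray(np.rot90(obj.mask, k=-1))
            ys, xs = np.nonzero(m)
            x1, y1, x2, y2 = b.to_pixels(*m.shape)
            assert (x1, y1) == (xs.min(), ys.min())
            assert (x2, y2) == (xs.max() + 1, ys.max() + 1)

    def test_invalid_angle_rejected(self, small_scene):
        with pytest.raises(ValueError):
            rotate_scene(small_scene, 45)


class _FixedRng:
    """Deterministic stand-in for the overlay's random draws."""

    def __init__(self, uniforms, integers):
        self._u = list(uniforms)
        self._i = list(integers)

    def uniform(self, *a, **k):
        return self._u.pop(0)

    def integers(self, *a, **k):
        return self._i.pop(0)


class TestOcclusionOverlay:
    def test_full_cover_drops_box(self):
        box = BoundingBox(0, 0.5, 0.5, 0.25, 0.25)
        s = _scene_with_boxes([box], size=64)
        # choose box 0; cover 100% of its area (frac=1.0 via area_frac);
        # patch position at box corner; source at (0, 0) is box-free
        rng = _FixedRng(uniforms=[1.0, 1.0], integers=[0, 24, 24, 0, 0])
        out = occlusion_overlay(s, rng, keep_fraction_threshold=0.3,
                                area_frac=(1.0, 1.0))
        assert out.boxes == []

    def test_partial_cover_keeps_box_unchanged(self):
        box = BoundingBox(0, 0.5, 0.5, 0.25, 0.25)
        s = _scene_with_boxes([box], size=64)
        rng = _FixedRng(uniforms=[0.4, 1.0], integers=[0, 24, 24, 0, 0])
        out = occlusion_overlay(s, rng, keep_fraction_threshold=0.3,
                                area_frac=(0.4, 0.4))
        assert len(out.boxes) == 1
        b = out.boxes[0]
        assert (b.cx, b.cy, b.w, b.h) == (box.cx, box.cy, box.w, box.h)

    def test_seeded_overlay_deterministic(self, small_scene):
        a = occlusion_overlay(copy.copy(small_scene), np.random.default_rng(9))
        b = occlusion_overlay(copy.copy(small_scene), np.random.default_rng(9))
        assert np.array_equal(a.rgb, b.rgb)
        assert len(a.boxes) == len(b.boxes)

    def test_no_free_region_returns_scene_unchanged(self, caplog):
        # one box covering the whole frame leaves nowhere to cut from
        s = _scene_with_boxes([BoundingBox(0, 0.5, 0.5, 1.0, 1.0)], size=16)
        out = occlusion_overlay(s, np.random.default_rng(0))
        assert out is s


class TestBuildDataset:
    def test_small_exact_tripling(self):
        scenes = make_dataset(10, seed=4, total_boxes=7, height=48, width=48,
                              spectral=False, n_leaves=2,
                              size_range=(0.1, 0.2))
        assert count_boxes(scenes) == 7
        out = build_tobacco3000(scenes, AugmentationPlan(pick=2, seed=0))
        assert len(out) == 30
        assert count_boxes(out) == 21

    def test_split_membership_preserved(self):
        scenes = make_dataset(10, seed=4, total_boxes=20, height=48, width=48,
                              spectral=False, n_leaves=2,
                              size_range=(0.1, 0.2))
        out = build_tobacco3000(scenes, AugmentationPlan(pick=2, seed=0))
        sizes = {t: sum(s.split_tag == t for s in out)
                 for t in ("train", "val", "test")}
        assert sizes == {"train": 18, "val": 6, "test": 6}

    def test_no_cross_split_leakage(self):
        scenes = make_dataset(10, seed=4, total_boxes=20, height=48, width=48,
                              spectral=False, n_leaves=2,
                              size_range=(0.1, 0.2))
        split_of_source = {s.scene_id: s.split_tag for s in scenes}
        out = build_tobacco3000(scenes, AugmentationPlan(pick=2, seed=0))
        for s in out:
            assert s.split_tag == split_of_source[s.source_id]

    def test_class_proportions_invariant_under_rotation(self):
        scenes = make_dataset(12, seed=5, total_boxes=36, height=48, width=48,
                              spectral=False, n_leaves=2,
                              size_range=(0.1, 0.2))

        def per_class(ss):
            c = [0, 0, 0]
            for s in ss:
                for b in s.boxes:
                    c[b.class_id] += 1
            return c

        out = build_tobacco3000(scenes, AugmentationPlan(pick=2, seed=1))
        assert per_class(out) == [3 * c for c in per_class(scenes)]

    def test_pick_cannot_exceed_rotations(self):
        with pytest.raises(ValueError):
            AugmentationPlan(rotations=(90, 180), pick=3)
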