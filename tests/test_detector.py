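"""Detector architecture, blocks, losses and accounting."""

import math

import numpy as np
import pytest

from dbytk.detector import (
    ModelSpec,
    build_model,
    count_flops,
    count_parameters,
)
from dbytk.detector.blocks import BiFPNFusion, C2f_EL, MBModule, channel_shuffle
from dbytk.detector.losses import (
    assign_targets,
    ciou,
    loss_bce,
    loss_ciou,
    loss_dfl,
    total_loss,
)
from dbytk.nn import autograd as ag
from dbytk.nn.autograd import Tensor


class TestChannelShuffle:
    def test_six_channels_two_groups(self):
        x = Tensor(np.arange(6, dtype=np.float32).reshape(1, 6, 1, 1))
        y = channel_shuffle(x, 2).data.reshape(-1)
        assert y.tolist() == [0, 3, 1, 4, 2, 5]


class TestMBModule:
    def test_shape_preserved(self):
        m = MBModule(12, kernels=(3, 5, 7), groups=2,
                     rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(2, 12, 8, 8)))
        assert m(x).shape == (2, 12, 8, 8)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3\\*groups"):
            MBModule(10, groups=2)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            MBModule(12, kernels=(3, 4, 7))


class TestC2fEL:
    def test_identity_inner_block_reduces_to_plain_split_concat_fuse(self):
        # zeroing the MB fuse conv makes the residual inner block an
        # identity, so the module must equal the bare C2f data path
        # computed by hand from its own cv1/cv2
        rng = np.random.default_rng(0)
        m = C2f_EL(8, 8, n=1, hidden=6, kernels=(3, 3, 5), groups=2, rng=rng)
        m.m[0].mb.fuse.conv.weight.data[:] = 0.0
        m.eval()
        x = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        y = m(x).data
        h = m.c
        mid = m.cv1(x)
        ys = [mid[:, :h], mid[:, h:], mid[:, h:]]
        ref = m.cv2(ag.concat(ys, axis=1)).data
        np.testing.assert_allclose(y, ref, atol=1e-6)

    def test_spatial_size_preserved(self):
        m = C2f_EL(8, 16, n=2, hidden=6, kernels=(3, 5, 7), groups=2,
                   rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 8, 10, 10)))
        assert m(x).shape == (1, 16, 10, 10)

    def test_gradient_reaches_every_depthwise_kernel(self):
        rng = np.random.default_rng(2)
        m = C2f_EL(6, 6, n=1, hidden=6, kernels=(3, 5, 7), groups=2, rng=rng)
        x = Tensor(rng.normal(size=(2, 6, 8, 8)))
        loss = ag.sum_(m(x) ** 2.0)
        loss.backward()
        for name, p in m.named_parameters():
            assert p.grad is not None, name
            assert np.abs(p.grad).sum() > 0, name


class TestBiFPNFusion:
    def test_equal_weights_give_mean(self):
        f = BiFPNFusion(3)
        xs = [Tensor(np.full((1, 2, 2, 2), v)) for v in (1.0, 2.0, 6.0)]
        out = f(xs).data
        np.testing.assert_allclose(out, 3.0, atol=1e-3)

    def test_one_hot_weight_passes_input_through(self):
        f = BiFPNFusion(2)
        f.weights.data[:] = [1.0, 0.0]
        a = Tensor(np.random.default_rng(0).normal(size=(1, 2, 2, 2)))
        b = Tensor(np.random.default_rng(1).normal(size=(1, 2, 2, 2)))
        np.testing.assert_allclose(f([a, b]).data, a.data, atol=2e-4)

    def test_rectifier_clamps_negative_raw_weights(self):
        f = BiFPNFusion(2)
        f.weights.data[:] = [-3.0, 2.0]
        w = f.fusion_weights()
        assert np.all(w >= 0)
        assert w[0] == 0.0 and w[1] == pytest.approx(1.0, abs=1e-3)


class TestArchitecture:
    def test_output_scales_stride_arithmetic(self):
        spec = ModelSpec.tiny()
        m = build_model(spec, seed=0)
        xs = [Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
              for _ in spec.branch_inputs]
        out = m(xs)
        sizes = [b.shape[2:] for b, _ in out]
        assert sizes == [(8, 8), (4, 4), (2, 2)]

    def test_input_not_divisible_by_32_rejected(self):
        spec = ModelSpec.tiny(dual=False)
        m = build_model(spec, seed=0)
        with pytest.raises(ValueError, match="divisible by 32"):
            m(Tensor(np.zeros((1, 3, 60, 60), dtype=np.float32)))

    def test_forward_deterministic_in_eval(self):
        spec = ModelSpec.tiny(dual=False)
        m = build_model(spec, seed=0)
        m.eval()
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64),
                                                   dtype=np.float32))
        with ag.no_grad():
            a = m(x)
            b = m(x)
        for (b1, c1), (b2, c2) in zip(a, b):
            assert np.array_equal(b1.data, b2.data)
            assert np.array_equal(c1.data, c2.data)

    def test_single_branch_baseline_parameter_count(self):
        m = build_model(ModelSpec.yolov8n_baseline(n_classes=3))
        assert count_parameters(m) == 3_011_433

    def test_flops_scale_quadratically_with_input(self):
        m = build_model(ModelSpec.tiny(dual=False))
        f1 = count_flops(m, 64)
        f2 = count_flops(m, 128)
        assert f2 == pytest.approx(4 * f1, rel=1e-9)
        assert count_parameters(m) == count_parameters(m)  # size-independent

    def test_wsum_branch_fusion_variant_builds(self):
        spec = ModelSpec.tiny()
        spec = type(spec)(**{**spec.__dict__, "fusion": "wsum"})
        m = build_model(spec, seed=0)
        xs = [Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32))
              for _ in spec.branch_inputs]
        out = m(xs)
        assert len(out) == 3


class TestLosses:
    def test_bce_printed_formula_example(self):
        # q=1, p=0.5 -> -log2(0.5) = 1 exactly in the base-2 variant
        val = float(loss_bce(Tensor(np.array(0.5)), Tensor(np.array(1.0)),
                             base=2).data)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_bce_probability_clamp(self):
        val = float(loss_bce(Tensor(np.array(1.0)), Tensor(np.array(0.0))).data)
        assert np.isfinite(val)

    def test_ciou_of_box_with_itself_is_one(self):
        box = np.array([[10.0, 20.0, 50.0, 80.0]])
        assert float(ciou(box, box).data[0]) == pytest.approx(1.0, abs=1e-6)
        assert float(loss_ciou(box, box).data[0]) == pytest.approx(0.0,
                                                                   abs=1e-6)

    def test_ciou_penalizes_center_offset_beyond_iou(self):
        a = np.array([[0.0, 0.0, 10.0, 10.0]])
        b = np.array([[20.0, 20.0, 30.0, 30.0]])  # disjoint, same shape
        c = np.array([[40.0, 40.0, 50.0, 50.0]])  # disjoint, farther away
        l_near = float(loss_ciou(a, b).data[0])
        l_far = float(loss_ciou(a, c).data[0])
        assert 0 < l_near < l_far <= 2.0 + 1e-6

    def test_aspect_term_matches_formula(self):
        a = np.array([[0.0, 0.0, 20.0, 10.0]])   # 2:1
        b = np.array([[0.0, 0.0, 10.0, 20.0]])   # 1:2, same corner
        got = float(ciou(a, b).data[0])
        # direct evaluation of the definition
        iou = 100.0 / (200 + 200 - 100)
        v = 4 / math.pi**2 * (math.atan(10 / 20) - math.atan(20 / 10)) ** 2
        alpha = v / ((1 - iou) + v)
        rho2 = 5.0**2 + 5.0**2
        c2 = 20.0**2 + 20.0**2
        assert got == pytest.approx(iou - rho2 / c2 - alpha * v, abs=1e-5)

    def test_dfl_zero_when_target_on_bin_with_full_mass(self):
        logits = np.full((1, 8), -20.0)
        logits[0, 3] = 20.0
        val = float(loss_dfl(Tensor(logits), np.array([3.0])).data[0])
        assert val == pytest.approx(0.0, abs=1e-4)

    def test_dfl_interpolates_flanking_bins(self):
        # uniform distribution, y = 2.5 -> -(0.5 log S2 + 0.5 log S3)
        logits = np.zeros((1, 8))
        val = float(loss_dfl(Tensor(logits), np.array([2.5])).data[0])
        assert val == pytest.approx(-math.log(1 / 8), abs=1e-5)

    def test_total_loss_weighted_sum(self):
        t = total_loss(Tensor(np.array(1.0)), Tensor(np.array(2.0)),
                       Tensor(np.array(3.0)))
        assert float(t.data) == pytest.approx(7.5 * 1 + 0.5 * 2 + 1.5 * 3)


class TestAssignment:
    def test_single_gt_gets_positive_anchors(self):
        rng = np.random.default_rng(0)
        anchors = np.stack(np.meshgrid(np.arange(4.0, 64, 8),
                                       np.arange(4.0, 64, 8)),
                           axis=-1).reshape(-1, 2)
        gt = np.array([[16.0, 16.0, 48.0, 48.0]])
        scores = np.full((len(anchors), 3), 0.5)
        boxes = np.tile(np.array([[14.0, 14.0, 50.0, 50.0]]),
                        (len(anchors), 1))
        res = assign_targets(scores, boxes, anchors, gt, np.array([1]))
        assert res.fg_mask.sum() > 0
        assert np.all(res.assigned_gt[res.fg_mask] == 0)
        assert np.all(res.target_scores[res.fg_mask, 1] > 0)
        assert res.target_scores[~res.fg_mask].sum() == 0

    def test_no_gt_means_no_positives(self):
        anchors = np.zeros((4, 2))
        res = assign_targets(np.zeros((4, 3)), np.zeros((4, 4)), anchors,
                             np.zeros((0, 4)), np.zeros(0, dtype=int))
        assert not res.fg_mask.any()
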