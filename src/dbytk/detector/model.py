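"""Backbone, necks and the assembled detector.

The backbone is the standard small anchor-free layout (stem + staged
C2f blocks + SPPF) exposing stride-8/16/32 features.  The single-branch
baseline pairs it with a PAN neck; the dual-branch model runs one backbone
per input modality (RGB and DCS), merges the two branches per scale by
channel concatenation + pointwise reduction, and fuses scales with the
BELFPN neck (BiFPN-weighted multi-input nodes followed by C2f_EL blocks).
"""

from __future__ import annotations

import numpy as np

from ..nn import autograd as ag
from ..nn.layers import ConvModule, MaxPool2d, Module, Upsample2x
from .blocks import BiFPNFusion, C2f, C2f_EL, Detect, SPPF
from .spec import ModelSpec


class Backbone(Module):
    """Stem + four stages; returns (P3, P4, P5) features."""

    def __init__(self, spec: ModelSpec, rng):
        super().__init__()
        c = spec.channels
        d = spec.depths
        self.stem = ConvModule(3, c[0], 3, 2, rng=rng)
        self.down1 = ConvModule(c[0], c[1], 3, 2, rng=rng)
        self.stage1 = C2f(c[1], c[1], d[0], shortcut=True, rng=rng)
        self.down2 = ConvModule(c[1], c[2], 3, 2, rng=rng)
        self.stage2 = C2f(c[2], c[2], d[1], shortcut=True, rng=rng)
        self.down3 = ConvModule(c[2], c[3], 3, 2, rng=rng)
        self.stage3 = C2f(c[3], c[3], d[2], shortcut=True, rng=rng)
        self.down4 = ConvModule(c[3], c[4], 3, 2, rng=rng)
        self.stage4 = C2f(c[4], c[4], d[3], shortcut=True, rng=rng)
        self.sppf = SPPF(c[4], c[4], rng=rng)
        self.out_channels = (c[2], c[3], c[4])

    def forward(self, x):
        x = self.stage1(self.down1(self.stem(x)))
        p3 = self.stage2(self.down2(x))
        p4 = self.stage3(self.down3(p3))
        p5 = self.sppf(self.stage4(self.down4(p4)))
        return p3, p4, p5

    def count_flops(self, h, w):
        total = 0
        for m in (self.stem, self.down1, self.stage1, self.down2, self.stage2):
            f, (h, w) = m.count_flops(h, w)
            total += f
        hw3 = (h, w)
        f, (h, w) = self.down3.count_flops(h, w)
        total += f
        f, _ = self.stage3.count_flops(h, w)
        total += f
        hw4 = (h, w)
        f, (h, w) = self.down4.count_flops(h, w)
        total += f
        for m in (self.stage4, self.sppf):
            f, (h, w) = m.count_flops(h, w)
            total += f
        return total, (hw3, hw4, (h, w))


class PANNeck(Module):
    """Top-down + bottom-up path aggregation with C2f fusion blocks."""

    def __init__(self, spec: ModelSpec, ch, rng):
        super().__init__()
        c3, c4, c5 = ch
        n = spec.depths[3]
        self.up = Upsample2x()
        self.td4 = C2f(c4 + c5, c4, n, rng=rng)
        self.td3 = C2f(c3 + c4, c3, n, rng=rng)
        self.down3 = ConvModule(c3, c3, 3, 2, rng=rng)
        self.bu4 = C2f(c3 + c4, c4, n, rng=rng)
        self.down4 = ConvModule(c4, c4, 3, 2, rng=rng)
        self.bu5 = C2f(c4 + c5, c5, n, rng=rng)
        self.out_channels = (c3, c4, c5)

    def forward(self, feats):
        p3, p4, p5 = feats
        t4 = self.td4(ag.concat([p4, self.up(p5)], axis=1))
        o3 = self.td3(ag.concat([p3, self.up(t4)], axis=1))
        o4 = self.bu4(ag.concat([t4, self.down3(o3)], axis=1))
        o5 = self.bu5(ag.concat([p5, self.down4(o4)], axis=1))
        return o3, o4, o5

    def count_flops(self, hws):
        (h3, w3), (h4, w4), (h5, w5) = hws
        total = self.td4.count_flops(h4, w4)[0]
        total += self.td3.count_flops(h3, w3)[0]
        total += self.down3.count_flops(h3, w3)[0]
        total += self.bu4.count_flops(h4, w4)[0]
        total += self.down4.count_flops(h4, w4)[0]
        total += self.bu5.count_flops(h5, w5)[0]
        return total


class BELFPN(Module):
    """BiFPN-weighted bidirectional fusion with C2f_EL blocks.

    Topology (widths w3 < w4 < w5 at strides 8/16/32): a top-down pass
    (P5 -> td4 -> out3) and a bottom-up pass (out3 -> out4 -> out5); every
    multi-input node is a normalized non-negative weighted sum followed by
    a C2f_EL block.  Channel alignment uses pointwise convolutions after
    nearest upsampling (descending) or 2x2 max-pooling (ascending).
    """

    def __init__(self, spec: ModelSpec, ch, rng):
        super().__init__()
        w3, w4, w5 = spec.neck_widths
        h3, h4, h5 = spec.neck_hidden
        k3, k4, k5 = spec.mb_kernels
        g = spec.shuffle_groups
        if (w3, w4, w5) != tuple(ch):
            raise ValueError(
                f"neck widths {spec.neck_widths} must match input channels {ch}"
            )
        self.up = Upsample2x()
        self.pool = MaxPool2d(2, 2)
        self.lat54 = ConvModule(w5, w4, 1, rng=rng)
        self.lat43 = ConvModule(w4, w3, 1, rng=rng)
        self.down34 = ConvModule(w3, w4, 1, rng=rng)
        self.down45 = ConvModule(w4, w5, 1, rng=rng)
        self.fuse_td4 = BiFPNFusion(2)
        self.fuse_out3 = BiFPNFusion(2)
        self.fuse_out4 = BiFPNFusion(3)
        self.fuse_out5 = BiFPNFusion(2)
        self.td4 = C2f_EL(w4, w4, 1, h4, k4, g, rng=rng)
        self.out3 = C2f_EL(w3, w3, 1, h3, k3, g, rng=rng)
        self.out4 = C2f_EL(w4, w4, 1, h4, k4, g, rng=rng)
        self.out5 = C2f_EL(w5, w5, 1, h5, k5, g, rng=rng)
        self.out_channels = (w3, w4, w5)

    def forward(self, feats):
        p3, p4, p5 = feats
        t4 = self.td4(self.fuse_td4([p4, self.lat54(self.up(p5))]))
        o3 = self.out3(self.fuse_out3([p3, self.lat43(self.up(t4))]))
        o4 = self.out4(self.fuse_out4([p4, t4, self.down34(self.pool(o3))]))
        o5 = self.out5(self.fuse_out5([p5, self.down45(self.pool(o4))]))
        return o3, o4, o5

    def fusion_modules(self):
        return (self.fuse_td4, self.fuse_out3, self.fuse_out4, self.fuse_out5)

    def count_flops(self, hws):
        (h3, w3), (h4, w4), (h5, w5) = hws
        total = self.lat54.count_flops(h4, w4)[0]   # applied after upsample
        total += self.lat43.count_flops(h3, w3)[0]
        total += self.down34.count_flops(h4, w4)[0]  # applied after pooling
        total += self.down45.count_flops(h5, w5)[0]
        total += self.td4.count_flops(h4, w4)[0]
        total += self.out3.count_flops(h3, w3)[0]
        total += self.out4.count_flops(h4, w4)[0]
        total += self.out5.count_flops(h5, w5)[0]
        return total


class Detector(Module):
    """Single- or dual-branch detector assembled from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.branches = [Backbone(spec, rng) for _ in spec.branch_inputs]
        bb_ch = self.branches[0].out_channels
        if spec.dual or spec.neck == "belfpn":
            # reduce (concatenated) branch features to the neck widths
            n_in = len(spec.branch_inputs)
            cin = [c * n_in if spec.fusion == "concat" else c for c in bb_ch]
            self.reduce = [
                ConvModule(cin[i], spec.neck_widths[i], 1, rng=rng)
                for i in range(3)
            ]
            if spec.fusion == "wsum" and spec.dual:
                self.branch_fuse = [BiFPNFusion(n_in) for _ in range(3)]
            neck_in = spec.neck_widths
        else:
            self.reduce = []
            neck_in = bb_ch
        if spec.neck == "belfpn":
            self.neck = BELFPN(spec, neck_in, rng)
        else:
            self.neck = PANNeck(spec, neck_in, rng)
        self.head = Detect(spec.n_classes, self.neck.out_channels,
                           spec.reg_max, rng=rng)

    # -- forward ---------------------------------------------------------
    def forward(self, inputs):
        """``inputs``: one NCHW tensor per branch (a lone tensor is fine
        for the single-branch model).  Returns per-scale
        (box_logits, cls_logits) pairs."""
        if not isinstance(inputs, (list, tuple)):
            inputs = (inputs,)
        if len(inputs) != len(self.branches):
            raise ValueError(
                f"model expects {len(self.branches)} input branches, "
                f"got {len(inputs)}"
            )
        h, w = inputs[0].shape[2], inputs[0].shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        feats = [b(x) for b, x in zip(self.branches, inputs)]
        if self.reduce:
            merged = []
            for i in range(3):
                per_branch = [f[i] for f in feats]
                if len(per_branch) == 1:
                    m = per_branch[0]
                elif self.spec.fusion == "concat":
                    m = ag.concat(per_branch, axis=1)
                else:
                    m = self.branch_fuse[i](per_branch)
                merged.append(self.reduce[i](m))
        else:
            merged = list(feats[0])
        return self.head(self.neck(merged))

    # -- accounting ------------------------------------------------------
    def count_flops(self, imgsz: int = 640) -> float:
        """Total GFLOPs at ``imgsz`` square inputs (2 x MAC, conv-only),
        summed over all branches."""
        total = 0
        for b in self.branches:
            f, hws = b.count_flops(imgsz, imgsz)
            total += f
        if self.reduce:
            bb_ch = self.branches[0].out_channels
            for i, r in enumerate(self.reduce):
                total += r.count_flops(*hws[i])[0]
        total += self.neck.count_flops(hws)
        total += self.head.count_flops(hws)
        return total / 1e9


def build_model(spec: ModelSpec, seed: int = 0) -> Detector:
    return Detector(spec, seed=seed)


def count_parameters(model: Module) -> int:
    """Total parameter count (includes the frozen DFL projection, matching
    the reference accounting convention)."""
    return int(sum(p.data.size for p in model.parameters()))


def count_flops(model: Detector, imgsz: int = 640) -> float:
    return model.count_flops(imgsz)
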