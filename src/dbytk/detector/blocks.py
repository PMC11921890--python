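"""Building blocks of the dual-branch detector.

``C2f`` is the split-transform-concatenate block of modern one-stage
detectors; ``MBModule`` is the lightweight multi-scale operator used here
instead of its bottleneck: the input is split channel-wise into three
groups, each filtered by a depthwise convolution with its own kernel size,
concatenated, channel-shuffled and fused by a pointwise convolution.
``ELModule`` wraps it with a residual add, and ``C2f_EL`` places it inside
the C2f topology.  ``BiFPNFusion`` is the normalized non-negative weighted
sum used at multi-input neck nodes.
"""

from __future__ import annotations

import numpy as np

from ..nn import autograd as ag
from ..nn.layers import (
    BatchNorm2d,
    Conv2d,
    ConvModule,
    DWConv2d,
    MaxPool2d,
    Module,
    Parameter,
)


def channel_shuffle(x, groups: int):
    """Interleave channel groups: with 6 channels and 2 groups,
    (0,1,2,3,4,5) -> (0,3,1,4,2,5)."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels ({c}) must be divisible by groups ({groups})")
    y = ag.reshape(x, (n, groups, c // groups, h, w))
    y = ag.transpose(y, (0, 2, 1, 3, 4))
    return ag.reshape(y, (n, c, h, w))


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvModule(c1, c_, 3, rng=rng)
        self.cv2 = ConvModule(c_, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def count_flops(self, h, w):
        f1, _ = self.cv1.count_flops(h, w)
        f2, _ = self.cv2.count_flops(h, w)
        return f1 + f2, (h, w)


class C2f(Module):
    """Split, n sequential bottlenecks with accumulated skips, fuse."""

    def __init__(self, c1, c2, n=1, shortcut=False, e=0.5, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvModule(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvModule((2 + n) * self.c, c2, 1, rng=rng)
        self.m = [Bottleneck(self.c, self.c, shortcut, e=1.0, rng=rng)
                  for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, : self.c], y[:, self.c:]]
        for blk in self.m:
            ys.append(blk(ys[-1]))
        return self.cv2(ag.concat(ys, axis=1))

    def count_flops(self, h, w):
        f, _ = self.cv1.count_flops(h, w)
        for blk in self.m:
            fb, _ = blk.count_flops(h, w)
            f += fb
        f2, _ = self.cv2.count_flops(h, w)
        return f + f2, (h, w)


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvModule(c1, c_, 1, rng=rng)
        self.cv2 = ConvModule(4 * c_, c2, 1, rng=rng)
        self.k = k

    def forward(self, x):
        y = self.cv1(x)
        p1 = ag.maxpool2d(y, self.k, 1, self.k // 2)
        p2 = ag.maxpool2d(p1, self.k, 1, self.k // 2)
        p3 = ag.maxpool2d(p2, self.k, 1, self.k // 2)
        return self.cv2(ag.concat([y, p1, p2, p3], axis=1))

    def count_flops(self, h, w):
        f1, _ = self.cv1.count_flops(h, w)
        f2, _ = self.cv2.count_flops(h, w)
        return f1 + f2, (h, w)


class MBModule(Module):
    """Three parallel depthwise branches with distinct kernel sizes.

    The input's channels are split into three equal groups; group ``i``
    passes through a depthwise convolution of kernel size ``kernels[i]``
    (same padding) followed by BN + SiLU.  The concatenated result is
    channel-shuffled with ``groups`` and fused by a pointwise ConvModule.
    Requires the channel count divisible by ``3 * groups``.
    """

    def __init__(self, c, kernels=(3, 5, 7), groups=2, rng=None):
        super().__init__()
        if len(kernels) != 3 or any(k % 2 == 0 for k in kernels):
            raise ValueError("kernels must be three odd sizes")
        if c % (3 * groups):
            raise ValueError(
                f"channel count {c} must be divisible by 3*groups = {3 * groups}"
            )
        self.c, self.groups, self.kernels = c, groups, tuple(kernels)
        cb = c // 3
        self.dw = [DWConv2d(cb, k, rng=rng) for k in kernels]
        self.bn = [BatchNorm2d(cb) for _ in kernels]
        self.fuse = ConvModule(c, c, 1, rng=rng)

    def forward(self, x):
        cb = self.c // 3
        outs = []
        for i, (dw, bn) in enumerate(zip(self.dw, self.bn)):
            outs.append(ag.silu(bn(dw(x[:, i * cb:(i + 1) * cb]))))
        y = channel_shuffle(ag.concat(outs, axis=1), self.groups)
        return self.fuse(y)

    def count_flops(self, h, w):
        f = sum(dw.count_flops(h, w)[0] for dw in self.dw)
        f += self.fuse.count_flops(h, w)[0]
        return f, (h, w)


class ELModule(Module):
    """MBModule with a residual add (the C2f_EL inner block)."""

    def __init__(self, c, kernels=(3, 5, 7), groups=2, rng=None):
        super().__init__()
        self.mb = MBModule(c, kernels, groups, rng=rng)

    def forward(self, x):
        return x + self.mb(x)

    def count_flops(self, h, w):
        return self.mb.count_flops(h, w)


class C2f_EL(Module):
    """C2f topology with ELModule inner blocks and an explicit hidden width."""

    def __init__(self, c1, c2, n=1, hidden=None, kernels=(3, 5, 7), groups=2,
                 rng=None):
        super().__init__()
        self.c = hidden if hidden is not None else int(c2 * 0.5)
        self.cv1 = ConvModule(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvModule((2 + n) * self.c, c2, 1, rng=rng)
        self.m = [ELModule(self.c, kernels, groups, rng=rng) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, : self.c], y[:, self.c:]]
        for blk in self.m:
            ys.append(blk(ys[-1]))
        return self.cv2(ag.concat(ys, axis=1))

    def count_flops(self, h, w):
        f, _ = self.cv1.count_flops(h, w)
        for blk in self.m:
            fb, _ = blk.count_flops(h, w)
            f += fb
        f2, _ = self.cv2.count_flops(h, w)
        return f + f2, (h, w)


class BiFPNFusion(Module):
    """Normalized non-negative weighted sum of same-shape inputs.

    Computes sum_i (w_i / (eps + sum_j w_j)) * I_i with learnable weights
    rectified to stay >= 0 and eps = 1e-4.
    """

    EPS = 1e-4

    def __init__(self, n_inputs: int):
        super().__init__()
        self.n_inputs = n_inputs
        self.weights = Parameter(np.ones(n_inputs))

    def fusion_weights(self) -> np.ndarray:
        """Current rectified, normalized weights (numpy)."""
        w = np.maximum(self.weights.data, 0.0)
        return w / (self.EPS + w.sum())

    def forward(self, inputs):
        if len(inputs) != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs")
        w = ag.relu(self.weights)
        denom = ag.sum_(w) + self.EPS
        out = None
        for i, x in enumerate(inputs):
            term = x * (w[i] / denom)
            out = term if out is None else out + term
        return out

    def count_flops(self, h, w):
        return 0, (h, w)


class DFL(Module):
    """Distribution-focal decoding: softmax over bins, expectation.

    The projection vector (0, 1, ..., reg_max-1) is registered as a frozen
    parameter, matching the reference detector's parameter accounting.
    """

    def __init__(self, reg_max=16):
        super().__init__()
        self.reg_max = reg_max
        self.proj = Parameter(np.arange(reg_max, dtype=np.float32),
                              trainable=False)

    def forward(self, x):
        # x: (N, 4*reg_max, A) -> expected distance (N, 4, A) in bin units
        n, _, a = x.shape
        y = ag.reshape(x, (n, 4, self.reg_max, a))
        p = ag.softmax(y, axis=2)
        return ag.sum_(p * ag.reshape(self.proj, (1, 1, self.reg_max, 1)), axis=2)

    def decode_numpy(self, x: np.ndarray) -> np.ndarray:
        n, _, a = x.shape
        y = x.reshape(n, 4, self.reg_max, a)
        y = y - y.max(axis=2, keepdims=True)
        e = np.exp(y)
        p = e / e.sum(axis=2, keepdims=True)
        return (p * self.proj.data.reshape(1, 1, -1, 1)).sum(axis=2)


class Detect(Module):
    """Decoupled anchor-free head over three scales.

    Per level: a box branch (two 3x3 ConvModules then a 1x1 conv to
    4*reg_max DFL logits) and a class branch (same shape to n_classes
    logits).  Hidden widths follow the reference small-detector rule:
    box branch max(16, ch0/4, 4*reg_max), class branch max(ch0, n_classes).
    """

    def __init__(self, nc, ch, reg_max=16, rng=None):
        super().__init__()
        self.nc, self.reg_max, self.ch = nc, reg_max, tuple(ch)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = [
            Sequential3(ConvModule(x, c2, 3, rng=rng),
                        ConvModule(c2, c2, 3, rng=rng),
                        Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng))
            for x in ch
        ]
        self.cv3 = [
            Sequential3(ConvModule(x, c3, 3, rng=rng),
                        ConvModule(c3, c3, 3, rng=rng),
                        Conv2d(c3, nc, 1, bias=True, rng=rng))
            for x in ch
        ]
        self.dfl = DFL(reg_max)
        # standard prior init: box branch biased to short distances, class
        # branch to a low positive rate (~5 objects per 640-px image)
        for i, s in enumerate((8, 16, 32)):
            self.cv2[i].c.bias.data[:] = 1.0
            self.cv3[i].c.bias.data[:] = float(
                np.log(5.0 / nc / (640.0 / s) ** 2)
            )

    def forward(self, feats):
        return [(self.cv2[i](f), self.cv3[i](f)) for i, f in enumerate(feats)]

    def count_flops(self, hws):
        total = 0
        for i, (h, w) in enumerate(hws):
            total += self.cv2[i].count_flops(h, w)[0]
            total += self.cv3[i].count_flops(h, w)[0]
        return total


class Sequential3(Module):
    def __init__(self, a, b, c):
        super().__init__()
        self.a, self.b, self.c = a, b, c

    def forward(self, x):
        return self.c(self.b(self.a(x)))

    def count_flops(self, h, w):
        f1, (h, w) = self.a.count_flops(h, w)
        f2, (h, w) = self.b.count_flops(h, w)
        f3, (h, w) = self.c.count_flops(h, w)
        return f1 + f2 + f3, (h, w)
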