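"""Neural-network layers built on the autograd engine.

Follows the conventions of modern one-stage detectors: convolutions carry
no bias (batch norm supplies the affine shift), ``ConvModule`` is the
conv + BN + SiLU unit, and weights are He-initialized from a generator
passed down by the model builder so construction is reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    __slots__ = ("trainable",)

    def __init__(self, data, trainable: bool = True):
        super().__init__(data, requires_grad=trainable)
        self.trainable = trainable


class Module:
    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, list) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield (f"{prefix}{n}", p)
        for mn, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{mn}.")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix=""):
        out = {}
        for n, p in self._params.items():
            out[f"{prefix}{n}"] = p.data.copy()
        for n, b in self._buffers.items():
            out[f"{prefix}{n}"] = b.copy()
        for mn, m in self._modules.items():
            out.update(m.state_dict(f"{prefix}{mn}."))
        return out

    def load_state_dict(self, state, prefix=""):
        for n, p in self._params.items():
            p.data[...] = state[f"{prefix}{n}"]
        for n in self._buffers:
            self._buffers[n][...] = state[f"{prefix}{n}"]
        for mn, m in self._modules.items():
            m.load_state_dict(state, f"{prefix}{mn}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # FLOP accounting (conv-only, 2 x multiply-accumulate convention): each
    # layer reports (flops, (h_out, w_out)) for an input of size (h, w).
    def count_flops(self, h: int, w: int):
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def count_flops(self, h, w):
        total = 0
        for m in self.mods:
            f, (h, w) = m.count_flops(h, w)
            total += f
        return total, (h, w)


class Conv2d(Module):
    """Plain convolution (optionally biased), He-initialized."""

    def __init__(self, cin, cout, k, stride=1, padding=None, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        sd = math.sqrt(2.0 / (cin * k * k))
        self.weight = Parameter(rng.normal(0.0, sd, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)

    def count_flops(self, h, w):
        ho = (h + 2 * self.padding - self.k) // self.stride + 1
        wo = (w + 2 * self.padding - self.k) // self.stride + 1
        return 2 * self.k * self.k * self.cin * self.cout * ho * wo, (ho, wo)


class DWConv2d(Module):
    """Depthwise convolution (one k x k filter per channel)."""

    def __init__(self, c, k, stride=1, padding=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c, self.k = c, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        sd = math.sqrt(2.0 / (k * k))
        self.weight = Parameter(rng.normal(0.0, sd, size=(c, k, k)))

    def forward(self, x):
        return ag.depthwise_conv2d(x, self.weight, self.stride, self.padding)

    def count_flops(self, h, w):
        ho = (h + 2 * self.padding - self.k) // self.stride + 1
        wo = (w + 2 * self.padding - self.k) // self.stride + 1
        return 2 * self.k * self.k * self.c * ho * wo, (ho, wo)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self._buffers["running_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x):
        g = ag.reshape(self.gamma, (1, self.c, 1, 1))
        b = ag.reshape(self.beta, (1, self.c, 1, 1))
        if self.training:
            mu = ag.mean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = ag.mean(xc * xc, axis=(0, 2, 3), keepdims=True)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            m = self.momentum
            rm *= 1 - m
            rm += m * mu.data.reshape(-1)
            rv *= 1 - m
            rv += m * var.data.reshape(-1)
            inv = ag.pow_(var + self.eps, -0.5)
            return xc * inv * g + b
        rm = self._buffers["running_mean"].reshape(1, self.c, 1, 1)
        rv = self._buffers["running_var"].reshape(1, self.c, 1, 1)
        inv = 1.0 / np.sqrt(rv + self.eps)
        return x * Tensor(inv) * g + (b - Tensor(rm * inv) * g)

    def count_flops(self, h, w):
        return 0, (h, w)


class SiLU(Module):
    def forward(self, x):
        return ag.silu(x)

    def count_flops(self, h, w):
        return 0, (h, w)


class MaxPool2d(Module):
    def __init__(self, k, stride=None, padding=0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride or k, padding

    def forward(self, x):
        return ag.maxpool2d(x, self.k, self.stride, self.padding)

    def count_flops(self, h, w):
        ho = (h + 2 * self.padding - self.k) // self.stride + 1
        wo = (w + 2 * self.padding - self.k) // self.stride + 1
        return 0, (ho, wo)


class Upsample2x(Module):
    def forward(self, x):
        return ag.upsample_nearest2x(x)

    def count_flops(self, h, w):
        return 0, (2 * h, 2 * w)


class ConvModule(Module):
    """conv (no bias) + batch norm + SiLU — the detector's basic unit."""

    def __init__(self, cin, cout, k=1, stride=1, rng=None, act=True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return ag.silu(y) if self.act else y

    def count_flops(self, h, w):
        return self.conv.count_flops(h, w)
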