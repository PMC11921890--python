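"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Only the primitives the detector needs are provided: broadcasting
arithmetic, the usual pointwise nonlinearities, reductions, slicing /
concatenation / reshaping, 2-D convolution (dense and depthwise, via
im2col), max-pooling and nearest-neighbor upsampling.  Convolution
backward scatters column gradients with k*k vectorized adds, so everything
stays in numpy's vectorized regime.

Tensors are float32.  ``backward()`` runs a topological sweep from the
output; gradients accumulate into ``.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        order, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, pow_(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), pow_(self, -1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def pow_(a, p: float):
    a = _as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def exp(a):
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), backward)


def log(a, eps: float = 0.0):
    a = _as_tensor(a)
    x = a.data + eps if eps else a.data
    out_data = np.log(x)

    def backward(g):
        a._accum(g / x)

    return _make(out_data, (a,), backward)


def sqrt(a):
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * 0.5 / np.maximum(out_data, 1e-12))

    return _make(out_data, (a,), backward)


def atan(a):
    a = _as_tensor(a)
    out_data = np.arctan(a.data)

    def backward(g):
        a._accum(g / (1.0 + a.data * a.data))

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def silu(a):
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), backward)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accum(g * mask)

    return _make(a.data * mask, (a,), backward)


def clamp(a, lo=None, hi=None):
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= a.data >= lo
    if hi is not None:
        mask *= a.data <= hi

    def backward(g):
        a._accum(g * mask)

    return _make(out_data, (a,), backward)


def softmax(a, axis=-1):
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shape


def sum_(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes):
    a = _as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx):
    a = _as_tensor(a)
    out_data = a.data[idx]

    # integer-array indices may repeat and need unbuffered accumulation;
    # basic slices and boolean masks can use the fast in-place add
    fancy = any(
        isinstance(i, np.ndarray) and i.dtype != bool
        for i in (idx if isinstance(idx, tuple) else (idx,))
    )

    def backward(g):
        full = np.zeros_like(a.data)
        if fancy:
            np.add.at(full, idx, g)
        else:
            full[idx] += g
        a._accum(full)

    return _make(out_data, (a,), backward)


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    w = sliding_window_view(xp, (k, k), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, p: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    ho, wo = dcols.shape[2], dcols.shape[3]
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                dcols[:, :, :, :, i, j]
    return dxp[:, :, p:p + h, p:p + w] if p else dxp


def conv2d(x, w, b=None, stride: int = 1, padding: int | None = None):
    """Dense 2-D convolution, NCHW; weight (Cout, Cin, k, k)."""
    x, w = _as_tensor(x), _as_tensor(w)
    k = w.data.shape[2]
    p = k // 2 if padding is None else padding
    cols = _windows(_pad_hw(x.data, p), k, stride)
    out_data = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        w._accum(np.einsum("nchwij,nohw->ocij", cols, g, optimize=True))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        dcols = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
        x._accum(_col2im(dcols, x.data.shape, k, stride, p))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def depthwise_conv2d(x, w, stride: int = 1, padding: int | None = None):
    """Depthwise 2-D convolution; weight (C, k, k), one filter per channel."""
    x, w = _as_tensor(x), _as_tensor(w)
    k = w.data.shape[1]
    p = k // 2 if padding is None else padding
    cols = _windows(_pad_hw(x.data, p), k, stride)
    out_data = np.einsum("nchwij,cij->nchw", cols, w.data, optimize=True)

    def backward(g):
        w._accum(np.einsum("nchwij,nchw->cij", cols, g, optimize=True))
        dcols = np.einsum("nchw,cij->nchwij", g, w.data, optimize=True)
        x._accum(_col2im(dcols, x.data.shape, k, stride, p))

    return _make(out_data, (x, w), backward)


def maxpool2d(x, k: int, stride: int | None = None, padding: int = 0):
    x = _as_tensor(x)
    stride = stride or k
    xp = _pad_hw(x.data, padding)
    if padding:
        xp[:, :, :padding, :] = -np.inf
        xp[:, :, -padding:, :] = -np.inf
        xp[:, :, :, :padding] = -np.inf
        xp[:, :, :, -padding:] = -np.inf
    wins = _windows(xp, k, stride)
    n, c, ho, wo = wins.shape[:4]
    flat = wins.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dxp = _col2im(dflat.reshape(wins.shape),
                      (n, c, xp.shape[2], xp.shape[3]), k, stride, 0)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    return _make(out_data, (x,), backward)


def upsample_nearest2x(x):
    x = _as_tensor(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h, w = x.data.shape
        a = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accum(a)

    return _make(out_data, (x,), backward)
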