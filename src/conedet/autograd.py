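"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the detector needs: broadcasted
arithmetic, matmul, pointwise nonlinearities, reductions, reshaping,
2-D (grouped/depthwise) convolution, same-padded max pooling, nearest
upsampling and a 1-D convolution over the channel axis.  All tensors
are float32.  Gradients propagate through a dynamically built tape;
`no_grad()` disables taping for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that suspends graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(_as_f32(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # single-use tape: break the closure reference cycles and drop
        # intermediate grads so memory is reclaimed promptly
        for node in topo:
            if node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # convenience
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._prev for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward(out)
    return out


# -- arithmetic --------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def bk(out):
        def run():
            a._accum(_unbroadcast(out.grad, a.shape))
            b._accum(_unbroadcast(out.grad, b.shape))
        return run

    return _make(data, (a, b), bk)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def bk(out):
        def run():
            a._accum(_unbroadcast(out.grad * b.data, a.shape))
            b._accum(_unbroadcast(out.grad * a.data, b.shape))
        return run

    return _make(data, (a, b), bk)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data / b.data

    def bk(out):
        def run():
            a._accum(_unbroadcast(out.grad / b.data, a.shape))
            b._accum(_unbroadcast(-out.grad * a.data / (b.data * b.data), b.shape))
        return run

    return _make(data, (a, b), bk)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    data = a.data ** p

    def bk(out):
        def run():
            a._accum(out.grad * p * a.data ** (p - 1))
        return run

    return _make(data, (a,), bk)


def exp(a) -> Tensor:
    a = _wrap(a)
    data = np.exp(a.data)

    def bk(out):
        def run():
            a._accum(out.grad * out.data)
        return run

    return _make(data, (a,), bk)


def log(a) -> Tensor:
    a = _wrap(a)
    data = np.log(a.data)

    def bk(out):
        def run():
            a._accum(out.grad / a.data)
        return run

    return _make(data, (a,), bk)


def sqrt(a) -> Tensor:
    a = _wrap(a)
    data = np.sqrt(a.data)

    def bk(out):
        def run():
            a._accum(out.grad * 0.5 / np.maximum(out.data, 1e-12))
        return run

    return _make(data, (a,), bk)


def sigmoid(a) -> Tensor:
    from scipy.special import expit
    a = _wrap(a)
    data = expit(a.data).astype(np.float32)

    def bk(out):
        def run():
            a._accum(out.grad * out.data * (1.0 - out.data))
        return run

    return _make(data, (a,), bk)


def atan(a) -> Tensor:
    a = _wrap(a)
    data = np.arctan(a.data)

    def bk(out):
        def run():
            a._accum(out.grad / (1.0 + a.data * a.data))
        return run

    return _make(data, (a,), bk)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    data = a.data * mask

    def bk(out):
        def run():
            a._accum(out.grad * mask)
        return run

    return _make(data, (a,), bk)


def clamp(a, lo=None, hi=None) -> Tensor:
    a = _wrap(a)
    data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask = mask * (a.data > lo)
    if hi is not None:
        mask = mask * (a.data < hi)

    def bk(out):
        def run():
            a._accum(out.grad * mask)
        return run

    return _make(data, (a,), bk)


def maximum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = np.maximum(a.data, b.data)
    amask = a.data >= b.data  # ties route to the first argument

    def bk(out):
        def run():
            a._accum(_unbroadcast(out.grad * amask, a.shape))
            b._accum(_unbroadcast(out.grad * (~amask), b.shape))
        return run

    return _make(data, (a, b), bk)


def minimum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = np.minimum(a.data, b.data)
    amask = a.data <= b.data

    def bk(out):
        def run():
            a._accum(_unbroadcast(out.grad * amask, a.shape))
            b._accum(_unbroadcast(out.grad * (~amask), b.shape))
        return run

    return _make(data, (a, b), bk)


# -- linear algebra, shape, reductions --------------------------------

def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data @ b.data

    def bk(out):
        def run():
            a._accum(out.grad @ b.data.T)
            b._accum(a.data.T @ out.grad)
        return run

    return _make(data, (a, b), bk)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bk(out):
        def run():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).astype(np.float32))
        return run

    return _make(data, (a,), bk)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod([a.shape[i] for i in np.atleast_1d(axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    data = a.data.reshape(shape)

    def bk(out):
        def run():
            a._accum(out.grad.reshape(a.shape))
        return run

    return _make(data, (a,), bk)


def getitem(a, idx) -> Tensor:
    """Basic (slice/integer) indexing with gradient scatter."""
    a = _wrap(a)
    data = a.data[idx]

    def bk(out):
        def run():
            g = np.zeros_like(a.data)
            g[idx] += out.grad
            a._accum(g)
        return run

    return _make(data, (a,), bk)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def bk(out):
        def run():
            a._accum(out.grad.transpose(inv))
        return run

    return _make(data, (a,), bk)


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bk(out):
        def run():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])
        return run

    return _make(data, tuple(tensors), bk)


# -- convolutions and resampling --------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D convolution (cross-correlation), NCHW layout.

    x: (N, Cin, H, W); w: (Cout, Cin, K, K); b: (Cout,) or None.
    Fast path for 1x1 kernels avoids im2col entirely.
    """
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    N, Cin, H, W = x.shape
    Cout, _, K, _ = w.shape

    if K == 1 and padding == 0:
        xs = x.data[:, :, ::stride, ::stride]
        Ho, Wo = xs.shape[2], xs.shape[3]
        wm = w.data.reshape(Cout, Cin)
        out_data = np.einsum("oc,nchw->nohw", wm, xs, optimize=True)
        if b is not None:
            out_data = out_data + b.data[None, :, None, None]

        def bk(out):
            def run():
                g = out.grad
                w._accum(np.einsum("nohw,nchw->oc", g, xs, optimize=True).reshape(w.shape))
                gx = np.einsum("oc,nohw->nchw", wm, g, optimize=True)
                if stride > 1:
                    full = np.zeros(x.shape, dtype=np.float32)
                    full[:, :, ::stride, ::stride] = gx
                    gx = full
                x._accum(gx)
                if b is not None:
                    b._accum(g.sum(axis=(0, 2, 3)))
            return run

        parents = (x, w) if b is None else (x, w, b)
        return _make(out_data, parents, bk)

    xp = _pad_hw(x.data, padding)
    Ho = (H + 2 * padding - K) // stride + 1
    Wo = (W + 2 * padding - K) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (K, K), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (N, Cin, Ho, Wo, K, K)
    col = view.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, Cin * K * K)
    wm = w.data.reshape(Cout, Cin * K * K)
    out_data = (col @ wm.T).reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def bk(out):
        def run():
            g = out.grad.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Cout)
            w._accum((g.T @ col).reshape(w.shape))
            dcol = (g @ wm).reshape(N, Ho, Wo, Cin, K, K)
            gx = np.zeros_like(xp)
            for i in range(K):
                for j in range(K):
                    gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += (
                        dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2))
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)
            if b is not None:
                b._accum(out.grad.sum(axis=(0, 2, 3)))
        return run

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bk)


def depthwise_conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise 2-D convolution: one K x K filter per channel.

    x: (N, C, H, W); w: (C, K, K).
    """
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    N, C, H, W = x.shape
    K = w.shape[-1]
    xp = _pad_hw(x.data, padding)
    Ho = (H + 2 * padding - K) // stride + 1
    Wo = (W + 2 * padding - K) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (K, K), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, K, K)
    out_data = np.einsum("nchwij,cij->nchw", view, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def bk(out):
        def run():
            g = out.grad
            w._accum(np.einsum("nchwij,nchw->cij", view, g, optimize=True))
            gx = np.zeros_like(xp)
            for i in range(K):
                for j in range(K):
                    gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += (
                        g * w.data[None, :, i, j, None, None])
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3)))
        return run

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bk)


def maxpool2d_same(x, k: int) -> Tensor:
    """Stride-1 max pool with same-size zero padding (odd k)."""
    if k % 2 == 0:
        raise ValueError("pool side must be odd for same-size pooling")
    x = _wrap(x)
    if k == 1:
        return x
    p = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    out_data = view.max(axis=(4, 5))
    H, W = x.shape[2], x.shape[3]

    def bk(out):
        def run():
            gx = np.zeros_like(xp)
            remaining = np.ones_like(out.data, dtype=bool)
            for i in range(k):
                for j in range(k):
                    hit = remaining & (xp[:, :, i:i + H, j:j + W] == out.data)
                    gx[:, :, i:i + H, j:j + W] += out.grad * hit
                    remaining &= ~hit
            x._accum(gx[:, :, p:-p, p:-p])
        return run

    return _make(out_data, (x,), bk)


def upsample_nearest2(x) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    x = _wrap(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bk(out):
        def run():
            N, C, H2, W2 = out.grad.shape
            g = out.grad.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            x._accum(g)
        return run

    return _make(out_data, (x,), bk)


def conv1d_channels(g, w) -> Tensor:
    """1-D convolution along the channel axis with zero padding.

    g: (N, C) per-channel descriptors; w: (k,) odd-length kernel.
    Returns (N, C).
    """
    g, w = _wrap(g), _wrap(w)
    k = w.shape[0]
    p = (k - 1) // 2
    N, C = g.shape
    gp = np.pad(g.data, ((0, 0), (p, p)))
    view = np.lib.stride_tricks.sliding_window_view(gp, k, axis=1)  # (N, C, k)
    out_data = view @ w.data

    def bk(out):
        def run():
            w._accum(np.einsum("nck,nc->k", view, out.grad, optimize=True))
            gg = np.zeros_like(gp)
            for i in range(k):
                gg[:, i:i + C] += out.grad * w.data[i]
            g._accum(gg[:, p:p + C] if p else gg)
        return run

    return _make(out_data, (g, w), bk)
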