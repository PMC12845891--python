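"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the primitives the 1D segmentation network needs:
elementwise arithmetic, reductions, strided/grouped 1-D convolution,
channelwise layer normalization, GELU/LeakyReLU, linear upsampling,
concatenation, slicing and padding. Tensors are float32; gradients are
accumulated by closures in reverse topological order.

Gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "concat", "conv1d", "dwconv1d", "layer_norm",
           "gelu", "leaky_relu", "upsample_linear", "pad_time"]


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, key):
        out = _make(self.data[key], (self,))
        if out._prev:
            def bwd(g, key=key, x=self):
                full = np.zeros_like(x.data)
                np.add.at(full, key, g)
                _accum(x, full)
            out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True) if g.dtype != np.float32 else g.copy()
    else:
        t.grad += g


def _make(data, prev) -> Tensor:
    parents = tuple(p for p in prev if p.requires_grad or p._prev)
    out = Tensor(data)
    out._prev = parents
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape it was broadcast from."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(a.data + b.data, (a, b))
    if out._prev:
        def bwd(g):
            if a.requires_grad or a._prev:
                _accum(a, _unbroadcast(g, a.data.shape))
            if b.requires_grad or b._prev:
                _accum(b, _unbroadcast(g, b.data.shape))
        out._backward = bwd
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(a.data * b.data, (a, b))
    if out._prev:
        def bwd(g):
            if a.requires_grad or a._prev:
                _accum(a, _unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad or b._prev:
                _accum(b, _unbroadcast(g * a.data, b.data.shape))
        out._backward = bwd
    return out


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out = _make(a.data**p, (a,))
    if out._prev:
        def bwd(g):
            _accum(a, _unbroadcast(g * p * a.data ** (p - 1), a.data.shape))
        out._backward = bwd
    return out


def exp(a) -> Tensor:
    a = _as_tensor(a)
    y = np.exp(a.data)
    out = _make(y, (a,))
    if out._prev:
        out._backward = lambda g: _accum(a, g * y)
    return out


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = _make(a.data.sum(axis=axis, keepdims=keepdims), (a,))
    if out._prev:
        def bwd(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(gg, a.data.shape))
        out._backward = bwd
    return out


def gelu(a) -> Tensor:
    """Exact (erf-based) GELU."""
    a = _as_tensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    out = _make(x * cdf, (a,))
    if out._prev:
        def bwd(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            _accum(a, g * (cdf + x * pdf))
        out._backward = bwd
    return out


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = _as_tensor(a)
    x = a.data
    out = _make(np.where(x > 0, x, slope * x), (a,))
    if out._prev:
        out._backward = lambda g: _accum(a, g * np.where(x > 0, 1.0, slope).astype(np.float32))
    return out


def softmax_channels(a) -> Tensor:
    """Softmax over axis 1 of an (N, C, L) tensor (numerically stabilized)."""
    a = _as_tensor(a)
    shifted = add(a, -a.data.max(axis=1, keepdims=True))
    e = exp(shifted)
    return mul(e, power(tsum(e, axis=1, keepdims=True), -1.0))


# -- structural -------------------------------------------------------------

def concat(tensors: list, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._prev:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._prev:
                    _accum(t, piece)
        out._backward = bwd
    return out


def pad_time(a, left: int, right: int) -> Tensor:
    """Zero-pad the last axis of an (N, C, L) tensor."""
    a = _as_tensor(a)
    if left == 0 and right == 0:
        return a
    out = _make(np.pad(a.data, ((0, 0), (0, 0), (left, right))), (a,))
    if out._prev:
        L = a.data.shape[-1]
        out._backward = lambda g: _accum(a, g[:, :, left : left + L])
    return out


def crop_time(a, start: int, stop: int) -> Tensor:
    a = _as_tensor(a)
    out = _make(a.data[:, :, start:stop], (a,))
    if out._prev:
        def bwd(g):
            full = np.zeros_like(a.data)
            full[:, :, start:stop] = g
            _accum(a, full)
        out._backward = bwd
    return out


# -- convolution ------------------------------------------------------------

def conv1d(x, w, b=None, stride: int = 1, padding: tuple[int, int] = (0, 0)) -> Tensor:
    """Dense 1-D convolution (cross-correlation).

    ``x``: (N, C_in, L); ``w``: (C_out, C_in, K); ``b``: (C_out,).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    xp = np.pad(x.data, ((0, 0), (0, 0), padding))
    n, c_in, lp = xp.shape
    c_out, _, k = w.data.shape
    l_out = (lp - k) // stride + 1
    win = sliding_window_view(xp, k, axis=2)[:, :, ::stride]  # (N, Cin, Lout, K)
    cols = win.transpose(0, 2, 1, 3).reshape(n, l_out, c_in * k)
    w2 = w.data.reshape(c_out, c_in * k)
    y = cols @ w2.T  # (N, Lout, Cout)
    if b is not None:
        b = _as_tensor(b)
        y = y + b.data[None, None, :]
    out = _make(np.ascontiguousarray(y.transpose(0, 2, 1)), ((x, w, b) if b is not None else (x, w)))
    if out._prev:
        def bwd(g):
            gy = g.transpose(0, 2, 1)  # (N, Lout, Cout)
            if w.requires_grad or w._prev:
                gw = np.tensordot(gy, cols, axes=([0, 1], [0, 1]))  # (Cout, Cin*K)
                _accum(w, gw.reshape(c_out, c_in, k))
            if b is not None and (b.requires_grad or b._prev):
                _accum(b, gy.sum(axis=(0, 1)))
            if x.requires_grad or x._prev:
                gcols = gy @ w2  # (N, Lout, Cin*K)
                gcols = gcols.reshape(n, l_out, c_in, k).transpose(0, 2, 1, 3)
                gxp = np.zeros_like(xp)
                for kk in range(k):
                    gxp[:, :, kk : kk + stride * l_out : stride] += gcols[:, :, :, kk]
                lpad, rpad = padding
                _accum(x, gxp[:, :, lpad : lpad + x.data.shape[-1]])
        out._backward = bwd
    return out


def dwconv1d(x, w, b=None, padding: tuple[int, int] = (0, 0)) -> Tensor:
    """Depthwise 1-D convolution, stride 1. ``w``: (C, K); ``b``: (C,)."""
    x, w = _as_tensor(x), _as_tensor(w)
    xp = np.pad(x.data, ((0, 0), (0, 0), padding))
    c, k = w.data.shape
    win = sliding_window_view(xp, k, axis=2)  # (N, C, Lout, K)
    y = np.einsum("nclk,ck->ncl", win, w.data, optimize=True)
    if b is not None:
        b = _as_tensor(b)
        y = y + b.data[None, :, None]
    out = _make(y, ((x, w, b) if b is not None else (x, w)))
    if out._prev:
        l_out = y.shape[-1]
        def bwd(g):
            if w.requires_grad or w._prev:
                _accum(w, np.einsum("ncl,nclk->ck", g, win, optimize=True))
            if b is not None and (b.requires_grad or b._prev):
                _accum(b, g.sum(axis=(0, 2)))
            if x.requires_grad or x._prev:
                gxp = np.zeros_like(xp)
                for kk in range(k):
                    gxp[:, :, kk : kk + l_out] += g * w.data[None, :, kk, None]
                lpad = padding[0]
                _accum(x, gxp[:, :, lpad : lpad + x.data.shape[-1]])
        out._backward = bwd
    return out


# -- normalization ----------------------------------------------------------

def layer_norm(x, gamma, beta, eps: float = 1e-6) -> Tensor:
    """LayerNorm over the channel axis of an (N, C, L) tensor."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g_ = gamma.data[None, :, None]
    out = _make(g_ * xhat + beta.data[None, :, None], (x, gamma, beta))
    if out._prev:
        c = x.data.shape[1]
        def bwd(g):
            if gamma.requires_grad or gamma._prev:
                _accum(gamma, (g * xhat).sum(axis=(0, 2)))
            if beta.requires_grad or beta._prev:
                _accum(beta, g.sum(axis=(0, 2)))
            if x.requires_grad or x._prev:
                dxhat = g * g_
                m1 = dxhat.mean(axis=1, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
                _accum(x, inv * (dxhat - m1 - xhat * m2))
        out._backward = bwd
    return out


def upsample_linear(x, factor: int) -> Tensor:
    """Linear interpolation upsampling of (N, C, L) by an integer factor."""
    x = _as_tensor(x)
    l_in = x.data.shape[-1]
    l_out = l_in * factor
    pos = (np.arange(l_out) + 0.5) / factor - 0.5
    i0 = np.clip(np.floor(pos).astype(int), 0, l_in - 1)
    i1 = np.clip(i0 + 1, 0, l_in - 1)
    w1 = np.clip(pos - i0, 0.0, 1.0).astype(np.float32)
    w0 = 1.0 - w1
    y = x.data[:, :, i0] * w0 + x.data[:, :, i1] * w1
    out = _make(y, (x,))
    if out._prev:
        def bwd(g):
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), i0), g * w0)
            np.add.at(gx, (slice(None), slice(None), i1), g * w1)
            _accum(x, gx)
        out._backward = bwd
    return out
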