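"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the material-decomposition network and its losses need
are implemented: 3D convolution (im2col + GEMM), spatial transposed
convolution and max-pooling, batch normalization, ReLU, channel
concatenation, scalar gating, softmax, fixed-kernel 2D convolution with
reflect padding (for the Sobel gradient loss) and elementwise arithmetic.
Tensors are single-sample (no batch axis): the training protocol uses batch
size 1 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):  # numpy scalar: keep its dtype
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        _acc(self, grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def sum(self):
        return tsum(self)

    def mean(self):
        return mul(tsum(self), 1.0 / self.data.size)

    def reshape(self, shape):
        return reshape(self, shape)


def _acc(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _as_array(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad),
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# elementwise ops


def add(a: Tensor, b):
    if isinstance(b, Tensor):
        out_data = a.data + b.data

        def backward(g):
            _acc(a, g if g.shape == a.data.shape else _unbroadcast(g, a.data.shape))
            _acc(b, g if g.shape == b.data.shape else _unbroadcast(g, b.data.shape))

        return _make(out_data, (a, b), backward)
    bb = np.asarray(b, dtype=a.data.dtype)

    def backward(g):
        _acc(a, g if g.shape == a.data.shape else _unbroadcast(g, a.data.shape))

    return _make(a.data + bb, (a,), backward)


def mul(a: Tensor, b):
    if isinstance(b, Tensor):
        out_data = a.data * b.data

        def backward(g):
            _acc(a, _unbroadcast(g * b.data, a.data.shape))
            _acc(b, _unbroadcast(g * a.data, b.data.shape))

        return _make(out_data, (a, b), backward)
    bb = np.asarray(b, dtype=a.data.dtype)

    def backward(g):
        _acc(a, _unbroadcast(g * bb, a.data.shape))

    return _make(a.data * bb, (a,), backward)


def _unbroadcast(g, shape):
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def power(x: Tensor, p: float):
    out_data = x.data**p

    def backward(g):
        _acc(x, g * p * x.data ** (p - 1.0))

    return _make(out_data, (x,), backward)


def log(x: Tensor):
    out_data = np.log(x.data)

    def backward(g):
        _acc(x, g / x.data)

    return _make(out_data, (x,), backward)


def clamp(x: Tensor, lo: float, hi: float):
    mask = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        _acc(x, g * mask)

    return _make(np.clip(x.data, lo, hi), (x,), backward)


def tsum(x: Tensor):
    def backward(g):
        _acc(x, np.broadcast_to(g, x.data.shape).astype(x.data.dtype, copy=False))

    return _make(np.asarray(x.data.sum()), (x,), backward)


def reshape(x: Tensor, shape):
    old = x.data.shape

    def backward(g):
        _acc(x, g.reshape(old))

    return _make(x.data.reshape(shape), (x,), backward)


def relu(x: Tensor):
    mask = x.data > 0

    def backward(g):
        _acc(x, g * mask)

    return _make(np.where(mask, x.data, 0), (x,), backward)


def scale(x: Tensor, g_param: Tensor):
    """Learnable scalar gate: out = g * x."""

    def backward(g):
        _acc(g_param, np.asarray(np.sum(g * x.data), dtype=g_param.data.dtype).reshape(g_param.data.shape))
        _acc(x, g * g_param.data)

    return _make(x.data * g_param.data, (x, g_param), backward)


def concat(a: Tensor, b: Tensor, axis: int = 0):
    na = a.data.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [na], axis=axis)
        _acc(a, ga)
        _acc(b, gb)

    return _make(np.concatenate([a.data, b.data], axis=axis), (a, b), backward)


def softmax(x: Tensor, axis: int = 0):
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        _acc(x, y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return _make(y, (x,), backward)


# ---------------------------------------------------------------------------
# structured ops (single sample, channels-first)


def conv3d(x: Tensor, w: Tensor, b: Tensor, pad=(1, 1, 1)):
    """3D convolution on (C, D, H, W) with zero 'same'-style padding."""
    C, D, H, W = x.data.shape
    cout, cin, kd, kh, kw = w.data.shape
    if cin != C:
        raise ValueError("channel mismatch")
    pd, ph, pw = pad
    xp = np.pad(x.data, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kd, kh, kw), axis=(1, 2, 3))
    Do, Ho, Wo = win.shape[1:4]
    cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        Do * Ho * Wo, C * kd * kh * kw
    )
    Wm = w.data.reshape(cout, -1)
    out = cols @ Wm.T + b.data
    out_t = np.ascontiguousarray(out.reshape(Do, Ho, Wo, cout).transpose(3, 0, 1, 2))

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(1, 2, 3, 0)).reshape(-1, cout)
        if w.requires_grad:
            _acc(w, (gm.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            _acc(b, gm.sum(0))
        if x.requires_grad:
            dcols = (gm @ Wm).reshape(Do, Ho, Wo, C, kd, kh, kw)
            dxp = np.zeros_like(xp)
            for a in range(kd):
                for bb in range(kh):
                    for cc in range(kw):
                        dxp[:, a : a + Do, bb : bb + Ho, cc : cc + Wo] += np.ascontiguousarray(
                            dcols[..., a, bb, cc].transpose(3, 0, 1, 2)
                        )
            _acc(x, dxp[:, pd : pd + D, ph : ph + H, pw : pw + W])

    return _make(out_t, (x, w, b), backward)


def maxpool_spatial(x: Tensor):
    """(1, 2, 2) max pooling on (C, D, H, W); H and W must be even."""
    C, D, H, W = x.data.shape
    xr = np.ascontiguousarray(
        x.data.reshape(C, D, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(C, D, H // 2, W // 2, 4)
    idx = xr.argmax(-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((C, D, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(C, D, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(C, D, H, W)
        _acc(x, dx)

    return _make(out, (x,), backward)


def conv_transpose_spatial(x: Tensor, w: Tensor, b: Tensor):
    """Transposed conv with (1, 2, 2) kernel and stride: doubles H and W.

    Weight shape (cin, cout, 2, 2).
    """
    cin, cout = w.data.shape[:2]
    C, D, H, W = x.data.shape
    out = np.empty((cout, D, 2 * H, 2 * W), dtype=x.data.dtype)
    for a in range(2):
        for c in range(2):
            out[:, :, a::2, c::2] = np.einsum("io,idhw->odhw", w.data[:, :, a, c], x.data)
    out += b.data[:, None, None, None]

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for a in range(2):
                for c in range(2):
                    dx += np.einsum("io,odhw->idhw", w.data[:, :, a, c], g[:, :, a::2, c::2])
            _acc(x, dx)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for a in range(2):
                for c in range(2):
                    dw[:, :, a, c] = np.einsum("idhw,odhw->io", x.data, g[:, :, a::2, c::2])
            _acc(w, dw)
        if b.requires_grad:
            _acc(b, g.sum(axis=(1, 2, 3)))

    return _make(out, (x, w, b), backward)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5,
              running: tuple | None = None):
    """Per-channel normalization over (D, H, W).

    With ``running=None`` batch statistics are used (training mode) and the
    batch mean/variance are attached to the output tensor's closure via the
    return value; pass ``running=(mean, var)`` for evaluation mode.
    """
    C = x.data.shape[0]
    axes = (1, 2, 3)
    if running is None:
        m = x.data.mean(axis=axes, keepdims=True)
        v = x.data.var(axis=axes, keepdims=True)
        stats = (m.reshape(C), v.reshape(C))
        inv = 1.0 / np.sqrt(v + eps)
        xhat = (x.data - m) * inv
        out = gamma.data[:, None, None, None] * xhat + beta.data[:, None, None, None]
        nM = x.data[0].size

        def backward(g):
            if gamma.requires_grad:
                _acc(gamma, (g * xhat).sum(axis=axes))
            if beta.requires_grad:
                _acc(beta, g.sum(axis=axes))
            if x.requires_grad:
                dxhat = g * gamma.data[:, None, None, None]
                mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
                mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
                _acc(x, inv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat))

        return _make(out, (x, gamma, beta), backward), stats
    rm, rv = running
    inv = (1.0 / np.sqrt(rv + eps))[:, None, None, None]
    xhat = (x.data - rm[:, None, None, None]) * inv
    out = gamma.data[:, None, None, None] * xhat + beta.data[:, None, None, None]

    def backward(g):
        if gamma.requires_grad:
            _acc(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _acc(beta, g.sum(axis=axes))
        if x.requires_grad:
            _acc(x, g * gamma.data[:, None, None, None] * inv)

    return _make(out, (x, gamma, beta), backward), (rm, rv)


def conv2d_fixed(x: Tensor, kernel: np.ndarray):
    """Per-channel 2D correlation with a fixed 3x3 kernel, reflect padding."""
    k = np.asarray(kernel, dtype=x.data.dtype)
    if k.shape != (3, 3):
        raise ValueError("kernel must be 3x3")
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1)), mode="reflect")
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))
    out = np.einsum("chwab,ab->chw", win, k)
    C, H, W = x.data.shape

    def backward(g):
        dxp = np.zeros_like(xp)
        for a in range(3):
            for b in range(3):
                dxp[:, a : a + H, b : b + W] += k[a, b] * g
        dx = dxp[:, 1:-1, 1:-1].copy()
        # fold the reflect-padding adjoint back inside
        dx[:, 1, :] += dxp[:, 0, 1:-1]
        dx[:, -2, :] += dxp[:, -1, 1:-1]
        dx[:, :, 1] += dxp[:, 1:-1, 0]
        dx[:, :, -2] += dxp[:, 1:-1, -1]
        dx[:, 1, 1] += dxp[:, 0, 0]
        dx[:, 1, -2] += dxp[:, 0, -1]
        dx[:, -2, 1] += dxp[:, -1, 0]
        dx[:, -2, -2] += dxp[:, -1, -1]
        _acc(x, dx)

    return _make(out, (x,), backward)
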