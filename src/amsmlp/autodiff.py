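"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation network needs: broadcasted
arithmetic, activations, reductions, shape manipulation, axis-wise dense
("fully connected") maps, stride-1 2-D convolution, kernel-2/stride-2
transposed convolution, 2x max pooling, k-fold average pooling, 2x bilinear
upsampling, layer normalization and batch normalization.

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on a
scalar output. A global :func:`no_grad` context disables graph construction
for inference.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "linear",
    "conv2d",
    "deconv2x",
    "maxpool2x",
    "avgpool",
    "upsample2x_bilinear",
    "layer_norm",
    "batch_norm",
]

_GRAD_ENABLED = True

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_array(data):
    a = np.asarray(data)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward pass ----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph references early
                node._backward = None
                node._parents = ()

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return _add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _add(self, _mul(other, -1.0))

    def __rsub__(self, other):
        return _add(_mul(self, -1.0), other)

    def __neg__(self):
        return _mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return _mul(self, other.reciprocal())
        return _mul(self, 1.0 / other)

    def reciprocal(self):
        inv = 1.0 / self.data

        def bwd(g):
            _accum(self, -g * inv * inv)

        return Tensor._make(inv, (self,), bwd)

    # -- activations -------------------------------------------------------
    def exp(self):
        y = np.exp(self.data)

        def bwd(g):
            _accum(self, g * y)

        return Tensor._make(y, (self,), bwd)

    def log(self):
        x = self.data

        def bwd(g):
            _accum(self, g / x)

        return Tensor._make(np.log(x), (self,), bwd)

    def sigmoid(self):
        y = expit(self.data)  # numerically stable logistic

        def bwd(g):
            _accum(self, g * y * (1.0 - y))

        return Tensor._make(y, (self,), bwd)

    def relu(self):
        y = np.maximum(self.data, 0.0)

        def bwd(g):
            _accum(self, g * (self.data > 0))

        return Tensor._make(y, (self,), bwd)

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        y = x * phi

        def bwd(g):
            pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
            _accum(self, g * (phi + x * pdf))

        return Tensor._make(y, (self,), bwd)

    def clip(self, lo, hi):
        """Clamp values; gradient passes through the interior only."""
        y = np.clip(self.data, lo, hi)

        def bwd(g):
            _accum(self, g * ((self.data >= lo) & (self.data <= hi)))

        return Tensor._make(y, (self,), bwd)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        y = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bwd(g):
            if axis is None:
                _accum(self, np.broadcast_to(g, shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(gg, shape).copy())

        return Tensor._make(y, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def bwd(g):
            _accum(self, g.reshape(src))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(g):
            _accum(self, g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        src_shape = self.data.shape

        def bwd(g):
            full = np.zeros(src_shape, dtype=g.dtype)
            full[idx] = g
            _accum(self, full)

        return Tensor._make(self.data[idx], (self,), bwd)


def _accum(t, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g
    else:
        t.grad = t.grad + g


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _add(a, b):
    if not isinstance(b, Tensor):
        # keep python scalars as scalars so float32 arrays stay float32
        b_val = b if isinstance(b, (int, float)) else _as_array(b)
        y = a.data + b_val

        def bwd(g):
            _accum(a, _unbroadcast(g, a.data.shape))

        return Tensor._make(y, (a,), bwd)
    y = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor._make(y, (a, b), bwd)


def _mul(a, b):
    if not isinstance(b, Tensor):
        b_val = b if isinstance(b, (int, float)) else _as_array(b)
        y = a.data * b_val

        def bwd(g):
            _accum(a, _unbroadcast(g * b_val, a.data.shape))

        return Tensor._make(y, (a,), bwd)
    y = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor._make(y, (a, b), bwd)


def concat(tensors, axis):
    """Concatenate tensors along ``axis``."""
    tensors = list(tensors)
    y = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, part in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, part)

    return Tensor._make(y, tensors, bwd)


def linear(x, w, b=None, axis=-1):
    """Dense map ``y = w @ x`` applied along a single axis of ``x``.

    ``w`` has shape [out, in] where ``in`` is the length of ``axis``; every
    other axis is untouched.
    """
    nd = x.data.ndim
    ax = axis % nd
    xm = np.moveaxis(x.data, ax, -1)
    lead = xm.shape[:-1]
    xf = xm.reshape(-1, xm.shape[-1])
    yf = xf @ w.data.T
    if b is not None:
        yf = yf + b.data
    y = np.moveaxis(yf.reshape(lead + (w.data.shape[0],)), -1, ax)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gm = np.moveaxis(g, ax, -1).reshape(-1, w.data.shape[0])
        _accum(x, np.moveaxis((gm @ w.data).reshape(lead + (xm.shape[-1],)), -1, ax))
        _accum(w, gm.T @ xf)
        if b is not None:
            _accum(b, gm.sum(axis=0))

    return Tensor._make(y, parents, bwd)


def conv2d(x, w, b=None, padding=None):
    """Stride-1 2-D convolution (cross-correlation) in NCHW layout.

    ``w`` has shape [Cout, Cin, k, k]; default padding keeps the spatial size
    ("same" for odd kernels).
    """
    B, C, H, W = x.data.shape
    Cout, Cin, kh, kw = w.data.shape
    if Cin != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cin}")
    if padding is None:
        padding = (kh - 1) // 2
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, C * kh * kw
    )
    wm = w.data.reshape(Cout, -1)
    yf = cols @ wm.T
    if b is not None:
        yf = yf + b.data
    y = yf.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, Cout)
        _accum(w, (gf.T @ cols).reshape(w.data.shape))
        if b is not None:
            _accum(b, gf.sum(axis=0))
        dcols = (gf @ wm).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j]
        _accum(x, dxp[:, :, p : p + H, p : p + W] if p else dxp)

    return Tensor._make(y, parents, bwd)


def deconv2x(x, w, b=None):
    """Transposed convolution, kernel 2 / stride 2: exact 2x upsampling.

    ``w`` has shape [Cin, Cout, 2, 2]; each input pixel expands into one
    non-overlapping 2x2 output block.
    """
    B, C, H, W = x.data.shape
    Cin, Cout = w.data.shape[:2]
    if Cin != C:
        raise ValueError(f"deconv2x: input has {C} channels, weight expects {Cin}")
    w2 = w.data.reshape(Cin, Cout * 4)
    xf = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, Cin)
    y = (
        (xf @ w2)
        .reshape(B, H, W, Cout, 2, 2)
        .transpose(0, 3, 1, 4, 2, 5)
        .reshape(B, Cout, 2 * H, 2 * W)
    )
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g6 = np.ascontiguousarray(
            g.reshape(B, Cout, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)
        ).reshape(-1, Cout * 4)
        _accum(x, (g6 @ w2.T).reshape(B, H, W, Cin).transpose(0, 3, 1, 2))
        _accum(w, (xf.T @ g6).reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, bwd)


def maxpool2x(x):
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""
    B, C, H, W = x.data.shape
    v = (
        x.data.reshape(B, C, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, H // 2, W // 2, 4)
    )
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = (
            gv.reshape(B, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H, W)
        )
        _accum(x, gx)

    return Tensor._make(y, (x,), bwd)


def avgpool(x, k):
    """k x k average pooling, stride k."""
    B, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avgpool: {H}x{W} not divisible by {k}")
    y = x.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def bwd(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / (k * k), (B, C, H // k, k, W // k, k)
        ).reshape(B, C, H, W)
        _accum(x, gx.copy())

    return Tensor._make(y, (x,), bwd)


def _bilinear_indices(n_in):
    """Gather indices/weights for 2x upsampling (align_corners=False)."""
    o = np.arange(2 * n_in)
    pos = (o + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(pos).astype(np.int64), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    wgt = np.clip(pos - np.floor(pos), 0.0, 1.0)
    wgt[pos < 0] = 0.0
    return i0, i1, wgt


def upsample2x_bilinear(x):
    """Bilinear 2x spatial upsampling (align_corners=False convention)."""
    B, C, H, W = x.data.shape
    ih0, ih1, wh = _bilinear_indices(H)
    iw0, iw1, ww = _bilinear_indices(W)
    whc = wh[None, None, :, None].astype(x.data.dtype)
    wwc = ww[None, None, None, :].astype(x.data.dtype)
    yh = x.data[:, :, ih0, :] * (1 - whc) + x.data[:, :, ih1, :] * whc
    y = yh[:, :, :, iw0] * (1 - wwc) + yh[:, :, :, iw1] * wwc

    def bwd(g):
        gh = np.zeros((B, C, 2 * H, W), dtype=g.dtype)
        np.add.at(gh, (slice(None), slice(None), slice(None), iw0), g * (1 - wwc))
        np.add.at(gh, (slice(None), slice(None), slice(None), iw1), g * wwc)
        gx = np.zeros((B, C, H, W), dtype=g.dtype)
        np.add.at(gx, (slice(None), slice(None), ih0), gh * (1 - whc))
        np.add.at(gx, (slice(None), slice(None), ih1), gh * whc)
        _accum(x, gx)

    return Tensor._make(y, (x,), bwd)


def layer_norm(x, gamma, beta, axis, eps=1e-5):
    """Normalize over one axis; ``gamma``/``beta`` broadcast over the rest."""
    ax = axis % x.data.ndim
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    shape = [1] * x.data.ndim
    shape[ax] = x.data.shape[ax]
    gb = gamma.data.reshape(shape)
    y = xhat * gb + beta.data.reshape(shape)

    def bwd(g):
        red = tuple(i for i in range(x.data.ndim) if i != ax)
        _accum(gamma, (g * xhat).sum(axis=red))
        _accum(beta, g.sum(axis=red))
        dxh = g * gb
        m1 = dxh.mean(axis=ax, keepdims=True)
        m2 = (dxh * xhat).mean(axis=ax, keepdims=True)
        _accum(x, inv * (dxh - m1 - xhat * m2))

    return Tensor._make(y, (x, gamma, beta), bwd)


def batch_norm(x, gamma, beta, running_mean, running_var, axes, training,
               momentum=0.1, eps=1e-5):
    """Batch normalization over ``axes`` with running-statistics side effect.

    ``running_mean``/``running_var`` are plain numpy arrays owned by the layer
    and updated in place during training.
    """
    shape = [1] * x.data.ndim
    feat_axes = tuple(i for i in range(x.data.ndim) if i not in axes)
    for i in feat_axes:
        shape[i] = x.data.shape[i]
    gb = gamma.data.reshape(shape)
    bb = beta.data.reshape(shape)
    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu.reshape(running_mean.shape)
        running_var *= 1.0 - momentum
        running_var += momentum * var.reshape(running_var.shape)
    else:
        mu = running_mean.reshape(shape)
        var = running_var.reshape(shape)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = xhat * gb + bb

    def bwd(g):
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))
        dxh = g * gb
        if training:
            m1 = dxh.mean(axis=axes, keepdims=True)
            m2 = (dxh * xhat).mean(axis=axes, keepdims=True)
            _accum(x, inv * (dxh - m1 - xhat * m2))
        else:
            _accum(x, dxh * inv)

    return Tensor._make(y, (x, gamma, beta), bwd)
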