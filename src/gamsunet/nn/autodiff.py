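"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set needed by the segmentation networks:
2D convolution (with stride, padding, dilation), group normalization,
leaky ReLU / ReLU / sigmoid, 2x2 max pooling, bilinear upsampling,
channel concatenation, global average pooling, elementwise arithmetic
with broadcasting, and a numerically stable binary cross-entropy on
logits.  Graphs are built eagerly; ``Tensor.backward`` runs a
topological sweep.

All floating point work is done in the dtype of the inputs (float32 in
the training pipeline), single threaded, so results are bitwise
reproducible for a fixed seed.

A global FLOP meter can be attached (see :mod:`gamsunet.nn.flops`); when
active, every primitive reports its cost as it executes, which keeps the
analytic cost accounting structurally identical to the executed graph.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np
from numpy.lib.stride_tricks import as_strided

# Active cost meter (None when disabled). Set via gamsunet.nn.flops.
_METER = None


def _tally(kind: str, amount: float) -> None:
    if _METER is not None:
        _METER.add(kind, amount)


class Tensor:
    """A node in the autodiff graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Sugar used by the model code; full operator coverage is not a goal.
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _const(-1.0, self)))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _const(v, like: Tensor) -> Tensor:
    return Tensor(np.asarray(v, dtype=like.data.dtype))


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None or t._parents for t in ts)


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


def _sum_to_shape(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def bwd(g):
        a._accumulate(_sum_to_shape(g, a.data.shape))
        b._accumulate(_sum_to_shape(g, b.data.shape))

    return _make(y, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    y = a.data * b.data

    def bwd(g):
        a._accumulate(_sum_to_shape(g * b.data, a.data.shape))
        b._accumulate(_sum_to_shape(g * a.data, b.data.shape))

    return _make(y, (a, b), bwd)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    y = np.where(mask, x.data, slope * x.data)
    _tally("elementwise", y.size)

    def bwd(g):
        x._accumulate(np.where(mask, g, slope * g))

    return _make(y, (x,), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    y = x.data * mask
    _tally("elementwise", y.size)

    def bwd(g):
        x._accumulate(g * mask)

    return _make(y, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    _tally("elementwise", y.size)

    def bwd(g):
        x._accumulate(g * y * (1.0 - y))

    return _make(y, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial dims of an (N, C, H, W) tensor, keepdims."""
    n, c, h, w = x.data.shape
    y = x.data.mean(axis=(2, 3), keepdims=True)
    _tally("elementwise", x.data.size)

    def bwd(g):
        x._accumulate(np.broadcast_to(g / (h * w), x.data.shape))

    return _make(y, (x,), bwd)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    y = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def bwd(g):
        start = 0
        for t, c in zip(tensors, sizes):
            t._accumulate(g[:, start : start + c])
            start += c

    return _make(y, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dil: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - dil * (kh - 1) - 1) // stride + 1
    wo = (w + 2 * pad - dil * (kw - 1) - 1) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(f"convolution output collapsed for input {x.shape}")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    s0, s1, s2, s3 = xp.strides
    cols = as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2 * dil, s3 * dil, s2 * stride, s3 * stride),
    )
    cols = np.ascontiguousarray(cols).reshape(n, c * kh * kw, ho * wo)
    return cols, ho, wo


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, dil, ho, wo):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        hi = i * dil
        for j in range(kw):
            wj = j * dil
            dxp[:, :, hi : hi + ho * stride : stride, wj : wj + wo * stride : stride] += d6[:, :, i, j]
    if pad:
        return dxp[:, :, pad : h + pad, pad : w + pad]
    return dxp


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2D convolution; weight is (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.data.shape[1]} channels, weight expects {cin}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding, dilation)
    wm = weight.data.reshape(cout, cin * kh * kw)
    y = np.matmul(wm, cols)  # (N, Cout, Ho*Wo)
    if bias is not None:
        y = y + bias.data.reshape(1, cout, 1)
    n = x.data.shape[0]
    y = y.reshape(n, cout, ho, wo)
    _tally("mac", float(kh * kw * cin * cout) * ho * wo * n)

    def bwd(g):
        gm = g.reshape(n, cout, ho * wo)
        if weight.requires_grad or weight._parents:
            dW = np.tensordot(gm, cols, axes=([0, 2], [0, 2]))
            weight._accumulate(dW.reshape(weight.data.shape))
        if bias is not None:
            bias._accumulate(gm.sum(axis=(0, 2)))
        dcols = np.matmul(wm.T, gm)
        dx = _col2im(dcols, x.data.shape, kh, kw, stride, padding, dilation, ho, wo)
        x._accumulate(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(y, parents, bwd)


# ---------------------------------------------------------------------------
# normalization / pooling / resampling
# ---------------------------------------------------------------------------

def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    n, c, h, w = x.data.shape
    if c % groups:
        raise ValueError(f"group_norm: {c} channels not divisible into {groups} groups")
    m = (c // groups) * h * w
    xg = x.data.reshape(n, groups, m)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    gam = gamma.data.reshape(1, c, 1, 1)
    y = xhat * gam + beta.data.reshape(1, c, 1, 1)
    _tally("elementwise", y.size)

    def bwd(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        dxhat = (g * gam).reshape(n, groups, m)
        xh = xhat.reshape(n, groups, m)
        t1 = dxhat.mean(axis=2, keepdims=True)
        t2 = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = (dxhat - t1 - xh * t2) * inv
        x._accumulate(dx.reshape(n, c, h, w))

    return _make(y, (x, gamma, beta), bwd)


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 requires even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    xw = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = xw.argmax(axis=4)
    y = np.take_along_axis(xw, idx[..., None], axis=4)[..., 0]
    _tally("elementwise", y.size)

    def bwd(g):
        dxw = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(dxw, idx[..., None], g[..., None], axis=4)
        dx = dxw.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(dx)

    return _make(y, (x,), bwd)


_BILINEAR_CACHE: dict[int, np.ndarray] = {}


def _bilinear_matrix(n_in: int, dtype) -> np.ndarray:
    """(2n x n) linear map realizing x2 bilinear upsampling, half-pixel centers."""
    key = n_in
    m = _BILINEAR_CACHE.get(key)
    if m is None:
        m = np.zeros((2 * n_in, n_in))
        for i in range(2 * n_in):
            src = (i + 0.5) / 2.0 - 0.5
            i0 = int(math.floor(src))
            frac = src - i0
            i0c = min(max(i0, 0), n_in - 1)
            i1c = min(max(i0 + 1, 0), n_in - 1)
            m[i, i0c] += 1.0 - frac
            m[i, i1c] += frac
        _BILINEAR_CACHE[key] = m
    return m.astype(dtype, copy=False)


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    mh = _bilinear_matrix(h, x.data.dtype)
    mw = _bilinear_matrix(w, x.data.dtype)
    y = np.matmul(np.matmul(mh, x.data), mw.T)
    _tally("elementwise", y.size)

    def bwd(g):
        x._accumulate(np.matmul(np.matmul(mh.T, g), mw))

    return _make(y, (x,), bwd)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable in logit space."""
    z = logits.data
    t = np.asarray(target, dtype=z.dtype)
    if t.shape != z.shape:
        raise ValueError(f"target shape {t.shape} != logits shape {z.shape}")
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    y = np.asarray(loss.mean(), dtype=z.dtype)
    _tally("elementwise", z.size)

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g * (p - t) / z.size)

    return _make(y, (logits,), bwd)
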