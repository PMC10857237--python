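"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers the operation that produced it.  ``Tensor.backward()`` walks the
graph in reverse topological order and accumulates gradients.  Only the
operations needed by the segmentation models are provided (elementwise
arithmetic, matmul, 2-D convolutions, pooling, bilinear upsampling,
reductions, concatenation and a few activations).

Convolutions are stride-1 with symmetric zero padding, which is all the
encoder/decoder architecture requires; downsampling is done by max-pooling
and upsampling by a fixed bilinear operator, so every convolution gradient
can itself be expressed as a convolution with a flipped kernel.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "exp",
    "log",
    "sigmoid",
    "relu",
    "gelu",
    "clip",
    "tensor_sum",
    "tensor_mean",
    "reshape",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "maxpool2x2",
    "upsample_bilinear2x",
    "sqrt",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate closures as we go; leaves keep their grad
            node._backward = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other, self.dtype))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other, self.dtype))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, as_tensor(np.asarray(-1, dtype=self.dtype)))

    def __sub__(self, other):
        return add(self, -as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return add(as_tensor(other, self.dtype), -self)

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)
        return mul(self, _reciprocal(other))

    def __rtruediv__(self, other):
        return mul(as_tensor(other, self.dtype), _reciprocal(self))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other, self.dtype))

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    elif dtype is not None and not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    return Tensor(arr)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents: Sequence[Tensor], backward: Callable | None) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  _parents=tuple(p for p in parents if p.requires_grad) if req else (),
                  _backward=backward if req else None)


# ---------------------------------------------------------------------------
# elementwise and linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def _reciprocal(a: Tensor) -> Tensor:
    out_data = 1.0 / a.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(-g * out_data * out_data)

    return _make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / out_data)

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided formulation
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), backward)


# plain Python floats: NumPy scalar constants would promote float32 graphs
_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    out_data = x * cdf

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        a._accumulate(g * (cdf + x * pdf))

    return _make(out_data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    out_data = np.clip(a.data, lo, hi)

    def backward(g):
        a._accumulate(g * ((a.data >= lo) & (a.data <= hi)))

    return _make(out_data, (a,), backward)


def tensor_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % a.data.ndim for i in ax)
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), backward)


def tensor_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    s = tensor_sum(a, axis=axis, keepdims=keepdims)
    return mul(s, as_tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# spatial operations (NCHW layout)
# ---------------------------------------------------------------------------

def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    """Zero-pad the trailing two axes (faster than np.pad for this case)."""
    if p == 0:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=x.dtype)
    out[:, :, p:p + h, p:p + w] = x
    return out


def _conv2d_raw(x: np.ndarray, w: np.ndarray, padding: int,
                xp: np.ndarray | None = None) -> np.ndarray:
    """Stride-1 cross-correlation of (N,C,H,W) with (O,C,kh,kw).

    Computed as a sum over kernel offsets: each tap is a (O,C) channel
    matmul against a shifted view of the padded input.  This avoids the
    large im2col buffer and keeps every matmul BLAS-friendly.
    """
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    if xp is None:
        xp = _pad2d(x, padding)
    ho = h + 2 * padding - kh + 1
    wo = wd + 2 * padding - kw + 1
    out = np.zeros((n, o, ho, wo), dtype=x.dtype)
    for di in range(kh):
        for dj in range(kw):
            xs = xp[:, :, di:di + ho, dj:dj + wo]
            out += np.tensordot(xs, w[:, :, di, dj], axes=([1], [1])) \
                     .transpose(0, 3, 1, 2)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Full 2-D convolution (cross-correlation), stride 1.

    ``w`` has shape (out_channels, in_channels, kh, kw); ``b`` broadcasts
    over the channel axis.
    """
    if x.data.shape[1] != w.data.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]}, "
            f"kernel expects {w.data.shape[1]}")
    xp = _pad2d(x.data, padding)
    out_data = _conv2d_raw(x.data, w.data, padding, xp=xp)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    kh, kw = w.data.shape[2], w.data.shape[3]

    def backward(g):
        n, c, h, wd = x.data.shape
        ho, wo = g.shape[2], g.shape[3]
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            gmat = g.reshape(n, g.shape[1], -1)
            for di in range(kh):
                for dj in range(kw):
                    xs = np.ascontiguousarray(
                        xp[:, :, di:di + ho, dj:dj + wo]).reshape(n, c, -1)
                    gw[:, :, di, dj] = np.einsum("nox,ncx->oc", gmat, xs,
                                                 optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros((n, c, h + 2 * padding, wd + 2 * padding),
                           dtype=g.dtype)
            for di in range(kh):
                for dj in range(kw):
                    gxp[:, :, di:di + ho, dj:dj + wo] += np.tensordot(
                        g, w.data[:, :, di, dj], axes=([1], [0])) \
                        .transpose(0, 3, 1, 2)
            x._accumulate(gxp[:, :, padding:padding + h, padding:padding + wd])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def _depthwise_raw(x: np.ndarray, w: np.ndarray, padding: int,
                   xp: np.ndarray | None = None) -> np.ndarray:
    """Per-channel correlation via the same shift-and-add scheme."""
    n, c, h, wd = x.shape
    kh, kw = w.shape[1], w.shape[2]
    if xp is None:
        xp = _pad2d(x, padding)
    ho = h + 2 * padding - kh + 1
    wo = wd + 2 * padding - kw + 1
    out = np.zeros((n, c, ho, wo), dtype=x.dtype)
    for di in range(kh):
        for dj in range(kw):
            out += w[None, :, di, dj, None, None] * xp[:, :, di:di + ho,
                                                       dj:dj + wo]
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     padding: int = 0) -> Tensor:
    """Per-channel (grouped, groups = C) convolution: w has shape (C, kh, kw)."""
    if x.data.shape[1] != w.data.shape[0]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]}, "
            f"depthwise kernel has {w.data.shape[0]}")
    xp = _pad2d(x.data, padding)
    out_data = _depthwise_raw(x.data, w.data, padding, xp=xp)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    kh, kw = w.data.shape[1], w.data.shape[2]

    def backward(g):
        n, c, h, wd = x.data.shape
        ho, wo = g.shape[2], g.shape[3]
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for di in range(kh):
                for dj in range(kw):
                    gw[:, di, dj] = (g * xp[:, :, di:di + ho, dj:dj + wo]) \
                        .sum(axis=(0, 2, 3))
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros((n, c, h + 2 * padding, wd + 2 * padding),
                           dtype=g.dtype)
            for di in range(kh):
                for dj in range(kw):
                    gxp[:, :, di:di + ho, dj:dj + wo] += \
                        w.data[None, :, di, dj, None, None] * g
            x._accumulate(gxp[:, :, padding:padding + h, padding:padding + wd])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2) \
                   .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gx = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
               .reshape(n, c, h, w)
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


_INTERP_CACHE: dict[tuple[int, int, str], np.ndarray] = {}


def _interp_matrix(n_in: int, scale: int, dtype) -> np.ndarray:
    """1-D bilinear interpolation matrix (scale*n_in, n_in), half-pixel centers."""
    key = (n_in, scale, np.dtype(dtype).str)
    m = _INTERP_CACHE.get(key)
    if m is None:
        n_out = n_in * scale
        src = (np.arange(n_out) + 0.5) / scale - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        t = src - i0
        m = np.zeros((n_out, n_in), dtype=dtype)
        m[np.arange(n_out), i0] += 1 - t
        m[np.arange(n_out), i1] += t
        _INTERP_CACHE[key] = m
    return m


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalization over axes (0, 2, 3).

    Returns (output, batch_mean, batch_var) — the batch statistics let the
    caller maintain running averages.  The backward pass uses the closed
    form for the gradient through the batch statistics:

        dx = inv_std * gamma * (g - mean(g) - xhat * mean(g * xhat))

    with the means taken per channel over (N, H, W).
    """
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    var = x.data.var(axis=(0, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gg = g * gamma.data.reshape(1, -1, 1, 1)
            m1 = gg.mean(axis=(0, 2, 3), keepdims=True)
            m2 = (gg * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x._accumulate(inv * (gg - m1 - xhat * m2))

    out = _make(out_data, (x, gamma, beta), backward)
    return out, mu.ravel(), var.ravel()


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    a = _interp_matrix(h, 2, x.data.dtype)
    bmat = _interp_matrix(w, 2, x.data.dtype)
    out_data = np.einsum("ph,qw,nchw->ncpq", a, bmat, x.data, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("ph,qw,ncpq->nchw", a, bmat, g, optimize=True))

    return _make(out_data, (x,), backward)
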