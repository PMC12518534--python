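"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core of the package: a small tape-based autodiff
engine providing exactly the primitives the segmentation network needs
(dense/batched matmul, 2D convolution with stride/padding and depthwise
groups, layer normalization, softmax, GELU/sigmoid, bilinear upsampling,
adaptive average pooling, shape ops). Gradients are accumulated by a
topological backward sweep, micrograd-style, but over whole ndarrays.

Two global contexts matter:

* :func:`no_grad` — disables graph construction (inference / profiling).
* :func:`flop_counter` — while active, every conv / matmul primitive adds
  its multiply-accumulate count to the enclosing counter. One MAC is
  counted as one FLOP when reporting GFLOPs (the convention used by the
  common profilers that segmentation papers quote budgets from).
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "is_grad_enabled",
    "flop_counter",
    "concat",
    "matmul",
    "softmax",
    "layer_norm",
    "gelu",
    "relu",
    "sigmoid",
    "clipped_log",
    "conv2d",
    "upsample_bilinear",
    "adaptive_avg_pool2d",
]

_GRAD_ENABLED = True
_FLOP_STACK: list[dict] = []


@contextlib.contextmanager
def no_grad():
    """Context manager disabling autodiff graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def flop_counter():
    """Collect multiply-accumulate counts of conv/matmul primitives.

    Yields a dict with keys ``macs`` (total) and ``by_op`` (per primitive
    kind). Elementwise ops, normalizations and interpolation are excluded,
    matching the MAC-counting convention of standard profilers.
    """
    rec = {"macs": 0, "by_op": {}}
    _FLOP_STACK.append(rec)
    try:
        yield rec
    finally:
        _FLOP_STACK.pop()


def _add_macs(kind: str, n: int) -> None:
    for rec in _FLOP_STACK:
        rec["macs"] += int(n)
        rec["by_op"][kind] = rec["by_op"].get(kind, 0) + int(n)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype.kind == "f" else np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev: tuple = ()

    # -- plumbing ---------------------------------------------------------
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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only valid for scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def build(t: Tensor):
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        build(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and node._prev:
                # free intermediate grads lazily? keep simple: retain.
                pass

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g), "add")

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g), "sub")

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        return self * -1.0

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda g, a, b: (g * b, g * a), "mul")

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide,
            lambda g, a, b: (g / b, -g * a / (b * b)), "div",
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(np.power(self.data, p), (self,))
        if out.requires_grad:
            a = self.data

            def bwd(g):
                _accum(self, g * p * np.power(a, p - 1))
            out._backward = bwd
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            shape = self.data.shape

            def bwd(g):
                buf = np.zeros(shape, dtype=g.dtype)
                np.add.at(buf, idx, g)
                _accum(self, buf)
            out._backward = bwd
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape

            def bwd(g):
                if axis is not None and not keepdims:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    ax = tuple(a % len(shape) for a in ax)
                    g = np.expand_dims(g, ax)
                _accum(self, np.broadcast_to(g, shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            orig = self.data.shape

            def bwd(g):
                _accum(self, g.reshape(orig))
            out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = _node(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)

            def bwd(g):
                _accum(self, g.transpose(inv))
            out._backward = bwd
        return out

    def exp(self):
        out = _node(np.exp(self.data), (self,))
        if out.requires_grad:
            y = out.data

            def bwd(g):
                _accum(self, g * y)
            out._backward = bwd
        return out

    def sqrt(self):
        return self ** 0.5


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(isinstance(p, Tensor) and p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype, copy=True)
    else:
        t.grad += g


def _binary(a, b, fwd, bwd_fn, name) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _node(fwd(a.data, b.data), (a, b))
    if out.requires_grad:
        ad, bd = a.data, b.data

        def bwd(g):
            ga, gb = bwd_fn(g, ad, bd)
            if a.requires_grad:
                _accum(a, _unbroadcast(ga, ad.shape))
            if b.requires_grad:
                _accum(b, _unbroadcast(gb, bd.shape))
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data
    # MACs: product over output shape times inner dim
    inner = a.data.shape[-1]
    _add_macs("matmul", int(np.prod(out_data.shape)) * inner)
    out = _node(out_data, (a, b))
    if out.requires_grad:
        ad, bd = a.data, b.data

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(bd, -1, -2)
                _accum(a, _unbroadcast(ga, ad.shape))
            if b.requires_grad:
                gb = np.swapaxes(ad, -1, -2) @ g
                _accum(b, _unbroadcast(gb, bd.shape))
        out._backward = bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
                _accum(t, gpart)
        out._backward = bwd
    return out


def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    # guard fully-masked (-inf) rows: exp(-inf - -inf) -> exp(nan); shift only finite max
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, (x,))
    if out.requires_grad:
        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            _accum(x, y * (g - dot))
        out._backward = bwd
    return out


def layer_norm(x, weight: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    x = as_tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _node(xhat * weight.data + bias.data, (x, weight, bias))
    if out.requires_grad:
        n = x.data.shape[-1]

        def bwd(g):
            if weight.requires_grad:
                _accum(weight, (g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            if bias.requires_grad:
                _accum(bias, g.sum(axis=tuple(range(g.ndim - 1))))
            if x.requires_grad:
                gx = g * weight.data
                gxh = gx * inv
                t1 = gxh.mean(axis=-1, keepdims=True)
                t2 = (gxh * xhat).mean(axis=-1, keepdims=True)
                _accum(x, gxh - t1 - xhat * t2)
        out._backward = bwd
    return out


def gelu(x) -> Tensor:
    x = as_tensor(x)
    xd = x.data
    cdf = 0.5 * (1.0 + erf(xd / np.sqrt(2.0)))
    out = _node(xd * cdf, (x,))
    if out.requires_grad:
        def bwd(g):
            pdf = np.exp(-0.5 * xd * xd) / np.sqrt(2.0 * np.pi)
            _accum(x, g * (cdf + xd * pdf))
        out._backward = bwd
    return out


def relu(x) -> Tensor:
    x = as_tensor(x)
    out = _node(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        mask = x.data > 0

        def bwd(g):
            _accum(x, g * mask)
        out._backward = bwd
    return out


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(y, (x,))
    if out.requires_grad:
        def bwd(g):
            _accum(x, g * y * (1.0 - y))
        out._backward = bwd
    return out


def clipped_log(x, eps: float = 1e-12) -> Tensor:
    """log(max(x, eps)) with zero gradient below the clamp."""
    x = as_tensor(x)
    xc = np.maximum(x.data, eps)
    out = _node(np.log(xc), (x,))
    if out.requires_grad:
        mask = x.data >= eps

        def bwd(g):
            _accum(x, g * mask / xc)
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# conv / pooling / resampling
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2D convolution (cross-correlation), NCHW layout.

    ``groups`` must be 1 (dense) or equal to the input channel count
    (depthwise, with ``w`` of shape (C, 1, kh, kw)).
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Ci, H, W = x.data.shape
    Co, Cig, kh, kw = w.data.shape
    depthwise = groups != 1
    if depthwise:
        if groups != Ci or Co != Ci or Cig != 1:
            raise ValueError("grouped conv supported only as depthwise (groups == C)")
    elif Cig != Ci:
        raise ValueError(f"weight expects {Cig} input channels, got {Ci}")
    s, p = int(stride), int(padding)
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    out_data = np.zeros((B, Co, Ho, Wo), dtype=x.data.dtype)
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape(1, Co, 1, 1)
    # offset-accumulation form: one (BLAS) contraction per kernel tap
    views = []
    for i in range(kh):
        row = []
        for j in range(kw):
            xs = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
            row.append(xs)
            if depthwise:
                out_data += xs * w.data[:, 0, i, j].reshape(1, Ci, 1, 1)
            else:
                flat = xs.transpose(1, 0, 2, 3).reshape(Ci, -1)
                out_data += (w.data[:, :, i, j] @ flat).reshape(Co, B, Ho, Wo).transpose(1, 0, 2, 3)
        views.append(row)
    _add_macs("conv2d", B * Co * Ho * Wo * (Ci // groups) * kh * kw)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents)
    if out.requires_grad:
        def bwd(g):
            if b is not None and b.requires_grad:
                _accum(b, g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        xs = views[i][j]
                        if depthwise:
                            gw[:, 0, i, j] = (g * xs).sum(axis=(0, 2, 3))
                        else:
                            gw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                _accum(w, gw)
            if x.requires_grad:
                gxp = np.zeros((B, Ci, H + 2 * p, W + 2 * p), dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        tgt = gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
                        if depthwise:
                            tgt += g * w.data[:, 0, i, j].reshape(1, Ci, 1, 1)
                        else:
                            gflat = g.transpose(1, 0, 2, 3).reshape(Co, -1)
                            tgt += (w.data[:, :, i, j].T @ gflat).reshape(Ci, B, Ho, Wo).transpose(1, 0, 2, 3)
                _accum(x, gxp[:, :, p:p + H, p:p + W] if p else gxp)
        out._backward = bwd
    return out


def _bilinear_weights(n_out: int, n_in: int, scale: float):
    o = np.arange(n_out)
    c = (o + 0.5) / scale - 0.5
    c = np.clip(c, 0, n_in - 1)
    i0 = np.floor(c).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = c - i0
    return i0, i1, w1


def upsample_bilinear(x, scale: int) -> Tensor:
    """Bilinear upsampling by an integer factor (align_corners=False)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    Ho, Wo = H * scale, W * scale
    hi0, hi1, hw = _bilinear_weights(Ho, H, scale)
    wi0, wi1, ww = _bilinear_weights(Wo, W, scale)
    rows = x.data[:, :, hi0, :] * (1 - hw)[None, None, :, None] + x.data[:, :, hi1, :] * hw[None, None, :, None]
    out_data = rows[:, :, :, wi0] * (1 - ww)[None, None, None, :] + rows[:, :, :, wi1] * ww[None, None, None, :]
    out = _node(out_data, (x,))
    if out.requires_grad:
        def bwd(g):
            grows = np.zeros((B, C, Ho, W), dtype=g.dtype)
            gm = np.moveaxis(grows, 3, 0)  # (W, B, C, Ho)
            gsrc = np.moveaxis(g, 3, 0)    # (Wo, B, C, Ho)
            np.add.at(gm, wi0, gsrc * (1 - ww)[:, None, None, None])
            np.add.at(gm, wi1, gsrc * ww[:, None, None, None])
            gx = np.zeros((B, C, H, W), dtype=g.dtype)
            gxm = np.moveaxis(gx, 2, 0)    # (H, B, C, W)
            gr = np.moveaxis(grows, 2, 0)  # (Ho, B, C, W)
            np.add.at(gxm, hi0, gr * (1 - hw)[:, None, None, None])
            np.add.at(gxm, hi1, gr * hw[:, None, None, None])
            _accum(x, gx)
        out._backward = bwd
    return out


def adaptive_avg_pool2d(x, out_size: int) -> Tensor:
    """Average pool (B,C,H,W) to (B,C,p,p); falls back to the largest
    divisor of each spatial dim not exceeding ``out_size``."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape

    def eff(n):
        p = min(out_size, n)
        while n % p:
            p -= 1
        return p

    ph, pw = eff(H), eff(W)
    fh, fw = H // ph, W // pw
    out_data = x.data.reshape(B, C, ph, fh, pw, fw).mean(axis=(3, 5))
    out = _node(out_data, (x,))
    if out.requires_grad:
        def bwd(g):
            gx = np.broadcast_to(
                g[:, :, :, None, :, None] / (fh * fw), (B, C, ph, fh, pw, fw)
            ).reshape(B, C, H, W)
            _accum(x, gx.copy())
        out._backward = bwd
    return out
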