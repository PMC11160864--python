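"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine providing exactly the primitives the
distillation framework needs: broadcasting arithmetic, reductions,
``exp``/``log``/``abs``/``relu``, strided 2-D convolution (im2col),
bilinear/nearest spatial resampling, concatenation, and an Adam
optimizer with cosine-annealed learning rate.  All computation is in
float64 for reproducibility and so that analytic test fixtures hold to
tight tolerances.

Gradients are built lazily: an operation only records a backward
closure when at least one input requires gradients, so forward passes
through frozen networks carry no graph.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float64


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        # closures never mutate grad arrays in place, so aliasing is safe
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def flatten(self):
        return reshape(self, (-1,))

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def abs(self):
        return tabs(self)

    def relu(self):
        return relu(self)

    def sqrt(self):
        return power(self, 0.5)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable | None) -> Tensor:
    needs = any(p.requires_grad for p in parents)
    if needs:
        return Tensor(data, requires_grad=True,
                      parents=tuple(parents), backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise / broadcasting operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data / b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out_data, (a, b), bw)


def power(a, exponent: float) -> Tensor:
    a = astensor(a)
    out_data = a.data ** exponent

    def bw(g):
        if a.requires_grad:
            a._accum(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), bw)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return _make(out_data, (a,), bw)


def log(a) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(out_data, (a,), bw)


def tabs(a) -> Tensor:
    a = astensor(a)
    out_data = np.abs(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * np.sign(a.data))

    return _make(out_data, (a,), bw)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(out_data, (a,), bw)


def maximum_scalar(a, c: float) -> Tensor:
    """max(a, c) elementwise; gradient flows only where a > c."""
    a = astensor(a)
    mask = a.data > c
    out_data = np.where(mask, a.data, c)

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(out_data, (a,), bw)


# ---------------------------------------------------------------------------
# reductions, shaping, indexing
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).astype(DTYPE, copy=True))
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).astype(DTYPE, copy=True))

    return _make(out_data, (a,), bw)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def bw(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), bw)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

    return _make(out_data, (a,), bw)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(out_data, tuple(tensors), bw)


# ---------------------------------------------------------------------------
# softmax / log-sum-exp
# ---------------------------------------------------------------------------

def softmax(a, axis: int = 1) -> Tensor:
    """Numerically stable softmax along `axis` (max-shift is detached)."""
    a = astensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(a - shift)
    return div(e, tsum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# 2-D convolution (im2col) and spatial resampling
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW convolution. `w` is (F, C, kh, kw); `b` is (F,) or None."""
    x, w = astensor(x), astensor(w)
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c2}")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wd + 2 * padding - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=DTYPE)
    for ki in range(kh):
        for kj in range(kw):
            cols[:, :, ki, kj] = xp[:, :, ki:ki + stride * oh:stride,
                                    kj:kj + stride * ow:stride]
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    w2 = w.data.reshape(f, c * kh * kw)
    out = np.matmul(w2, cols2)          # (n, f, oh*ow)
    if b is not None:
        b = astensor(b)
        out = out + b.data[:, None]
    out_data = out.reshape(n, f, oh, ow)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gg = g.reshape(n, f, oh * ow)
        if b is not None and b.requires_grad:
            b._accum(gg.sum(axis=(0, 2)))
        if w.requires_grad:
            # matmul on the transposed view avoids re-copying the cols buffer
            dw2 = np.matmul(gg, cols2.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw2.reshape(w.data.shape))
        if x.requires_grad:
            dcols2 = np.matmul(w2.T, gg)  # (n, q, p)
            dcols = dcols2.reshape(n, c, kh, kw, oh, ow)
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki:ki + stride * oh:stride,
                        kj:kj + stride * ow:stride] += dcols[:, :, ki, kj]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return _make(out_data, parents, bw)


_RESIZE_CACHE: dict[tuple[int, int, str], np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int, mode: str) -> np.ndarray:
    """Row-stochastic (n_out, n_in) 1-D resampling matrix, half-pixel centers."""
    key = (n_in, n_out, mode)
    mat = _RESIZE_CACHE.get(key)
    if mat is not None:
        return mat
    mat = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        if mode == "nearest":
            j = min(n_in - 1, max(0, int(math.floor(src + 0.5))))
            mat[i, j] = 1.0
        else:  # bilinear
            src = min(max(src, 0.0), n_in - 1.0)
            j0 = int(math.floor(src))
            j1 = min(j0 + 1, n_in - 1)
            t = src - j0
            mat[i, j0] += 1.0 - t
            mat[i, j1] += t
    _RESIZE_CACHE[key] = mat
    return mat


def resize2d(x, size: tuple[int, int], mode: str = "bilinear") -> Tensor:
    """Resample the trailing two axes of `x` to `size`.

    Bilinear (default) uses half-pixel-aligned separable linear
    interpolation, which preserves constants exactly; "nearest" is also
    available.  Works on arrays of any leading shape (..., H, W).
    """
    x = astensor(x)
    h, w = x.data.shape[-2:]
    oh, ow = size
    if (h, w) == (oh, ow):
        return x
    ah = _resize_matrix(h, oh, mode)
    aw = _resize_matrix(w, ow, mode)
    out_data = np.matmul(np.matmul(ah, x.data), aw.T)

    def bw(g):
        if x.requires_grad:
            x._accum(np.matmul(np.matmul(ah.T, g), aw))

    return _make(out_data, (x,), bw)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with optional cosine-annealed learning rate.

    `lr` is the initial rate; if `min_lr` and `total_steps` are given,
    `step_schedule()` advances a cosine decay from `lr` to `min_lr`.
    """

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 min_lr: float | None = None, total_steps: int | None = None):
        self.params = [p for p in params if p.requires_grad]
        self.lr0 = lr
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.min_lr = min_lr
        self.total_steps = total_steps
        self._sched_step = 0
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def step_schedule(self) -> None:
        """Advance the cosine annealing schedule by one unit (e.g. an epoch)."""
        if self.min_lr is None or self.total_steps is None or self.total_steps <= 1:
            return
        self._sched_step = min(self._sched_step + 1, self.total_steps - 1)
        frac = self._sched_step / (self.total_steps - 1)
        self.lr = self.min_lr + 0.5 * (self.lr0 - self.min_lr) * (1 + math.cos(math.pi * frac))
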