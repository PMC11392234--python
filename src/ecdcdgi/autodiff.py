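"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides exactly the primitives the encoder and readout need
(dense/sparse matrix products, elementwise nonlinearities, row
normalization, layer normalization, concatenation, reductions) as a small
define-by-run tape.  Every public function is polymorphic: called on plain
``ndarray`` inputs it computes the forward value directly, called on (or
with) :class:`Tensor` inputs it records the operation so :meth:`Tensor.backward`
can later accumulate exact gradients.  This keeps a single source of truth
for the forward mathematics across the training path, the diagnostic path
and the test oracles.

All computation is in double precision.  Gradients are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "log",
    "exp",
    "clip",
    "concat",
    "row_normalize",
    "layer_norm",
    "const_matmul",
    "tsum",
    "transpose",
    "div",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (undo NumPy broadcasting)."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation tape: a float64 array plus gradient slots."""

    __slots__ = ("data", "grad", "requires_grad", "_links")

    # defer mixed ndarray/Tensor arithmetic to the Tensor operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        # list of (parent Tensor, fn mapping upstream grad -> parent grad)
        self._links: list[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = []

    # -- introspection ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable parent."""
        if grad is None:
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
            for parent, _ in node._links:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._links:
                g = fn(node.grad)
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators -------------------------------------------------------

    def __add__(self, other):
        return _binary(
            self, other, np.add,
            lambda a, b, g: _unbroadcast(g, a.shape),
            lambda a, b, g: _unbroadcast(g, b.shape),
        )

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(
            self, other, np.subtract,
            lambda a, b, g: _unbroadcast(g, a.shape),
            lambda a, b, g: _unbroadcast(-g, b.shape),
        )

    def __rsub__(self, other):
        return _binary(
            other, self, np.subtract,
            lambda a, b, g: _unbroadcast(g, a.shape),
            lambda a, b, g: _unbroadcast(-g, b.shape),
        )

    def __neg__(self):
        return _unary(self, np.negative, lambda x, g: -g)

    def __mul__(self, other):
        return _binary(
            self, other, np.multiply,
            lambda a, b, g: _unbroadcast(g * b, a.shape),
            lambda a, b, g: _unbroadcast(g * a, b.shape),
        )

    __rmul__ = __mul__

    def __matmul__(self, other):
        return _binary(
            self, other, np.matmul,
            lambda a, b, g: g @ b.T,
            lambda a, b, g: a.T @ g,
        )

    def __rmatmul__(self, other):
        return _binary(
            other, self, np.matmul,
            lambda a, b, g: g @ b.T,
            lambda a, b, g: a.T @ g,
        )

    @property
    def T(self) -> "Tensor":
        return transpose(self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, links) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p, _ in links))
    if out.requires_grad:
        out._links = [(p, fn) for p, fn in links if _has_grad_path(p)]
    return out


def _has_grad_path(t: Tensor) -> bool:
    return t.requires_grad or bool(t._links)


def _unary(x, fwd, grad_fn):
    if not isinstance(x, Tensor):
        return fwd(np.asarray(x, dtype=np.float64))
    data = fwd(x.data)
    return _make(data, [(x, lambda g, xd=x.data: grad_fn(xd, g))])


def _binary(a, b, fwd, grad_a, grad_b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return fwd(np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64))
    ta, tb = _wrap(a), _wrap(b)
    data = fwd(ta.data, tb.data)
    ad, bd = ta.data, tb.data
    return _make(data, [
        (ta, lambda g: grad_a(ad, bd, g)),
        (tb, lambda g: grad_b(ad, bd, g)),
    ])


# -- elementwise nonlinearities -----------------------------------------


def relu(x):
    """Elementwise max(x, 0)."""
    return _unary(x, lambda v: np.maximum(v, 0.0), lambda v, g: g * (v > 0))


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    def fwd(v):
        out = np.empty_like(v)
        pos = v >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
        ev = np.exp(v[~pos])
        out[~pos] = ev / (1.0 + ev)
        return out

    if not isinstance(x, Tensor):
        return fwd(np.asarray(x, dtype=np.float64))
    data = fwd(x.data)
    return _make(data, [(x, lambda g, y=data: g * y * (1.0 - y))])


def log(x):
    """Natural logarithm."""
    return _unary(x, np.log, lambda v, g: g / v)


def exp(x):
    """Elementwise exponential."""
    if not isinstance(x, Tensor):
        return np.exp(np.asarray(x, dtype=np.float64))
    data = np.exp(x.data)
    return _make(data, [(x, lambda g, y=data: g * y)])


def clip(x, lo: float, hi: float):
    """Clamp values into [lo, hi]; the gradient is zero where clamped."""
    if not isinstance(x, Tensor):
        return np.clip(np.asarray(x, dtype=np.float64), lo, hi)
    data = np.clip(x.data, lo, hi)
    inside = (x.data > lo) & (x.data < hi)
    return _make(data, [(x, lambda g, m=inside: g * m)])


# -- structural ops ------------------------------------------------------


def transpose(x):
    if not isinstance(x, Tensor):
        return np.asarray(x).T
    return _make(x.data.T, [(x, lambda g: g.T)])


def concat(parts: Sequence, axis: int = 1):
    """Concatenate along ``axis`` (row-wise feature concatenation by default)."""
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate([np.asarray(p, dtype=np.float64) for p in parts], axis=axis)
    tensors = [_wrap(p) for p in parts]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    links = []
    start = 0
    for t in tensors:
        size = t.data.shape[axis]
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(start, start + size)
        links.append((t, lambda g, s=tuple(sl): g[s]))
        start += size
    return _make(data, links)


def tsum(x, axis=None, keepdims: bool = False):
    """Sum reduction with gradient broadcast back to the input shape."""
    if not isinstance(x, Tensor):
        return np.asarray(x, dtype=np.float64).sum(axis=axis, keepdims=keepdims)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def grad_fn(g, shape=x.data.shape):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, shape).copy()

    return _make(np.asarray(data, dtype=np.float64), [(x, grad_fn)])


def div(a, b):
    """Elementwise division a / b."""
    return _binary(
        a, b, np.divide,
        lambda ad, bd, g: _unbroadcast(g / bd, ad.shape),
        lambda ad, bd, g: _unbroadcast(-g * ad / (bd * bd), bd.shape),
    )


def row_normalize(x):
    """Divide each row by its sum, producing a row-stochastic matrix."""
    if not isinstance(x, Tensor):
        v = np.asarray(x, dtype=np.float64)
        return v / v.sum(axis=1, keepdims=True)
    s = x.data.sum(axis=1, keepdims=True)
    data = x.data / s

    def grad_fn(g, xd=x.data, sd=s):
        # d(x_ij/s_i)/dx_ik = delta_jk/s_i - x_ij/s_i^2
        return g / sd - ((g * xd).sum(axis=1, keepdims=True) / (sd * sd))

    return _make(data, [(x, grad_fn)])


def const_matmul(M, x):
    """Product ``M @ x`` where ``M`` is a constant (possibly sparse) matrix."""
    if not isinstance(x, Tensor):
        out = M @ np.asarray(x, dtype=np.float64)
        return np.asarray(out)
    data = np.asarray(M @ x.data)
    MT = M.T if sp.issparse(M) else np.asarray(M).T
    return _make(data, [(x, lambda g: np.asarray(MT @ g))])


def layer_norm(x, gain, shift, eps: float = 1e-5):
    """Per-row standardization followed by a learned affine map.

    Each row is shifted to zero mean and scaled to unit variance (variance
    computed with the biased 1/d convention, ``eps`` added before the square
    root), then multiplied by ``gain`` and offset by ``shift``.
    """
    if not any(isinstance(v, Tensor) for v in (x, gain, shift)):
        xv = np.asarray(x, dtype=np.float64)
        mu = xv.mean(axis=1, keepdims=True)
        var = xv.var(axis=1, keepdims=True)
        xhat = (xv - mu) / np.sqrt(var + eps)
        return xhat * np.asarray(gain) + np.asarray(shift)

    tx, tg, ts = _wrap(x), _wrap(gain), _wrap(shift)
    xv = tx.data
    d = xv.shape[1]
    mu = xv.mean(axis=1, keepdims=True)
    var = xv.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xv - mu) * inv
    data = xhat * tg.data + ts.data

    def grad_x(g, xh=xhat, iv=inv, gd=tg.data, dd=d):
        gy = g * gd
        return (gy - gy.mean(axis=1, keepdims=True)
                - xh * (gy * xh).mean(axis=1, keepdims=True)) * iv

    return _make(data, [
        (tx, grad_x),
        (tg, lambda g, xh=xhat: _unbroadcast(g * xh, tg.data.shape)),
        (ts, lambda g: _unbroadcast(g, ts.data.shape)),
    ])
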