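"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The whole stack — the cell builder, the radial edge embedding, and both
graph networks — is written against this module so that model outputs are
differentiable end-to-end with respect to both network weights and the
12 crystal parameters.

Every function here accepts plain :class:`numpy.ndarray` (or scalar)
inputs as well as :class:`Tensor`; plain inputs take a fast NumPy path
that records no tape.  Gradients are accumulated by a topological-order
sweep over the recorded tape (``Tensor.backward``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "is_tensor",
    "add",
    "mul",
    "matmul",
    "sin",
    "cos",
    "sqrt",
    "exp",
    "log",
    "log10",
    "tanh",
    "leaky_relu",
    "sum",
    "mean",
    "stack",
    "concat",
    "gather",
    "segment_sum",
    "segment_max",
    "reshape",
    "transpose",
    "maximum_const",
    "minimum_const",
    "layer_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of this (scalar or array) node into the tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many conv layers)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            node._backward(node.grad)

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(other, mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __truediv__(self, other):
        return mul(self, _reciprocal(other))

    def __rtruediv__(self, other):
        return mul(other, _reciprocal(self))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return _power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return _getitem(self, idx)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# ----------------------------------------------------------------------
# elementwise binary ops
# ----------------------------------------------------------------------

def add(a, b):
    if not _any_tensor(a, b):
        return _data(a) + _data(b)
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def mul(a, b):
    if not _any_tensor(a, b):
        return _data(a) * _data(b)
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def _reciprocal(a):
    if not _any_tensor(a):
        return 1.0 / _data(a)
    a = astensor(a)
    out = Tensor(1.0 / a.data, (a,))

    def bw(g):
        a._accum(_unbroadcast(-g / (a.data**2), a.data.shape))

    out._backward = bw
    return out


def _power(a, p: float):
    if not _any_tensor(a):
        return _data(a) ** p
    a = astensor(a)
    out = Tensor(a.data**p, (a,))

    def bw(g):
        a._accum(_unbroadcast(g * p * a.data ** (p - 1), a.data.shape))

    out._backward = bw
    return out


def matmul(a, b):
    if not _any_tensor(a, b):
        return _data(a) @ _data(b)
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        ad, bd = a.data, b.data
        if ad.ndim == 1 and bd.ndim == 2:
            a._accum(g @ bd.T)
            b._accum(np.outer(ad, g))
        elif ad.ndim == 2 and bd.ndim == 1:
            a._accum(np.outer(g, bd))
            b._accum(ad.T @ g)
        elif ad.ndim == 1 and bd.ndim == 1:
            a._accum(g * bd)
            b._accum(g * ad)
        else:
            a._accum(g @ np.swapaxes(bd, -1, -2))
            b._accum(np.swapaxes(ad, -1, -2) @ g)

    out._backward = bw
    return out


# ----------------------------------------------------------------------
# elementwise unary ops
# ----------------------------------------------------------------------

def _unary(a, fn, dfn):
    if not _any_tensor(a):
        return fn(_data(a))
    a = astensor(a)
    out = Tensor(fn(a.data), (a,))

    def bw(g):
        a._accum(g * dfn(a.data, out.data))

    out._backward = bw
    return out


def sin(a):
    return _unary(a, np.sin, lambda x, y: np.cos(x))


def cos(a):
    return _unary(a, np.cos, lambda x, y: -np.sin(x))


def sqrt(a):
    return _unary(a, np.sqrt, lambda x, y: 0.5 / y)


def exp(a):
    return _unary(a, np.exp, lambda x, y: y)


def log(a):
    return _unary(a, np.log, lambda x, y: 1.0 / x)


def log10(a):
    return _unary(a, np.log10, lambda x, y: 1.0 / (x * np.log(10.0)))


def tanh(a):
    return _unary(a, np.tanh, lambda x, y: 1.0 - y**2)


def leaky_relu(a, slope: float = 0.01):
    return _unary(
        a,
        lambda x: np.where(x > 0, x, slope * x),
        lambda x, y: np.where(x > 0, 1.0, slope),
    )


def maximum_const(a, c: float):
    """Elementwise max against a constant (clip floor)."""
    return _unary(
        a,
        lambda x: np.maximum(x, c),
        lambda x, y: np.where(x > c, 1.0, 0.0),
    )


def minimum_const(a, c: float):
    return _unary(
        a,
        lambda x: np.minimum(x, c),
        lambda x, y: np.where(x < c, 1.0, 0.0),
    )


# ----------------------------------------------------------------------
# reductions / shape ops
# ----------------------------------------------------------------------

def sum(a, axis=None, keepdims=False):  # noqa: A001 - mirrors numpy naming
    if not _any_tensor(a):
        return _data(a).sum(axis=axis, keepdims=keepdims)
    a = astensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def bw(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    out._backward = bw
    return out


def mean(a, axis=None, keepdims=False):
    if not _any_tensor(a):
        return _data(a).mean(axis=axis, keepdims=keepdims)
    a = astensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    if not _any_tensor(a):
        return _data(a).reshape(shape)
    a = astensor(a)
    out = Tensor(a.data.reshape(shape), (a,))

    def bw(g):
        a._accum(g.reshape(a.data.shape))

    out._backward = bw
    return out


def transpose(a, axes=None):
    if not _any_tensor(a):
        return np.transpose(_data(a), axes)
    a = astensor(a)
    out = Tensor(np.transpose(a.data, axes), (a,))

    def bw(g):
        inv = None if axes is None else np.argsort(axes)
        a._accum(np.transpose(g, inv))

    out._backward = bw
    return out


def stack(parts, axis=0):
    if not _any_tensor(*parts):
        return np.stack([_data(p) for p in parts], axis=axis)
    parts = [astensor(p) for p in parts]
    out = Tensor(np.stack([p.data for p in parts], axis=axis), tuple(parts))

    def bw(g):
        for i, p in enumerate(parts):
            p._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def concat(parts, axis=0):
    if not _any_tensor(*parts):
        return np.concatenate([_data(p) for p in parts], axis=axis)
    parts = [astensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for i, p in enumerate(parts):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            p._accum(g[tuple(sl)])

    out._backward = bw
    return out


def _getitem(a, idx):
    if not _any_tensor(a):
        return _data(a)[idx]
    a = astensor(a)
    out = Tensor(a.data[idx], (a,))

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    out._backward = bw
    return out


def gather(a, index):
    """Row gather: ``out[k] = a[index[k]]`` with scatter-add backward."""
    index = np.asarray(index, dtype=np.intp)
    if not _any_tensor(a):
        return _data(a)[index]
    a = astensor(a)
    out = Tensor(a.data[index], (a,))

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, index, g)
        a._accum(full)

    out._backward = bw
    return out


def segment_sum(a, segment_ids, num_segments: int):
    """Sum rows of ``a`` into ``num_segments`` buckets (unsorted segments)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    if not _any_tensor(a):
        ad = _data(a)
        out = np.zeros((num_segments,) + ad.shape[1:], dtype=np.float64)
        np.add.at(out, segment_ids, ad)
        return out
    a = astensor(a)
    data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, a.data)
    out = Tensor(data, (a,))

    def bw(g):
        a._accum(g[segment_ids])

    out._backward = bw
    return out


def segment_max(a, segment_ids, num_segments: int):
    """Per-segment max over rows; gradient flows to the argmax rows only.

    Empty segments yield 0 with zero gradient.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    ad = _data(a)
    out_data = np.full((num_segments,) + ad.shape[1:], -np.inf)
    np.maximum.at(out_data, segment_ids, ad)
    empty = ~np.isfinite(out_data)
    out_data = np.where(empty, 0.0, out_data)
    if not _any_tensor(a):
        return out_data
    a = astensor(a)
    # winner mask: a row contributes where it equals the segment max
    winner = (ad == out_data[segment_ids]) & ~empty[segment_ids]
    # break ties: keep first winner per (segment, column)
    order = np.argsort(segment_ids, kind="stable")
    first = np.zeros_like(winner)
    taken = np.zeros((num_segments,) + ad.shape[1:], dtype=bool)
    for row in order:
        seg = segment_ids[row]
        sel = winner[row] & ~taken[seg]
        first[row] = sel
        taken[seg] |= sel
    out = Tensor(out_data, (a,))

    def bw(g):
        a._accum(np.where(first, g[segment_ids], 0.0))

    out._backward = bw
    return out


def layer_norm(x, gain, bias, eps: float = 1e-5):
    """Row-wise layer normalization with learnable gain/bias."""
    mu = mean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = mean(mul(xc, xc), axis=-1, keepdims=True)
    inv = _power(add(var, eps), -0.5)
    return add(mul(mul(xc, inv), gain), bias)
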