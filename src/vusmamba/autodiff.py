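"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`vusmamba.model` is small enough (tens of thousands of
parameters, single-sample training) that a hand-rolled tape plus numpy
kernels is fast enough on one CPU.  The engine supports exactly the
operations the architecture needs: broadcasting arithmetic, matmul,
reshapes/permutations, elementwise nonlinearities, reductions, padding,
slicing, concatenation and a token-order gather used by the directional
scans.  Everything is float64.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims numpy added
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}, name={self.name!r})"

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(_as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, axes: Sequence[int]):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = parents
        out._backward = backward
    return out


# -- primitive ops --------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def power(a, p) -> Tensor:
    a = _as_tensor(a)
    if isinstance(p, Tensor):
        raise TypeError("exponent must be a python scalar")
    data = a.data ** p

    def backward(g):
        a._accum(_unbroadcast(g * p * a.data ** (p - 1), a.shape))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.ndim == 1 and b.ndim == 2:
            a._accum(g @ b.data.T)
            b._accum(np.outer(a.data, g))
        elif a.ndim == 2 and b.ndim == 2:
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)
        else:  # batched: (..., m, k) @ (k, n) or (..., m, k) @ (..., k, n)
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accum(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def silu(a) -> Tensor:
    """x * sigmoid(x)."""
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    data = a.data * s

    def backward(g):
        a._accum(g * (s + a.data * s * (1.0 - s)))

    return _make(data, (a,), backward)


def softplus(a) -> Tensor:
    a = _as_tensor(a)
    data = np.logaddexp(0.0, a.data)

    def backward(g):
        a._accum(g / (1.0 + np.exp(-a.data)))

    return _make(data, (a,), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).copy() if np.ndim(g) else np.full(a.shape, g))
        else:
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape))

    return _make(data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)
    orig = a.shape

    def backward(g):
        a._accum(g.reshape(orig))

    return _make(data, (a,), backward)


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def _idx_has_arrays(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return any(isinstance(i, (np.ndarray, list)) for i in items)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    data = a.data[idx]
    fancy = _idx_has_arrays(idx)

    def backward(g):
        buf = np.zeros(a.shape)
        if fancy:  # repeated indices need unbuffered accumulation
            np.add.at(buf, idx, g)
        else:
            buf[idx] += g
        a._accum(buf)

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _make(data, tuple(ts), backward)


def pad(a, pad_width) -> Tensor:
    """Zero padding; pad_width as in np.pad."""
    a = _as_tensor(a)
    data = np.pad(a.data, pad_width)
    sl = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, a.shape))

    def backward(g):
        a._accum(g[sl])

    return _make(data, (a,), backward)


def take_rows(a, index: np.ndarray) -> Tensor:
    """Reorder rows of a 2-D tensor by a permutation index."""
    a = _as_tensor(a)
    index = np.asarray(index)
    data = a.data[index]

    def backward(g):
        buf = np.zeros(a.shape)
        buf[index] = g  # permutation: rows are unique
        a._accum(buf)

    return _make(data, (a,), backward)


# -- composites ------------------------------------------------------------

def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the trailing (channel) axis."""
    mu = mean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = mean(xc * xc, axis=-1, keepdims=True)
    inv = power(var + eps, -0.5)
    return xc * inv * gamma + beta


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    return shift - log(sum_(exp(shift), axis=axis, keepdims=True))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(x, axis=axis))
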