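"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the differentiable substrate of the package: multilayer perceptrons,
the hybrid losses, and the process models (Lotka-Volterra integrator, flux
mini-model) are all written against the :class:`Tensor` type so that gradients
can flow backwards through an entire network -> process-model -> network
composition, the defining requirement of the physics-embedding variant.

Only the operations the package needs are implemented.  Values are float64
numpy arrays; broadcasting follows numpy semantics and is undone in the
backward pass by summing over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "sigmoid",
    "relu",
    "absolute",
    "maximum",
    "minimum",
    "clip",
    "where",
    "matmul",
    "concatenate",
    "stack",
    "mean",
    "total",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: a float64 array plus backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    # defer to our reflected operators instead of numpy broadcasting over the
    # Tensor as an opaque object
    __array_ufunc__ = None

    def __init__(self, value, requires_grad: bool = False, _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, seed=None) -> None:
        """Backpropagate from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        if seed is None:
            seed = np.ones_like(self.value)
        self.grad = np.asarray(seed, dtype=np.float64).reshape(self.value.shape).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            a._accumulate(g)
            b._accumulate(g)

        return Tensor(self.value + other.value, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accumulate(-g)

        return Tensor(-self.value, _parents=(self,), _backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            a._accumulate(g * b.value)
            b._accumulate(g * a.value)

        return Tensor(self.value * other.value, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            a._accumulate(g / b.value)
            b._accumulate(-g * a.value / (b.value * b.value))

        return Tensor(self.value / other.value, _parents=(self, other), _backward=bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("Tensor ** only supports scalar exponents")
        out_val = self.value**exponent

        def bwd(g, a=self, e=exponent, ov=out_val):
            a._accumulate(g * e * a.value ** (e - 1))

        return Tensor(out_val, _parents=(self,), _backward=bwd)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(as_tensor(other), self)

    # ------------------------------------------------------------- shape ops
    def __getitem__(self, idx):
        def bwd(g, a=self, idx=idx):
            full = np.zeros_like(a.value)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor(self.value[idx], _parents=(self,), _backward=bwd)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g, a=self):
            a._accumulate(g.reshape(a.value.shape))

        return Tensor(self.value.reshape(shape), _parents=(self,), _backward=bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.value.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.value.shape))

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def item(self) -> float:
        return float(self.value)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -------------------------------------------------------------- elementwise
def _unary(x, fn, dfn):
    if not isinstance(x, Tensor):
        return fn(np.asarray(x, dtype=np.float64))
    out_val = fn(x.value)

    def bwd(g, a=x, ov=out_val):
        a._accumulate(g * dfn(a.value, ov))

    return Tensor(out_val, _parents=(x,), _backward=bwd)


def exp(x):
    return _unary(x, np.exp, lambda v, ov: ov)


def log(x):
    return _unary(x, np.log, lambda v, ov: 1.0 / v)


def sqrt(x):
    return _unary(x, np.sqrt, lambda v, ov: 0.5 / ov)


def tanh(x):
    return _unary(x, np.tanh, lambda v, ov: 1.0 - ov * ov)


def sigmoid(x):
    def fn(v):
        out = np.empty_like(v)
        pos = v >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
        ev = np.exp(v[~pos])
        out[~pos] = ev / (1.0 + ev)
        return out

    if not isinstance(x, Tensor):
        return fn(np.atleast_1d(np.asarray(x, dtype=np.float64))).reshape(np.shape(x))
    return _unary(x, lambda v: fn(np.atleast_1d(v)).reshape(v.shape), lambda v, ov: ov * (1.0 - ov))


def relu(x):
    return _unary(x, lambda v: np.maximum(v, 0.0), lambda v, ov: (v > 0).astype(np.float64))


def absolute(x):
    return _unary(x, np.abs, lambda v, ov: np.sign(v))


def maximum(a, b):
    """Elementwise max; at ties the gradient goes to the first argument."""
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.maximum(a, b)
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.value >= b.value

    def bwd(g, a=a, b=b, m=take_a):
        a._accumulate(g * m)
        b._accumulate(g * (~m))

    return Tensor(np.maximum(a.value, b.value), _parents=(a, b), _backward=bwd)


def minimum(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.minimum(a, b)
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.value <= b.value

    def bwd(g, a=a, b=b, m=take_a):
        a._accumulate(g * m)
        b._accumulate(g * (~m))

    return Tensor(np.minimum(a.value, b.value), _parents=(a, b), _backward=bwd)


def clip(x, lo, hi):
    return minimum(maximum(x, lo), hi)


def where(cond, a, b):
    """Select by a boolean (non-differentiated) condition array."""
    cond = np.asarray(cond, dtype=bool)
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.where(cond, a, b)
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g, a=a, b=b, c=cond):
        a._accumulate(np.where(c, g, 0.0))
        b._accumulate(np.where(c, 0.0, g))

    return Tensor(np.where(cond, a.value, b.value), _parents=(a, b), _backward=bwd)


# ------------------------------------------------------------------- linalg
def matmul(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.matmul(a, b)
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g, a=a, b=b):
        av, bv = a.value, b.value
        ga = np.matmul(g, np.swapaxes(bv, -1, -2))
        gb = np.matmul(np.swapaxes(av, -1, -2), g)
        a._accumulate(_unbroadcast(ga, av.shape))
        b._accumulate(_unbroadcast(gb, bv.shape))

    return Tensor(np.matmul(a.value, b.value), _parents=(a, b), _backward=bwd)


def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tensors, off=offsets, axis=axis):
        sl = [slice(None)] * g.ndim
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bwd,
    )


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g, ts=tensors, axis=axis):
        for i, t in enumerate(ts):
            t._accumulate(np.take(g, i, axis=axis))

    return Tensor(
        np.stack([t.value for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bwd,
    )


def mean(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.mean(x, axis=axis, keepdims=keepdims)
    return x.mean(axis=axis, keepdims=keepdims)


def total(x, axis=None, keepdims=False):
    """Sum that dispatches on Tensor vs. plain array."""
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis, keepdims=keepdims)
    return x.sum(axis=axis, keepdims=keepdims)


def value_of(x) -> np.ndarray:
    """The plain numpy value of a Tensor or array-like."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
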