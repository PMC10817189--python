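"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the likelihood trainer needs: arithmetic
with broadcasting, matmul, tanh/exp/log/sqrt, softplus, and gammaln (whose
gradient is digamma).  Gradients are accumulated by reverse topological
traversal of the expression graph; correctness is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln as _gammaln

__all__ = ["Var", "const", "tanh", "exp", "log", "sqrt", "softplus", "gammaln", "vsum", "vmean"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """A node in the expression graph: value, parents, and a backward rule."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # -- graph traversal --------------------------------------------------
    def backward(self):
        """Populate ``.grad`` on every ancestor; self must be scalar."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        visit(self)
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        other = const(other)

        def back(g):
            self.grad += _unbroadcast(g, self.shape)
            other.grad += _unbroadcast(g, other.shape)

        return Var(self.value + other.value, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self.grad += _unbroadcast(-g, self.shape)

        return Var(-self.value, (self,), back)

    def __sub__(self, other):
        return self + (-const(other))

    def __rsub__(self, other):
        return const(other) + (-self)

    def __mul__(self, other):
        other = const(other)

        def back(g):
            self.grad += _unbroadcast(g * other.value, self.shape)
            other.grad += _unbroadcast(g * self.value, other.shape)

        return Var(self.value * other.value, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = const(other)

        def back(g):
            self.grad += _unbroadcast(g / other.value, self.shape)
            other.grad += _unbroadcast(-g * self.value / other.value**2, other.shape)

        return Var(self.value / other.value, (self, other), back)

    def __rtruediv__(self, other):
        return const(other) / self

    def __pow__(self, k):
        if not np.isscalar(k):
            raise TypeError("only constant exponents are supported")

        def back(g):
            self.grad += _unbroadcast(g * k * self.value ** (k - 1), self.shape)

        return Var(self.value**k, (self,), back)

    def __matmul__(self, other):
        other = const(other)

        def back(g):
            self.grad += g @ other.value.T
            other.grad += self.value.T @ g

        return Var(self.value @ other.value, (self, other), back)


def const(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def tanh(x: Var) -> Var:
    x = const(x)
    t = np.tanh(x.value)

    def back(g):
        x.grad += _unbroadcast(g * (1.0 - t**2), x.shape)

    return Var(t, (x,), back)


def exp(x: Var) -> Var:
    x = const(x)
    e = np.exp(x.value)

    def back(g):
        x.grad += _unbroadcast(g * e, x.shape)

    return Var(e, (x,), back)


def log(x: Var) -> Var:
    x = const(x)

    def back(g):
        x.grad += _unbroadcast(g / x.value, x.shape)

    return Var(np.log(x.value), (x,), back)


def sqrt(x: Var) -> Var:
    x = const(x)
    s = np.sqrt(x.value)

    def back(g):
        x.grad += _unbroadcast(g * 0.5 / s, x.shape)

    return Var(s, (x,), back)


def softplus(x: Var) -> Var:
    """log(1 + exp(x)), numerically stable; gradient is the logistic."""
    x = const(x)
    v = np.logaddexp(0.0, x.value)

    def back(g):
        x.grad += _unbroadcast(g / (1.0 + np.exp(-x.value)), x.shape)

    return Var(v, (x,), back)


def gammaln(x: Var) -> Var:
    x = const(x)

    def back(g):
        x.grad += _unbroadcast(g * digamma(x.value), x.shape)

    return Var(_gammaln(x.value), (x,), back)


def vsum(x: Var, axis=None, keepdims=False) -> Var:
    x = const(x)

    def back(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        x.grad += np.broadcast_to(gg, x.shape).copy()

    return Var(x.value.sum(axis=axis, keepdims=keepdims), (x,), back)


def vmean(x: Var, axis=None, keepdims=False) -> Var:
    x = const(x)
    n = x.value.size if axis is None else x.value.shape[axis]
    return vsum(x, axis=axis, keepdims=keepdims) * (1.0 / n)
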