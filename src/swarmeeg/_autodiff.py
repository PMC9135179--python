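"""Minimal reverse-mode automatic differentiation over numpy arrays.

Every network in this package (sparse autoencoder, softmax DNN, BiLSTM,
attention, Tree-LSTM, Q-network) is defined as a composition of the ops
below; gradients are exact analytic gradients obtained by backpropagation
through the recorded graph, and are validated against central finite
differences in the test suite.

Float64 throughout: the gradient-check tolerances (relative error < 1e-4)
require double precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "parameter", "constant", "concat", "stack_rows",
           "softmax_cross_entropy", "Adam", "RMSprop", "max_norm_"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph holding a float64 ndarray."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = _unbroadcast(g, self.value.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ------------------------------------------------------
    def _coerce(self, other):
        return other if isinstance(other, Tensor) else constant(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.value + other.value, (self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.value * other.value, (self, other))
        out._backward = lambda g: (self._accum(g * other.value),
                                   other._accum(g * self.value))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.value / other.value, (self, other))

        def bwd(g):
            self._accum(g / other.value)
            other._accum(-g * self.value / other.value ** 2)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.value @ other.value, (self, other))

        def bwd(g):
            self._accum(g @ other.value.T)
            other._accum(self.value.T @ g)

        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, (self,))
        out._backward = lambda g: self._accum(g.T)
        return out

    # -- nonlinearities --------------------------------------------------
    def tanh(self):
        y = np.tanh(self.value)
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - y ** 2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.value > 0
        out = Tensor(self.value * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def exp(self):
        y = np.exp(self.value)
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.value), (self,))
        out._backward = lambda g: self._accum(g / self.value)
        return out

    def square(self):
        out = Tensor(self.value ** 2, (self,))
        out._backward = lambda g: self._accum(2.0 * g * self.value)
        return out

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.value.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], (self,))

        def bwd(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    def softmax(self, axis=-1):
        """Row-stochastic softmax along `axis` (gradient flows)."""
        shifted = self - constant(self.value.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def parameter(value) -> Tensor:
    return Tensor(np.array(value, dtype=np.float64))


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)


def concat(tensors, axis=-1) -> Tensor:
    vals = [t.value for t in tensors]
    out = Tensor(np.concatenate(vals, axis=axis), tuple(tensors))
    sizes = [v.shape[axis] for v in vals]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


def stack_rows(tensors) -> Tensor:
    """Stack 1-D/row tensors into a matrix along a new leading axis."""
    out = Tensor(np.stack([t.value for t in tensors]), tuple(tensors))

    def bwd(g):
        for t, piece in zip(tensors, g):
            t._accum(piece)

    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Numerically stable fused op with the standard (p - y)/N gradient.
    """
    z = logits.value
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean()
    out = Tensor(nll, (logits,))

    def bwd(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(g * grad / n)

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class RMSprop:
    """RMSprop optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.sq[i] = self.rho * self.sq[i] + (1 - self.rho) * g * g
            p.value -= self.lr * g / (np.sqrt(self.sq[i]) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def max_norm_(params, max_norm: float) -> None:
    """Rescale columns of each weight matrix to at most `max_norm` L2 norm."""
    for p in params:
        if p.value.ndim < 2:
            continue
        norms = np.linalg.norm(p.value, axis=0, keepdims=True)
        scale = np.minimum(1.0, max_norm / np.maximum(norms, 1e-12))
        p.value *= scale
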