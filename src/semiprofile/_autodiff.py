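"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the VAE-GAN needs: broadcasting arithmetic,
matmul, slicing/concatenation, reductions, and the transcendental functions
appearing in the ZINB/Gaussian likelihoods (exp, log, lgamma, sigmoid,
softmax, rectifiers). Gradients are checked against finite differences in the
test suite.

The module-level math helpers (``exp``, ``log``, ...) dispatch on input type:
a :class:`Tensor` builds the computation graph, a plain ndarray/scalar is
evaluated eagerly with numpy/scipy. Loss functions written against these
helpers therefore serve both as differentiable training objectives and as
plain numerical routines.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor",
    "concat",
    "exp",
    "log",
    "log1p",
    "sqrt",
    "sigmoid",
    "softmax",
    "relu",
    "leaky_relu",
    "lgamma",
    "tsum",
    "tmean",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes introduced or stretched by broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators instead of elementwise
    # consuming the Tensor
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def build(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data**p, (self,), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = back
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def back():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = back
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def back():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out = Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = back
    return out


# -- dual-dispatch math helpers -------------------------------------------


def _unary(x, fn, dfn):
    if not isinstance(x, Tensor):
        return fn(np.asarray(x, dtype=np.float64))
    y = fn(x.data)
    out = Tensor._make(y, (x,), None)

    def back():
        if x.requires_grad:
            x._accum(out.grad * dfn(x.data, y))

    out._backward = back
    return out


def exp(x):
    return _unary(x, np.exp, lambda d, y: y)


def log(x):
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def log1p(x):
    return _unary(x, np.log1p, lambda d, y: 1.0 / (1.0 + d))


def sqrt(x):
    return _unary(x, np.sqrt, lambda d, y: 0.5 / y)


def sigmoid(x):
    return _unary(x, _sp.expit, lambda d, y: y * (1.0 - y))


def relu(x):
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda d, y: (d > 0).astype(float))


def leaky_relu(x, slope: float = 0.01):
    return _unary(
        x,
        lambda d: np.where(d > 0, d, slope * d),
        lambda d, y: np.where(d > 0, 1.0, slope),
    )


def lgamma(x):
    return _unary(x, _sp.gammaln, lambda d, y: _sp.digamma(d))


def softmax(x, axis: int = -1):
    def fn(d):
        m = d - d.max(axis=axis, keepdims=True)
        e = np.exp(m)
        return e / e.sum(axis=axis, keepdims=True)

    if not isinstance(x, Tensor):
        return fn(np.asarray(x, dtype=np.float64))
    y = fn(x.data)
    out = Tensor._make(y, (x,), None)

    def back():
        if x.requires_grad:
            dot = (out.grad * y).sum(axis=axis, keepdims=True)
            x._accum(y * (out.grad - dot))

    out._backward = back
    return out


def tsum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def tmean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)
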