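"""Reverse-mode automatic differentiation over numpy arrays.

All neural networks in this package (encoder/decoder, discriminator, batch
and cell-type classifiers, the hierarchical-prior autoencoder) are dense
multi-layer perceptrons trained with ADAM; their objectives mix count
log-likelihoods, Gaussian KL terms and adversarial losses.  This module
provides the minimal tensor type and primitive set those objectives need:
broadcast-aware arithmetic, matmul, exp/log/sqrt, relu/sigmoid/softplus,
log-gamma, reductions, concatenation and stable log-sum-exp.

Every primitive's vector-Jacobian product is exercised by finite-difference
gradient checks in the test suite.  The functional wrappers at module level
(``exp``, ``log``, ``lsum`` ...) dispatch on input type so that the same
loss code runs on plain numpy arrays (no graph, used by the closed-form
loss functions) and on :class:`Tensor` (used during training).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import special as _sp


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy scalars/arrays defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        return Tensor(data, _parents=parents, _backward=backward)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    # -- elementwise non-linearities -----------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = _sp.expit(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        return self._make(out_data, (self,), lambda g: (g * _sp.expit(self.data),))

    def gammaln(self):
        return self._make(_sp.gammaln(self.data), (self,), lambda g: (g * _sp.digamma(self.data),))

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = np.exp(self.data - m)
        s = shifted.sum(axis=axis, keepdims=True)
        out_data = (np.log(s) + m)
        soft = shifted / s

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (g * soft,)

        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + pgrad


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, _parents=tuple(tensors), _backward=backward)


# ----------------------------------------------------------------------
# duck-typed functional interface: works on Tensor and plain ndarrays
# ----------------------------------------------------------------------

def _is_t(x) -> bool:
    return isinstance(x, Tensor)


def exp(x):
    return x.exp() if _is_t(x) else np.exp(x)


def log(x):
    return x.log() if _is_t(x) else np.log(x)


def sqrt(x):
    return x.sqrt() if _is_t(x) else np.sqrt(x)


def relu(x):
    return x.relu() if _is_t(x) else np.maximum(x, 0.0)


def sigmoid(x):
    return x.sigmoid() if _is_t(x) else _sp.expit(x)


def softplus(x):
    return x.softplus() if _is_t(x) else np.logaddexp(0.0, x)


def gammaln(x):
    return x.gammaln() if _is_t(x) else _sp.gammaln(x)


def tsum(x, axis=None, keepdims=False):
    return x.sum(axis=axis, keepdims=keepdims) if _is_t(x) else np.sum(x, axis=axis, keepdims=keepdims)


def tmean(x, axis=None, keepdims=False):
    return x.mean(axis=axis, keepdims=keepdims) if _is_t(x) else np.mean(x, axis=axis, keepdims=keepdims)


def logsumexp(x, axis=-1, keepdims=False):
    return x.logsumexp(axis=axis, keepdims=keepdims) if _is_t(x) else _sp.logsumexp(x, axis=axis, keepdims=keepdims)


def softmax(x, axis=-1):
    z = x - logsumexp(x, axis=axis, keepdims=True)
    return exp(z)


def log_softmax(x, axis=-1):
    return x - logsumexp(x, axis=axis, keepdims=True)


def value(x) -> np.ndarray:
    """The raw ndarray behind ``x`` (identity for ndarrays)."""
    return x.data if _is_t(x) else np.asarray(x)
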