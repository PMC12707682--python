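"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical core the model components are built on: a
:class:`Tensor` wrapping an ``ndarray`` together with a backward closure, and
the small set of differentiable operations the architecture needs (broadcasted
arithmetic, batched matmul, activations, softmax, layer norm, reductions,
gather/concat). Gradients are accumulated by a topological-order sweep from
the output scalar.

Design notes
------------
* Operations accept plain arrays or scalars anywhere a tensor is accepted;
  non-tensors are treated as constants.
* Broadcasting follows numpy; gradients are un-broadcast (summed) back to the
  operand shape.
* ``softmax`` subtracts the row max as a constant: softmax is shift invariant,
  so the gradient is unaffected.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "softmax",
    "layer_norm",
    "dropout",
    "relu",
    "leaky_relu",
    "elu",
    "gelu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "AdamW",
    "clip_grad_norm",
    "xavier_uniform",
    "kaiming_normal",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # collapse axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray-Tensor arithmetic to our reflected ops
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def __array__(self, dtype=None, copy=None):
        arr = np.asarray(self.data)
        return arr.astype(dtype) if dtype is not None else arr

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction --------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only constant exponents are supported")

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires tensors with ndim >= 2")

        def backward(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            self.grad = grad if self.grad is None else self.grad + grad

        return Tensor._make(self.data[idx], (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# -- elementwise nonlinearities ----------------------------------------------

def exp(x) -> Tensor:
    x = as_tensor(x)
    out_data = np.exp(x.data)

    def backward(g):
        x._accum(g * out_data)

    return Tensor._make(out_data, (x,), backward)


def log(x) -> Tensor:
    x = as_tensor(x)

    def backward(g):
        x._accum(g / x.data)

    return Tensor._make(np.log(x.data), (x,), backward)


def sqrt(x) -> Tensor:
    return as_tensor(x) ** 0.5


def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def leaky_relu(x, negative_slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def backward(g):
        x._accum(g * np.where(mask, 1.0, negative_slope))

    return Tensor._make(np.where(mask, x.data, negative_slope * x.data), (x,), backward)


def elu(x, alpha: float = 1.0) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)

    def backward(g):
        x._accum(g * np.where(mask, 1.0, neg + alpha))

    return Tensor._make(np.where(mask, x.data, neg), (x,), backward)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    s[~pos] = e / (1.0 + e)

    def backward(g):
        x._accum(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def tanh(x) -> Tensor:
    x = as_tensor(x)
    t = np.tanh(x.data)

    def backward(g):
        x._accum(g * (1.0 - t**2))

    return Tensor._make(t, (x,), backward)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    x = as_tensor(x)
    u = _GELU_C * (x.data + 0.044715 * x.data**3)
    t = np.tanh(u)
    out = 0.5 * x.data * (1.0 + t)

    def backward(g):
        du = _GELU_C * (1.0 + 3 * 0.044715 * x.data**2)
        x._accum(g * (0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t**2) * du))

    return Tensor._make(out, (x,), backward)


# -- composite ops -----------------------------------------------------------

def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x, gain, bias, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then apply elementwise affine."""
    x = as_tensor(x)
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / sqrt(var + eps) * gain + bias


def dropout(x, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; only call in training mode."""
    if rate <= 0.0:
        return as_tensor(x)
    keep = 1.0 - rate
    mask = (rng.random(as_tensor(x).shape) < keep) / keep
    return as_tensor(x) * mask


def concatenate(tensors: Sequence, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


# -- parameter initialisation ------------------------------------------------

def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def kaiming_normal(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    fan_in = shape[-2] if len(shape) > 1 else shape[0]
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


# -- optimisation ------------------------------------------------------------

def clip_grad_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self._t)
            v_hat = v / (1 - b2**self._t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)
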