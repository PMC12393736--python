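"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model components here are small multilayer perceptrons trained with an
alternating three-stage procedure, which needs selective parameter updates
and detached (gradient-stopped) forward passes.  This module provides just
the tensor operations those networks use: affine maps, LeakyReLU, sigmoid,
row softmax, batch normalization, elementwise arithmetic and reductions.

Gradients are accumulated by a topological backward sweep; every operation's
derivative is exercised against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over dimensions that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an associated gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(fwd(self.data, other.data), _parents=(self, other))

        def _backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(bwd_self(g), self.data.shape))
            other._accumulate(_unbroadcast(bwd_other(g), other.data.shape))

        out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor(other).__sub__(self)

    def __mul__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(
            other_t,
            np.multiply,
            lambda g: g * other_t.data,
            lambda g: g * self.data,
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(
            other_t,
            np.divide,
            lambda g: g / other_t.data,
            lambda g: -g * self.data / other_t.data**2,
        )

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))

        def _backward(g: np.ndarray) -> None:
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = _backward
        return out

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def _backward(g: np.ndarray) -> None:
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = _backward
        return out

    __matmul__ = matmul

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _backward(g: np.ndarray) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _parents=(self,))

        def _backward(g: np.ndarray) -> None:
            self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        s = expit(self.data)
        out = Tensor(s, _parents=(self,))

        def _backward(g: np.ndarray) -> None:
            self._accumulate(g * s * (1.0 - s))

        out._backward = _backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))

        def _backward(g: np.ndarray) -> None:
            self._accumulate(g * e)

        out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def _backward(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        out._backward = _backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is zero where the clamp binds."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))

        def _backward(g: np.ndarray) -> None:
            self._accumulate(g * ((self.data > lo) & (self.data < hi)))

        out._backward = _backward
        return out

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        out = Tensor(self.data[:, start:stop], _parents=(self,))

        def _backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._accumulate(full)

        out._backward = _backward
        return out


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax; the max shift is a detached constant for stability."""
    shift = x - x.data.max(axis=1, keepdims=True)
    e = shift.exp()
    return e / e.sum(axis=1, keepdims=True)


def parameter(rng: np.random.Generator, shape: Sequence[int], fan_in: int) -> Tensor:
    """Uniform fan-in-scaled initial weights, the standard for linear layers."""
    limit = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None


class Adam:
    """Adam optimizer over an explicit parameter list.

    A separate instance is held per training sub-step so first/second moment
    estimates never leak between parameter groups.
    """

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        zero_grads(self.params)
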