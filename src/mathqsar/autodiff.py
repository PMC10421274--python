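"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based engine providing exactly the operations the attention model
needs: broadcast arithmetic, (batched) matrix products, softmax with additive
masking, layer normalization, ReLU, reductions and a fused
binary-cross-entropy-with-logits loss. Gradients follow the standard
closed-form backward rules; correctness is enforced by central
finite-difference checks in the test suite.

Everything is float64 and purely deterministic.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse NumPy broadcasting: reduce ``grad`` back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_sum_to_shape(g, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_sum_to_shape(g, other.shape))

        out._backward = bw
        return out

    def __mul__(self, other) -> "Tensor":
        if np.isscalar(other):
            out = _node(self.data * other, (self,))
            out._backward = lambda g: self._accumulate(g * other)
            return out
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_sum_to_shape(g * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_sum_to_shape(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = _node(np.matmul(self.data, other.data), (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_sum_to_shape(ga, self.shape))
            if other.requires_grad or other._parents:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_sum_to_shape(gb, other.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # ---- shape ------------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inv = tuple(int(i) for i in np.argsort(axes))
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # ---- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = _node(s, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    # ---- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = _node(np.array(self.data.mean()), (self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g / n, self.shape).copy())
        return out


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    return out


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def softmax(x: Tensor, bias: Optional[np.ndarray] = None) -> Tensor:
    """Row softmax over the last axis, with an optional additive (mask) bias.

    ``bias`` is a plain array (no gradient) added to the scores before
    normalization; large negative entries exclude positions.
    """
    z = x.data if bias is None else x.data + bias
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = _node(s, (x,))

    def bw(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        x._accumulate(s * (g - dot))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then scale & shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = _node(xhat * gamma.data + beta.data, (x, gamma, beta))
    d = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate(_sum_to_shape(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_sum_to_shape(g, beta.shape))
        gx = g * gamma.data
        term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        x._accumulate(term * inv)

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable fused op)."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = _node(np.array(loss.mean()), (logits,))
    p = 1.0 / (1.0 + np.exp(-z))
    out._backward = lambda g: logits._accumulate(g * (p - y) / z.size)
    return out


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
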