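"""Minimal vectorized reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for dense and recurrent networks: a ``Tensor`` wraps
an ndarray, records the operation that produced it, and ``backward()``
propagates gradients through the tape in reverse topological order.
float64 throughout so training runs are bit-stable for a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev = _prev

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def bw() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def bw() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other: float) -> "Tensor":
        return Tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, True, (self, other))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = bw
        return out

    __matmul__ = matmul

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], True, (self,))

        def bw() -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[key] = out.grad
                self._accum(g)

        out._backward = bw
        return out

    # ---- elementwise nonlinearities ------------------------------------

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, True, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * (1.0 - y * y))

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, True, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * y * (1.0 - y))

        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), True, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, True, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * y)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), True, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = bw
        return out

    def square(self) -> "Tensor":
        return self * self

    def sqrt(self) -> "Tensor":
        y = np.sqrt(self.data)
        out = Tensor(y, True, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * 0.5 / y)

        out._backward = bw
        return out

    # ---- reductions -----------------------------------------------------

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), True, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad))

        out._backward = bw
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), True, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad / n))

        out._backward = bw
        return out

    # ---- autodiff driver -------------------------------------------------

    def backward(self) -> None:
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
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def concat_const(t: Tensor, const_right: np.ndarray) -> Tensor:
    """Concatenate a constant block to the right of a (B x D) tensor."""
    const_right = np.asarray(const_right, dtype=np.float64)
    out = Tensor(np.concatenate([t.data, const_right], axis=1), True, (t,))
    d = t.data.shape[1]

    def bw() -> None:
        if t.requires_grad:
            t._accum(out.grad[:, :d])

    out._backward = bw
    return out


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate (B x D_i) tensors along axis 1."""
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=1), True, tuple(tensors)
    )
    offsets = np.cumsum([0] + [t.data.shape[1] for t in tensors])

    def bw() -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(out.grad[:, lo:hi])

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, target_idx: np.ndarray) -> Tensor:
    """Sum over the batch of -log softmax(logits)[target].

    ``logits`` is (batch x classes); ``target_idx`` is an int vector. The
    softmax/log/one-hot chain is fused for numerical stability.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), target_idx], 1e-300)).sum()
    out = Tensor(nll, True, (logits,))

    def bw() -> None:
        if logits.requires_grad:
            g = probs.copy()
            g[np.arange(n), target_idx] -= 1.0
            logits._accum(out.grad * g)

    out._backward = bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain (non-differentiated) row softmax for inference-time decoding."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adaptive-moment first-order optimizer."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
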