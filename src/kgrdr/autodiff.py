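"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set the fusion and predictor modules need:
broadcasting add/mul/div, matmul, elementwise exp/log/relu/sigmoid/softplus,
axis reductions, transpose and reshape. Gradients are accumulated by a
topological-order backward sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "relu", "sigmoid", "softplus", "exp", "log", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- factory helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = Tensor._result(self.data.T, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: (g.T,)
        return out

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out = Tensor._result(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: (g.reshape(old),)
        return out

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor._result(self.data + other.data, (self, other), None)
        if out.requires_grad:
            sa, sb = self.data.shape, other.data.shape
            out._backward = lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb))
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor._result(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor._result(self.data * other.data, (self, other), None)
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor._result(self.data / other.data, (self, other), None)
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape),
            )
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor._result(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (g @ b.data.T, a.data.T @ g)
        return out

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor._result(self.data ** p, (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: (g * p * a.data ** (p - 1),)
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            shape = self.data.shape

            def backward(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                return (np.broadcast_to(g, shape).copy(),)

            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ---- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = np.exp(x.data)
    out = Tensor._result(data, (x,), None)
    if out.requires_grad:
        out._backward = lambda g: (g * data,)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor._result(np.log(x.data), (x,), None)
    if out.requires_grad:
        out._backward = lambda g: (g / x.data,)
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor._result(np.maximum(x.data, 0.0), (x,), None)
    if out.requires_grad:
        mask = (x.data > 0).astype(np.float64)
        out._backward = lambda g: (g * mask,)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = Tensor._result(data, (x,), None)
    if out.requires_grad:
        out._backward = lambda g: (g * data * (1.0 - data),)
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed stably; gradient is sigmoid(x)."""
    x = as_tensor(x)
    data = np.logaddexp(0.0, x.data)
    out = Tensor._result(data, (x,), None)
    if out.requires_grad:
        sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
        out._backward = lambda g: (g * sig,)
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
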