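"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network needs only a small, fixed set of differentiable
operations (element-wise algebra, convolution, batch norm, pooling, bilinear
resizing, sigmoid/ReLU, reductions).  Each operation records a backward
closure on the output tensor; :meth:`Tensor.backward` runs a topological
sweep.  Arrays are kept in whatever float dtype they arrive in (float32 for
network parameters).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff plumbing ----------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req and backward is not None:
            out._parents = tuple(parents)
            out._backward = lambda: backward(out)
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- element-wise algebra -------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(out.grad)
            if other.requires_grad:
                other._accumulate(out.grad)

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(out: Tensor) -> None:
            self._accumulate(-out.grad)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(out.grad * other.data)
            if other.requires_grad:
                other._accumulate(out.grad * self.data)

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(out.grad / other.data)
            if other.requires_grad:
                other._accumulate(-out.grad * self.data / (other.data ** 2))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        def bwd(out: Tensor) -> None:
            self._accumulate(out.grad * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), bwd)

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(out: Tensor) -> None:
            self._accumulate(out.grad * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        # piecewise form avoids exp overflow for large |x|
        z = np.exp(-np.abs(self.data))
        y = np.where(self.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))

        def bwd(out: Tensor) -> None:
            self._accumulate(out.grad * y * (1.0 - y))

        return Tensor._make(y, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(out: Tensor) -> None:
            self._accumulate(out.grad / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Hard clip; gradient is zero outside [lo, hi] (saturating)."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(out: Tensor) -> None:
            self._accumulate(out.grad * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bwd)

    # -- reductions / reshaping ----------------------------------------------

    def sum(self) -> "Tensor":
        def bwd(out: Tensor) -> None:
            self._accumulate(np.broadcast_to(out.grad, self.data.shape))

        return Tensor._make(self.data.sum(), (self,), bwd)

    def mean(self) -> "Tensor":
        n = self.data.size

        def bwd(out: Tensor) -> None:
            self._accumulate(np.broadcast_to(out.grad / n, self.data.shape))

        return Tensor._make(self.data.mean(), (self,), bwd)

    def reshape(self, *shape: int) -> "Tensor":
        def bwd(out: Tensor) -> None:
            self._accumulate(out.grad.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(out: Tensor) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(a, b)
                t._accumulate(out.grad[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bwd)
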