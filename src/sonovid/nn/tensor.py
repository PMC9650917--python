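"""Reverse-mode automatic differentiation over NumPy arrays.

A minimal tape-based autograd engine: each :class:`Tensor` wraps a
``float32`` ndarray and records the closure needed to propagate gradients
to its parents. ``Tensor.backward()`` topologically sorts the tape and
accumulates gradients. Only the operations needed by the video-classifier
stack are implemented (elementwise arithmetic, matmul with broadcasting,
reductions, reshapes, fancy indexing, tanh/relu/exp/log).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward=None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ meta
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------ accumulate
    def _accumulate(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=np.float32)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed Python recursion limit
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- operators
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, other.data.swapaxes(-1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(self.data.swapaxes(-1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # ------------------------------------------------------------- functions
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def sqrt(self) -> "Tensor":
        return self**0.5

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if np.isscalar(axis) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bwd)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack_detached(tensors: Iterable[Tensor]) -> np.ndarray:
    return np.stack([t.data for t in tensors])
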