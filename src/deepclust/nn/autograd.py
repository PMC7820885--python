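"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains its autoencoder backbones with plain numpy, so the
differentiable primitives live here: a :class:`Tensor` wrapping an ndarray,
elementwise arithmetic with numpy broadcasting, matmul, reductions,
reshaping/indexing, and the nonlinearities the backbones need.  Gradients
are accumulated by a topological backward sweep from any node; correctness
is asserted against central finite differences in the test suite.

Only float64 is used: the engine is built for small, deterministic,
desk-scale models where numerical verifiability matters more than speed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.1):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * factor)

        return Tensor._from_op(self.data * factor, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * s * (1 - s))

        return Tensor._from_op(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (1 - t * t))

        return Tensor._from_op(t, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * e)

        return Tensor._from_op(e, (self,), backward)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    @property
    def T(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.T)

        return Tensor._from_op(self.data.T, (self,), backward)

    def __getitem__(self, idx):
        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- backward sweep --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Propagate ``grad`` (default: ones) from this node to all leaves.

        Gradients accumulate into ``.grad``; call ``zero_grad`` on
        parameters between optimizer steps.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            # post-order DFS without recursion
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)
        # free intermediate grads (keep leaves')
        for node in topo:
            if node is not self and node._parents:
                node.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)

    def backward(out):
        grads = np.moveaxis(out.grad, axis, 0)
        for t, g in zip(tensors, grads):
            if t.requires_grad:
                t._accum(g)

    return Tensor._from_op(
        np.stack([t.data for t in tensors], axis=axis), tensors, backward
    )
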