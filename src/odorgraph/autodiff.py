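"""Minimal reverse-mode automatic differentiation over NumPy float64 arrays.

The network in :mod:`odorgraph.model` needs only a small, fixed set of dense
operations (broadcast arithmetic, batched matmul, reductions, a few
nonlinearities).  This module provides exactly those as a :class:`Tensor`
wrapper that records a tape and back-propagates with the chain rule.  All
arithmetic is in float64, which keeps finite-difference gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in prev))
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        # never mutate in place: incoming grads may be shared between parents
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(g)
            other._accum(g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim >= 2:
                    self._accum(np.matmul(g, np.swapaxes(b, -1, -2)))
                else:  # b is a vector
                    self._accum(np.multiply.outer(g, b))
            if other.requires_grad:
                if a.ndim >= 2:
                    other._accum(np.matmul(np.swapaxes(a, -1, -2), g))
                else:
                    other._accum(np.multiply.outer(a, g))

        return self._make(out_data, (self, other), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g_arr = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g_arr = np.expand_dims(g_arr, ax)
            self._accum(np.broadcast_to(g_arr, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accum(np.asarray(g).reshape(self.data.shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def abs(self):
        def backward(g):
            self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def selu(self):
        # Klambauer et al. self-normalizing constants.
        scale, alpha = 1.0507009873554805, 1.6732632423543772
        pos = self.data > 0
        out_data = scale * np.where(pos, self.data, alpha * np.expm1(self.data))

        def backward(g):
            local = scale * np.where(pos, 1.0, alpha * np.exp(self.data))
            self._accum(g * local)

        return self._make(out_data, (self,), backward)

    def scatter_rows(self, indices: np.ndarray, n_rows: int):
        """Place rows at `indices` of an otherwise-zero (n_rows, ...) tensor."""
        out_data = np.zeros((n_rows, *self.data.shape[1:]))
        out_data[indices] = self.data

        def backward(g):
            self._accum(np.asarray(g)[indices])

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the un-clamped region only."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accum(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def softmax(self):
        """Softmax over the last axis (numerically shifted; shift is constant)."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=-1, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    # -- autograd driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)
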