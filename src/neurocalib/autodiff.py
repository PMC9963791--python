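"""Minimal reverse-mode automatic differentiation over numpy arrays.

The calibration method trains a neural network *through* a numerical
SDE solver, so the gradient of a scalar loss must flow from predicted
trajectories back into both the network weights and the proposed model
parameters.  This module provides the small set of differentiable array
operations that the solvers and the network require: arithmetic with
numpy broadcasting, matrix products, reductions, ``exp``/``log``,
absolute value, powers with differentiable exponents, indexing,
stacking and clipping.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` and records its parents and a
  backward closure on a tape; :meth:`Tensor.backward` runs the tape in
  reverse topological order.
* Random increments are ordinary numpy arrays (constants), so noise is
  automatically treated as fixed during differentiation.
* ``abs`` is nondifferentiable at 0; the subgradient of minimum norm
  (0) is used there.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Union

import numpy as np

ArrayLike = Union["Tensor", np.ndarray, float, int]

__all__ = ["Tensor", "as_tensor", "stack", "concatenate", "exp", "log", "power"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the differentiation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected Tensor operators instead of
    # broadcasting over a Tensor as an object array
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | float | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative post-order DFS (tapes from long SDE integrations can be deep)
        visit: list[tuple[Tensor, bool]] = [(self, False)]
        del stack_
        while visit:
            node, processed = visit.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visit.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    visit.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient only valid for scalars")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(g)
                other._accumulate(g)
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(g * other.data)
                other._accumulate(g * self.data)
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(g / other.data)
                other._accumulate(-g * self.data / other.data**2)
            out._backward = _bw
        return out

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if isinstance(exponent, Tensor):
            return power(self, exponent)
        out = Tensor(self.data**exponent, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def __matmul__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def _bw(g):
                a, b = self.data, other.data
                if a.ndim == 1 and b.ndim == 1:          # inner product
                    self._accumulate(g * b)
                    other._accumulate(g * a)
                elif a.ndim == 2 and b.ndim == 1:        # matrix @ vector
                    self._accumulate(np.outer(g, b))
                    other._accumulate(a.T @ g)
                elif a.ndim == 1 and b.ndim == 2:        # vector @ matrix
                    self._accumulate(g @ b.T)
                    other._accumulate(np.outer(a, g))
                else:                                    # matrix @ matrix
                    self._accumulate(g @ b.T)
                    other._accumulate(a.T @ g)
            out._backward = _bw
        return out

    def __rmatmul__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) @ self

    # ------------------------------------------------------------------
    # reductions and elementwise functions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            shape = self.data.shape

            def _bw(g):
                g = np.asarray(g, dtype=float)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), parents=(self,))
        if out.requires_grad:
            # sign(0) = 0: the minimum-norm subgradient at the kink
            out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    __abs__ = abs

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clip_min(self, floor: float) -> "Tensor":
        """Elementwise maximum with ``floor``; gradient passes where unclipped."""
        out = Tensor(np.maximum(self.data, floor), parents=(self,))
        if out.requires_grad:
            mask = (self.data > floor).astype(float)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def clip_max(self, ceiling: float) -> "Tensor":
        """Elementwise minimum with ``ceiling``; gradient passes where unclipped."""
        out = Tensor(np.minimum(self.data, ceiling), parents=(self,))
        if out.requires_grad:
            mask = (self.data < ceiling).astype(float)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(np.asarray(g).reshape(orig))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            def _bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = _bw
        return out


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def exp(x: ArrayLike) -> Tensor:
    return as_tensor(x).exp()


def log(x: ArrayLike) -> Tensor:
    return as_tensor(x).log()


def power(base: ArrayLike, exponent: ArrayLike) -> Tensor:
    """``base ** exponent`` with a differentiable exponent (base > 0)."""
    return exp(as_tensor(exponent) * log(base))


def stack(tensors: Sequence[ArrayLike], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis, differentiably."""
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in ts], axis=axis), parents=tuple(ts))
    if out.requires_grad:
        def _bw(g):
            for i, t in enumerate(ts):
                t._accumulate(np.take(g, i, axis=axis))
        out._backward = _bw
    return out


def concatenate(tensors: Iterable[ArrayLike], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), parents=tuple(ts))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in ts]
        offsets = np.cumsum([0] + sizes)

        def _bw(g):
            for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * np.asarray(g).ndim
                sl[axis] = slice(a, b)
                t._accumulate(np.asarray(g)[tuple(sl)])
        out._backward = _bw
    return out
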