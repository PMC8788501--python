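"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  The operation set is deliberately small — exactly
what an encoder–decoder segmentation network needs (dense layers,
convolutions, pooling, pointwise nonlinearities, reductions, concatenation,
resampling) — and everything is plain numpy, so the whole stack runs on a
single CPU with no extension modules.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled", "as_tensor"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the ``with`` block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], list[np.ndarray | None]] | None) -> "Tensor":
        """Create a result tensor; ``backward(grad_out)`` returns one gradient
        per parent (``None`` for parents that do not require grad)."""
        parents = tuple(parents)
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._prev = ()
        out._backward = None
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if out.requires_grad and backward is not None:
            out._prev = parents

            def _bw():
                grads = backward(out.grad)
                for parent, g in zip(parents, grads):
                    if g is None or not parent.requires_grad:
                        continue
                    g = g.astype(parent.data.dtype, copy=False)
                    if parent.grad is None:
                        parent.grad = g.copy() if g.base is not None else g
                    else:
                        parent.grad += g

            out._backward = _bw
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without argument requires a scalar tensor")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

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
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
                # free the tape eagerly: intermediate grads and closures are
                # not needed once propagated (graphs are single-use)
                node._backward = None
                node._prev = ()
                if node is not self:
                    node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: [_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)])

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: [-g])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: [_unbroadcast(g * other.data, self.data.shape),
                       _unbroadcast(g * self.data, other.data.shape)])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: [_unbroadcast(g / other.data, self.data.shape),
                       _unbroadcast(-g * self.data / other.data ** 2, other.data.shape)])

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        return Tensor._make(
            self.data ** exponent, (self,),
            lambda g: [g * exponent * self.data ** (exponent - 1)])

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def bw(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return [_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)]

        return Tensor._make(a @ b, (self, other), bw)

    # -- pointwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: [g * mask])

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: [g * out_data * (1.0 - out_data)])

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: [g * out_data])

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: [g / self.data])

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                return [np.broadcast_to(g, self.data.shape).copy()]
            if not keepdims:
                g = np.expand_dims(g, axis)
            return [np.broadcast_to(g, self.data.shape).copy()]

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                full = np.broadcast_to(out_data, self.data.shape)
                gg = np.broadcast_to(g, self.data.shape)
            else:
                full = out_data if keepdims else np.expand_dims(out_data, axis)
                gg = g if keepdims else np.expand_dims(g, axis)
                full = np.broadcast_to(full, self.data.shape)
                gg = np.broadcast_to(gg, self.data.shape)
            mask = (self.data == full)
            # ties share the gradient equally so the map stays well defined
            if axis is None:
                norm = mask.sum()
            else:
                norm = mask.sum(axis=axis, keepdims=True)
            return [gg * mask / norm]

        return Tensor._make(out_data, (self,), bw)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: [g.reshape(old)])

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: [g.transpose(inv)])

    def __getitem__(self, key):
        def bw(g):
            out = np.zeros_like(self.data)
            out[key] = g
            return [out]

        return Tensor._make(self.data[key], (self,), bw)

    def narrow(self, axis: int, start: int, length: int):
        """Slice ``length`` entries from ``start`` along ``axis``."""
        key = tuple([slice(None)] * axis + [slice(start, start + length)])
        return self[key]

    def pad2d(self, ph: int, pw: int):
        """Zero-pad the last two axes by (ph, pw) on each side."""
        if ph == 0 and pw == 0:
            return self
        pads = [(0, 0)] * (self.data.ndim - 2) + [(ph, ph), (pw, pw)]
        sl = tuple([slice(None)] * (self.data.ndim - 2)
                   + [slice(ph, self.data.shape[-2] + ph), slice(pw, self.data.shape[-1] + pw)])
        return Tensor._make(np.pad(self.data, pads), (self,), lambda g: [g[sl]])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return list(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


class Parameter(Tensor):
    """A tensor that is learnable by construction."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
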