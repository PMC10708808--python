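"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a NumPy array together with an optional gradient and a
closure that propagates upstream gradients to its parents.  The graph is a
plain tape: every differentiable operation appends one node, and
:meth:`Tensor.backward` walks the tape in reverse topological order.

Only the operations the segmentation stack needs are provided; anything
array-shaped but non-differentiable (index bookkeeping, metric computation)
stays in plain NumPy.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "reshape",
    "transpose",
    "concat",
    "narrow",
    "sum_",
    "mean_",
    "expand",
    "as_tensor",
]


class Tensor:
    """An array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- convenience -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- operators ---------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    # -- backprop ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative DFS topological sort (graphs can be deep)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_node(data: np.ndarray, parents: Sequence[Tensor],
              backward: Callable[[np.ndarray], None]) -> Tensor:
    """Create a tape node; the closure is kept only if a parent needs grads."""
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def accumulate(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------- elementwise
def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        accumulate(a, _unbroadcast(g, a.shape))
        accumulate(b, _unbroadcast(g, b.shape))

    return make_node(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        accumulate(a, _unbroadcast(g, a.shape))
        accumulate(b, _unbroadcast(-g, b.shape))

    return make_node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        accumulate(a, _unbroadcast(g * b.data, a.shape))
        accumulate(b, _unbroadcast(g * a.data, b.shape))

    return make_node(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            accumulate(a, _unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            accumulate(b, _unbroadcast(gb, b.shape))

    return make_node(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        accumulate(x, g * mask)

    return make_node(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        accumulate(x, g * s * (1.0 - s))

    return make_node(s, (x,), backward)


# -------------------------------------------------------------- shape algebra
def reshape(x: Tensor, shape) -> Tensor:
    old_shape = x.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        accumulate(x, g.reshape(old_shape))

    return make_node(out_data, (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    out_data = x.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        accumulate(x, g.transpose(inv))

    return make_node(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            accumulate(t, g[tuple(idx)])

    return make_node(out_data, tuple(tensors), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis (the inverse of :func:`concat`)."""
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = x.data[idx]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[idx] = g
        accumulate(x, gx)

    return make_node(out_data, (x,), backward)


def sum_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            accumulate(x, np.broadcast_to(g, x.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        accumulate(x, np.broadcast_to(g, x.shape).copy())

    return make_node(out_data, (x,), backward)


def mean_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.shape[a] for a in axes]))
    s = sum_(x, axis=axis, keepdims=keepdims)
    return mul(s, Tensor(np.asarray(1.0 / n, dtype=x.dtype)))


def expand(x: Tensor, axis: int, size: int) -> Tensor:
    """Replicate a length-1 axis to ``size`` (gradient sums back)."""
    if x.shape[axis] != 1:
        raise ValueError(f"expand requires size-1 axis, got {x.shape[axis]}")
    reps = [1] * x.ndim
    reps[axis] = size
    out_data = np.tile(x.data, reps)

    def backward(g):
        accumulate(x, g.sum(axis=axis, keepdims=True))

    return make_node(out_data, (x,), backward)
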