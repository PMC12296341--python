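"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable parts of the pipeline (text projection, position-wise
feed-forward net, taxonomy embedding table and the graph-convolution head)
are small dense models, so a compact tape-based engine is sufficient.
Tensors wrap ``numpy`` arrays; calling :meth:`Tensor.backward` on a scalar
loss accumulates gradients into every reachable parameter.

Only the operations the model needs are implemented: (batched) matmul,
broadcast add/sub/mul, relu, sigmoid, softmax, mean, reshape/transpose,
concatenation and row gathering.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "sigmoid", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._wrap(other)
        data = self.data - other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return self._make(data, (self, other), backward)

    def __mul__(self, other):
        other = self._wrap(other)
        data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __matmul__(self, other):
        other = self._wrap(other)
        data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        data = self.data.reshape(*shape)

        def backward(g):
            return (g.reshape(orig),)

        return self._make(data, (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def backward(g):
            return (g.transpose(inv),)

        return self._make(data, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def mean(self, axis=None):
        data = self.data.mean(axis=axis)
        denom = self.data.size if axis is None else self.data.shape[axis]
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.full(shape, g / denom),)
            g = np.expand_dims(g, axis)
            return (np.broadcast_to(g / denom, shape).copy(),)

        return self._make(data, (self,), backward)

    def sum(self, axis=None):
        data = self.data.sum(axis=axis)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.full(shape, g),)
            g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(data, (self,), backward)

    def gather_rows(self, index: np.ndarray):
        """Select rows by integer index (embedding-table lookup)."""
        index = np.asarray(index, dtype=np.intp)
        data = self.data[index]
        shape = self.shape

        def backward(g):
            out = np.zeros(shape)
            np.add.at(out, index, g)
            return (out,)

        return self._make(data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            if t._parents == () and t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        return (g * mask,)

    return x._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        return (g * s * (1.0 - s),)

    return x._make(s, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return x._make(s, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
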