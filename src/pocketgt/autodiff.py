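"""Minimal reverse-mode automatic differentiation over numpy arrays.

Covers exactly the operations the graph transformer needs: broadcast
arithmetic, matmul, reductions, exp/log/relu/clamp, row gather and
segment-sum (the sparse scatter/gather pair behind edge-restricted
attention and graph pooling), concatenation, reshape, and numerically
stable sigmoid/softplus.  Float64 throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad=None):
        """Accumulate gradients of this tensor w.r.t. every ancestor."""
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that requires no grad")
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += _unbroadcast(g, parent.data.shape)

    def zero_grad(self):
        self.grad = None

    # -- operators ------------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitives ---------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data + b.data, parents=(a, b), backward=lambda g: (g, g))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        backward=lambda g: (g * b.data, g * a.data),
    )


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data**exponent
    return Tensor(
        out,
        parents=(a,),
        backward=lambda g: (g * exponent * a.data ** (exponent - 1.0),),
    )


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        backward=lambda g: (g @ b.data.T, a.data.T @ g),
    )


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        g_exp = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g_exp, a.data.shape).copy(),)

    return Tensor(out, parents=(a,), backward=backward)


def texp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * out,))


def tlog(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(np.log(a.data), parents=(a,), backward=lambda g: (g / a.data,))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, parents=(a,), backward=lambda g: (g * mask,))


def clamp(a, lo: float, hi: float) -> Tensor:
    """Hard clip; gradient passes only where the input is within [lo, hi]."""
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)
    return Tensor(np.clip(a.data, lo, hi), parents=(a,), backward=lambda g: (g * mask,))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = expit(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * out * (1.0 - out),))


def softplus(a) -> Tensor:
    """log(1 + exp(x)), computed stably; derivative is sigmoid(x)."""
    a = as_tensor(a)
    out = np.logaddexp(0.0, a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * expit(a.data),))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return Tensor(
        a.data.reshape(shape),
        parents=(a,),
        backward=lambda g: (g.reshape(a.data.shape),),
    )


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=lambda g: tuple(np.split(g, splits, axis=axis)),
    )


def gather(a, indices) -> Tensor:
    """Select rows along axis 0; backward scatter-adds."""
    a = as_tensor(a)
    indices = np.asarray(indices, dtype=int)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, indices, g)
        return (out,)

    return Tensor(a.data[indices], parents=(a,), backward=backward)


def segment_sum(a, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets along axis 0."""
    a = as_tensor(a)
    segment_ids = np.asarray(segment_ids, dtype=int)
    out = np.zeros((num_segments,) + a.data.shape[1:])
    np.add.at(out, segment_ids, a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g[segment_ids],))
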