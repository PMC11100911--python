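"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the geometric message-passing layers and
the diffusion objectives need: elementwise arithmetic with broadcasting,
matrix products, channel mixing for per-node vector features, row gather /
segment-sum (the graph primitives), reductions and a handful of smooth
nonlinearities.  Everything is float64; gradients are accumulated by a
topological backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "take_rows",
    "segment_sum",
    "vecmix",
    "silu",
    "softmax_rows",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                order.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    # -------------------------------------------------------------- functions
    def exp(self):
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out.data)

        out._backward = backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data**2))

        out._backward = backward
        return out

    def sigmoid(self):
        from scipy.special import expit

        s = expit(self.data)
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            parents=(self,),
        )

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if isinstance(key, np.ndarray):
                    np.add.at(full, key, g)
                else:
                    full[key] += g
                self._accumulate(full)

        out._backward = backward
        return out


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def take_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows (axis 0) by an integer index array."""
    index = np.asarray(index, dtype=np.intp)
    out = Tensor(t.data[index], requires_grad=t.requires_grad, parents=(t,))

    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, index, g)
            t._accumulate(full)

    out._backward = backward
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets (graph aggregation)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, t.data)
    out = Tensor(data, requires_grad=t.requires_grad, parents=(t,))

    def backward(g):
        if t.requires_grad:
            t._accumulate(g[segment_ids])

    out._backward = backward
    return out


def vecmix(weight: Tensor, vectors: Tensor) -> Tensor:
    """Mix vector channels: out[n, o, :] = sum_i W[o, i] * V[n, i, :].

    The per-node 3-vectors are combined linearly across channels only, which
    keeps the operation rotation-equivariant.
    """
    weight = as_tensor(weight)
    vectors = as_tensor(vectors)
    out = Tensor(
        np.matmul(weight.data, vectors.data),
        requires_grad=weight.requires_grad or vectors.requires_grad,
        parents=(weight, vectors),
    )

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(np.tensordot(g, vectors.data, axes=([0, 2], [0, 2])))
        if vectors.requires_grad:
            vectors._accumulate(np.matmul(weight.data.T, g))

    out._backward = backward
    return out


def silu(t: Tensor) -> Tensor:
    return t * t.sigmoid()


def softmax_rows(t: Tensor) -> Tensor:
    """Row-wise softmax (last axis), stabilised with a detached max shift."""
    shift = Tensor(t.data.max(axis=-1, keepdims=True))
    e = (t - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)
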