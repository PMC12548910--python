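"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The synergy model is small (graphs of tens of nodes, hidden dims of tens),
so a straightforward define-by-run tape over dense float64 arrays is both
fast enough and exact enough for finite-difference verification. Only the
operations the model needs are implemented.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "softmax_rows", "log_clipped",
           "scatter_symmetric"]

_LOG_CLIP = 1e-12  # floor applied to probabilities before log


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only supported by scalars")
        return self * (1.0 / float(other))

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy()
                              if np.ndim(g) else np.full(a.shape, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis: int = 0):
        """Max-reduce along one axis; gradient routes to the argmax entry."""
        a = self
        idx = np.argmax(a.data, axis=axis)

        def backward(g):
            if not a.requires_grad:
                return
            grad = np.zeros_like(a.data)
            grid = np.indices(idx.shape)
            index = list(grid)
            index.insert(axis, idx)
            grad[tuple(index)] = g
            a._accumulate(grad)

        return self._make(a.data.max(axis=axis), (a,), backward)

    # ------------------------------------------------------------- elementwise
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log_clipped(self):
        """log(max(x, eps)); the gradient is zero where the clip is active."""
        a = self
        clipped = np.maximum(a.data, _LOG_CLIP)
        active = a.data >= _LOG_CLIP

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * active / clipped)

        return self._make(np.log(clipped), (a,), backward)

    @property
    def T(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.T)

        return self._make(a.data.T, (a,), backward)

    def reshape(self, *shape):
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def softmax_rows(self):
        """Row-wise softmax for 2-D tensors."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            if a.requires_grad:
                dot = (g * out_data).sum(axis=-1, keepdims=True)
                a._accumulate(out_data * (g - dot))

        return self._make(out_data, (a,), backward)


# ------------------------------------------------------------ free functions
def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis`, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = backward
    return out


def scatter_symmetric(values: Tensor, rows, cols, n: int) -> Tensor:
    """Build an n x n symmetric matrix with ``values[k]`` at (rows[k], cols[k])
    and (cols[k], rows[k]); all other entries zero. Index pairs must be
    distinct unordered pairs off the diagonal."""
    values = Tensor._lift(values)
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    data = np.zeros((n, n))
    data[rows, cols] = values.data
    data[cols, rows] = values.data
    out = Tensor(data)
    if values.requires_grad:
        out.requires_grad = True
        out._parents = (values,)

        def backward(g):
            values._accumulate(g[rows, cols] + g[cols, rows])

        out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    return x.relu()


def softmax_rows(x: Tensor) -> Tensor:
    return x.softmax_rows()


def log_clipped(x: Tensor) -> Tensor:
    return x.log_clipped()
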