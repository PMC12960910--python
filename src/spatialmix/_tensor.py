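"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the mixture model, its losses and the
integrated-gradients attribution need: elementwise arithmetic with
broadcasting, matmul, exp/log/tanh/softplus/leaky-relu/elu, reductions,
row gathering, segment sums and a numerically stable (log-)softmax, plus
a segment softmax for attention over edge lists.

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on
a scalar. The graph is built eagerly; ``backward`` runs a topological
sort over parents. Float64 throughout: at desk scale the clarity and
testability of double precision beat speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):  # pragma: no cover - not needed
            raise TypeError("tensor exponents unsupported")

        def backward(g, a=self, p=exponent):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._from_op(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - o ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def softplus(self):
        # log(1 + e^x), overflow-safe
        out_data = np.logaddexp(0.0, self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / (1.0 + np.exp(-a.data)))

        return Tensor._from_op(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        out_data = np.where(pos, self.data, slope * self.data)

        def backward(g, a=self, mask=pos, s=slope):
            if a.requires_grad:
                a._accum(g * np.where(mask, 1.0, s))

        return Tensor._from_op(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        expm = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(pos, self.data, expm)

        def backward(g, a=self, mask=pos, e=expm, al=alpha):
            if a.requires_grad:
                a._accum(g * np.where(mask, 1.0, e + al))

        return Tensor._from_op(out_data, (self,), backward)

    def clamp_min(self, floor: float):
        """max(x, floor); gradient is 0 where the floor is active."""
        mask = self.data > floor
        out_data = np.where(mask, self.data, floor)

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if kd else np.expand_dims(g, ax)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        shifted = self.data - m
        lse = m + np.log(np.sum(np.exp(shifted), axis=axis, keepdims=True))
        soft = np.exp(self.data - lse)
        out_data = lse if keepdims else np.squeeze(lse, axis=axis)

        def backward(g, a=self, s=soft, ax=axis, kd=keepdims):
            if a.requires_grad:
                gg = g if kd else np.expand_dims(g, ax)
                a._accum(gg * s)

        return Tensor._from_op(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()

    def log_softmax(self, axis: int = -1):
        return self - self.logsumexp(axis=axis, keepdims=True)

    # -- shaping / indexing ---------------------------------------------------
    def reshape(self, *shape):
        old_shape = self.shape

        def backward(g, a=self, s=old_shape):
            if a.requires_grad:
                a._accum(g.reshape(s))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def take_rows(self, idx):
        """Gather rows along axis 0 (duplicates allowed)."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g, a=self, ii=idx):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.add.at(acc, ii, g)
                a._accum(acc)

        return Tensor._from_op(self.data[idx], (self,), backward)

    def segment_sum(self, segment_ids, num_segments: int):
        """Sum rows into ``num_segments`` buckets given per-row segment ids."""
        ids = np.asarray(segment_ids, dtype=np.intp)
        out_data = np.zeros((num_segments,) + self.data.shape[1:])
        np.add.at(out_data, ids, self.data)

        def backward(g, a=self, ii=ids):
            if a.requires_grad:
                a._accum(g[ii])

        return Tensor._from_op(out_data, (self,), backward)

    def segment_softmax(self, segment_ids, num_segments: int):
        """Softmax over groups of rows sharing a segment id (attention norm).

        Stability shift by the per-segment max is treated as a constant,
        which leaves the gradient exact (softmax is shift-invariant).
        """
        ids = np.asarray(segment_ids, dtype=np.intp)
        seg_max = np.full((num_segments,) + self.data.shape[1:], -np.inf)
        np.maximum.at(seg_max, ids, self.data)
        shifted = self - Tensor(seg_max[ids])
        ex = shifted.exp()
        denom = ex.segment_sum(ids, num_segments)
        return ex / denom.take_rows(ids)

    # -- autograd driver ------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a matrix."""
    return concat([t.reshape(1, -1) for t in tensors], axis=0)
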