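"""Minimal reverse-mode automatic differentiation over numpy arrays.

The multiscale attention model and the fine-tuning MLP are trained with
full-graph gradient descent; this module supplies the small set of
differentiable primitives they need (dense linear algebra, elementwise
nonlinearities, gather/segment reductions for per-neighborhood softmax).
Gradients are accumulated by topological traversal of the recorded tape.

Every op is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "segment_softmax"]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop.

    Parameters with ``requires_grad=True`` accumulate into ``.grad`` when
    ``backward()`` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- broadcasting-aware grad reduction ------------------------------------

    @staticmethod
    def _unbroadcast(g, shape):
        """Sum gradient ``g`` down to ``shape`` (undo numpy broadcasting)."""
        if g.shape == shape:
            return g
        extra = g.ndim - len(shape)
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g.reshape(shape)

    # -- arithmetic ------------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(Tensor._unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(Tensor._unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(Tensor._unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(Tensor._unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(Tensor._unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(
                    Tensor._unbroadcast(-g * a.data / (b.data**2), b.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    # -- shape ops -------------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def gather(self, idx):
        """Row selection ``x[idx]`` with scatter-add backward."""
        idx = np.asarray(idx)

        def backward(g, a=self):
            if a.requires_grad:
                out = np.zeros_like(a.data)
                np.add.at(out, idx, g)
                a._accumulate(out)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions ------------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.full_like(a.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * factor)

        return Tensor._make(self.data * factor, (self,), backward)

    def tanh(self):
        out = np.tanh(self.data)

        def backward(g, a=self, out=out):
            if a.requires_grad:
                a._accumulate(g * (1.0 - out**2))

        return Tensor._make(out, (self,), backward)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g, a=self, out=out):
            if a.requires_grad:
                a._accumulate(g * out * (1.0 - out))

        return Tensor._make(out, (self,), backward)

    def exp(self):
        out = np.exp(np.clip(self.data, -700, 700))

        def backward(g, a=self, out=out):
            if a.requires_grad:
                a._accumulate(g * out)

        return Tensor._make(out, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out = np.sqrt(self.data)

        def backward(g, a=self, out=out):
            if a.requires_grad:
                a._accumulate(g * 0.5 / out)

        return Tensor._make(out, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior only."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- backward driver -------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS post-order (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def segment_sum(x: Tensor, segments, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row ids."""
    segments = np.asarray(segments)

    def backward(g, a=x):
        if a.requires_grad:
            a._accumulate(g[segments])

    out = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(out, segments, x.data)
    return Tensor._make(out, (x,), backward)


def segment_softmax(scores: Tensor, segments, n_segments: int) -> Tensor:
    """Softmax of ``scores`` rows grouped by segment id (per-neighborhood
    attention normalization). Numerically stabilized by subtracting the
    per-segment max as a constant, which leaves the softmax unchanged."""
    segments = np.asarray(segments)
    smax = np.full((n_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(smax, segments, scores.data)
    shifted = scores - Tensor(smax[segments])
    e = shifted.exp()
    denom = segment_sum(e, segments, n_segments)
    return e / denom.gather(segments)
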