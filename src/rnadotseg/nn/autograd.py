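"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the tensor operations the segmentation network needs:
elementwise arithmetic with broadcasting, reductions, reshapes, channel
concatenation, sigmoid/GELU/tanh nonlinearities and the convolution
primitives defined in :mod:`rnadotseg.nn.ops`.  Gradients are accumulated
by topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
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
        self.grad = np.ones_like(self.data) if grad is None \
            else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        needs = any(p.requires_grad or p._prev for p in prev)
        out = Tensor(data, _prev=tuple(prev) if needs else ())
        if needs:
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path, keeps dtype
            c = other

            def backward_s(g):
                self._accumulate(g)

            return self._make(self.data + c, (self,), backward_s)
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            c = other

            def backward_s(g):
                self._accumulate(g * c)

            return self._make(self.data * c, (self,), backward_s)
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._lift(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            return self ** (-1.0) * other
        return self._lift(other) * self ** (-1.0)

    @staticmethod
    def _pow(x: np.ndarray, e: float) -> np.ndarray:
        # np.power with a float exponent is slow; special-case the exponents
        # the network actually uses
        if e == 2.0:
            return x * x
        if e == -1.0:
            return 1.0 / x
        if e == 0.5:
            return np.sqrt(x)
        if e == -0.5:
            return 1.0 / np.sqrt(x)
        if e == -2.0:
            return 1.0 / (x * x)
        return np.power(x, e)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            self._accumulate(g * e * self._pow(self.data, e - 1.0))

        return self._make(self._pow(self.data, e), (self,), backward)

    # -- reductions & shape ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- nonlinearities -------------------------------------------------

    def sigmoid(self):
        # clamp the logit so float32 exp cannot overflow; sigmoid is already
        # saturated to machine precision well inside +/-60
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def gelu(self):
        # tanh approximation; derivative in closed form
        c = float(np.sqrt(2.0 / np.pi))  # python float keeps float32 arrays float32
        x = self.data
        x2 = x * x
        t = np.tanh(c * (x + 0.044715 * (x2 * x)))

        def backward(g):
            du = c * (1.0 + (3 * 0.044715) * x2)
            self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du))

        return self._make(0.5 * x * (1.0 + t), (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            self._accumulate(g * e)

        return self._make(e, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor; `trainable` gates optimizer updates (backbone freezing)."""

    __slots__ = ("trainable",)

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.trainable = True


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` (channel concatenation in the decoder)."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    needs = any(t.requires_grad or t._prev for t in tensors)
    out = Tensor(data, _prev=tuple(tensors) if needs else ())
    if needs:
        out._backward = backward
    return out
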