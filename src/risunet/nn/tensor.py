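"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ``ndarray`` and records, for every
operation, a closure that propagates the adjoint to its parents.  Calling
:meth:`Tensor.backward` on a scalar loss walks the recorded graph in reverse
topological order and accumulates ``grad`` on every tensor that requires it.

The op set is deliberately small: the elementwise/reduction primitives live
here, the structured 2D ops (convolution, pooling, batch norm) in
:mod:`risunet.nn.functional`.  Everything is float64 — segmentation batches
at the sizes this package trains are cheap enough that numerical robustness
(exact gradient checks, bit-reproducible runs) wins over float32 speed.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (inference mode); nests safely."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make `ndarray <op> Tensor` dispatch to the Tensor reflected op
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar tensor")
            grad = np.ones_like(self.data)
        # iterative topological sort (training graphs are deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = make(self.data + other.data, (self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self.accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other.accumulate(_unbroadcast(g, other.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = make(self.data * other.data, (self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self.accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other.accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = make(self.data / other.data, (self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self.accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other.accumulate(_unbroadcast(
                        -g * self.data / (other.data ** 2), other.shape))
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = make(self.data ** exponent, (self,))
        if out.requires_grad:
            def backward(g):
                self.accumulate(g * exponent * self.data ** (exponent - 1))
            out._backward = backward
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = make(np.where(mask, self.data, 0.0), (self,))
        if out.requires_grad:
            def backward(g):
                self.accumulate(g * mask)
            out._backward = backward
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = make(y, (self,))
        if out.requires_grad:
            def backward(g):
                self.accumulate(g * y * (1.0 - y))
            out._backward = backward
        return out

    def log(self):
        out = make(np.log(self.data), (self,))
        if out.requires_grad:
            def backward(g):
                self.accumulate(g / self.data)
            out._backward = backward
        return out

    def clamp(self, lo: float, hi: float):
        """Clip values to [lo, hi]; gradient passes only inside the range."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = make(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            def backward(g):
                self.accumulate(g * inside)
            out._backward = backward
        return out

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def backward(g):
                if axis is None:
                    self.accumulate(np.broadcast_to(g, self.shape).copy())
                    return
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self.accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            def backward(g):
                self.accumulate(g.reshape(self.shape))
            out._backward = backward
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def make(data: np.ndarray, parents: tuple) -> Tensor:
    """Create a graph node; records parents only while grad mode is on."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = make(np.concatenate(datas, axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t.accumulate(g[tuple(sl)])
        out._backward = backward
    return out
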