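"""A small reverse-mode automatic differentiation engine on numpy arrays.

Supports exactly the operations the model needs: broadcasting arithmetic,
(batched) matmul, the usual pointwise nonlinearities, reductions, reshaping,
concatenation/slicing, row gathering and segment sums (the scatter-add used
for graph neighbor aggregation and per-graph pooling). Gradients are checked
against central finite differences in the test suite.

Usage mirrors the familiar tape-based pattern::

    x = Tensor(np.random.randn(3, 4), requires_grad=True)
    y = (x @ w + b).relu().sum()
    y.backward()
    x.grad  # dL/dx
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=rg, _parents=parents if rg else (),
                      _backward=backward if rg else None)

    def _accum(self, grad: np.ndarray) -> None:
        # first accumulation copies (grad may alias a child's buffer)
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            def backward_s(out):
                if self.requires_grad:
                    self._accum(out.grad)

            return self._make(self.data + other, (self,), backward_s)
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._lift(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return self._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def backward_s(out):
                if self.requires_grad:
                    self._accum(out.grad * other)

            return self._make(self.data * other, (self,), backward_s)
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2,
                                 other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                g = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    def __pow__(self, p: float):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    # -- pointwise nonlinearities -----------------------------------------

    def exp(self):
        value = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * value)

        return self._make(value, (self,), backward)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        value = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - value**2))

        return self._make(value, (self,), backward)

    def sigmoid(self):
        value = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * value * (1.0 - value))

        return self._make(value, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return self._make(np.maximum(self.data, 0.0), (self,), backward)

    def leaky_relu(self, alpha: float = 0.2):
        slope = np.where(self.data > 0, 1.0, alpha)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * slope)

        return self._make(self.data * slope, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only where unclipped."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions / shape -----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes: tuple[int, ...]):
        inv = np.argsort(axes)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accum(g)

        return self._make(self.data[key], (self,), backward)

    # -- gather / scatter ---------------------------------------------------

    def gather_rows(self, index: np.ndarray):
        """Rows `self[index]`; backward scatter-adds into the source rows."""
        index = np.asarray(index, dtype=np.int64)

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, index, out.grad)
                self._accum(g)

        return self._make(self.data[index], (self,), backward)

    def segment_sum(self, index: np.ndarray, n_segments: int):
        """Sum rows into `n_segments` buckets given per-row bucket indices."""
        index = np.asarray(index, dtype=np.int64)
        out_data = np.zeros((n_segments,) + self.data.shape[1:],
                            dtype=self.data.dtype)
        np.add.at(out_data, index, self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad[index])

        return self._make(out_data, (self,), backward)

    # -- autograd ----------------------------------------------------------

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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis if axis >= 0 else out.grad.ndim + axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    rg = any(t.requires_grad for t in tensors)
    return Tensor(data, requires_grad=rg, _parents=tuple(tensors) if rg else (),
                  _backward=backward if rg else None)


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a matrix (axis 0)."""
    def backward(out):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(out.grad[i])

    data = np.stack([t.data for t in tensors])
    rg = any(t.requires_grad for t in tensors)
    return Tensor(data, requires_grad=rg, _parents=tuple(tensors) if rg else (),
                  _backward=backward if rg else None)
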