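"""A small reverse-mode automatic-differentiation engine over numpy arrays.

The neural predictors in this package run at desk scale (hidden widths of
a few units, 20 x 20 feature maps), where a compact tape-based engine is
sufficient and keeps the package self-contained. ``Tensor`` wraps an
ndarray, records the operations applied to it, and ``backward()`` walks
the tape in reverse topological order accumulating gradients into every
tensor created with ``requires_grad=True``.

Supported primitives: elementwise arithmetic with numpy broadcasting,
matmul, exp/log/tanh/sigmoid/relu, power, reductions (sum/mean), elementwise
maximum, shape ops (reshape/transpose/concat/pad/basic slicing). Anything
else (softmax, convolutions, LSTM cells) is composed from these in
:mod:`idrfuse.layers`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "maximum", "sigmoid", "relu", "softmax", "pad2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes broadcasting added relative to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        data = self.data ** exponent

        def backward(g, out):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return self._make(data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        data = np.exp(self.data)

        def backward(g, out):
            return (g * out.data,)

        return self._make(data, (self,), backward)

    def log(self):
        def backward(g, out):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g, out):
            return (g * (1.0 - out.data ** 2),)

        return self._make(data, (self,), backward)

    def relu(self):
        data = np.maximum(self.data, 0.0)

        def backward(g, out):
            return (g * (self.data > 0.0),)

        return self._make(data, (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, out):
            return (g * out.data * (1.0 - out.data),)

        return self._make(data, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, out):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward(g, out):
            return (g.transpose(inverse),)

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, index):
        """Basic (slice/int/ellipsis) indexing only; repeated fancy indices
        are not supported, which keeps the backward a plain scatter-add."""

        def backward(g, out):
            full = np.zeros(self.shape, dtype=np.float64)
            full[index] += g
            return (full,)

        return self._make(self.data[index], (self,), backward)

    # -- autodiff ----------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
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
            for parent in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g, node)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


# ---------------------------------------------------------------------------
# Free functions
# ---------------------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, out):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(lo, hi)
            grads.append(g[tuple(index)])
        return tuple(grads)

    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad or t._parents for t in tensors):
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; ties send the gradient to the first argument."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    mask = a.data >= b.data

    def backward(g, out):
        return (
            _unbroadcast(g * mask, a.shape),
            _unbroadcast(g * ~mask, b.shape),
        )

    out = Tensor(np.maximum(a.data, b.data))
    if any(t.requires_grad or t._parents for t in (a, b)):
        out._parents = (a, b)
        out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    return Tensor._lift(x).sigmoid()


def relu(x: Tensor) -> Tensor:
    return Tensor._lift(x).relu()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the last two axes of a (..., H, W) tensor by ``pad``."""
    if pad == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]

    def backward(g, out):
        index = tuple(
            slice(None) if lo == 0 else slice(lo, -hi) for lo, hi in widths
        )
        return (g[index],)

    out = Tensor(np.pad(x.data, widths))
    if x.requires_grad or x._parents:
        out._parents = (x,)
        out._backward = backward
    return out
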