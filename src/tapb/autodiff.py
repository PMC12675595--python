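"""Reverse-mode automatic differentiation on numpy arrays.

The model in :mod:`tapb.model` is small (widths of a few dozen channels,
three-layer stacks), so a compact tape-based engine over float64 numpy
arrays is sufficient and keeps the whole package pure-Python. Only the
primitives the model needs are implemented; gradients are checked
numerically in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "embedding",
    "softmax",
    "layer_norm",
    "relu",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
    ):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers ------------------------------------
    def _lift(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep the graph in this tensor's dtype (python floats would upcast)
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def _make(self, data, parents, backward) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, parents=parents, backward=backward)
        return Tensor(data)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(grad):
            return (
                _unbroadcast(grad, self.data.shape),
                _unbroadcast(grad, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.data.shape),
                _unbroadcast(grad * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self**-1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def backward(grad):
            return (grad * exponent * self.data ** (exponent - 1.0),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(grad):
            ga = np.matmul(grad, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), grad)
            return (
                _unbroadcast(ga, self.data.shape),
                _unbroadcast(gb, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    # -- elementwise functions -----------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad):
            return (grad * out_data,)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(grad):
            return (grad / self.data,)

        return self._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(grad):
            return (grad * (1.0 - out_data**2),)

        return self._make(out_data, (self,), backward)

    def clip_min(self, floor: float) -> "Tensor":
        """Clamp from below; gradient passes only where input was above floor."""
        out_data = np.maximum(self.data, floor)
        mask = (self.data > floor).astype(np.float64)

        def backward(grad):
            return (grad * mask,)

        return self._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)
        orig = self.data.shape

        def backward(grad):
            return (grad.reshape(orig),)

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        out_data = self.data.transpose(*axes)
        inverse = np.argsort(axes)

        def backward(grad):
            return (grad.transpose(*inverse),)

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def backward(grad):
            return (np.swapaxes(grad, a, b),)

        return self._make(out_data, (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def backward(grad):
            g = np.zeros_like(self.data)
            np.add.at(g, key, grad)
            return (g,)

        return self._make(out_data, (self,), backward)

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad += pgrad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


# -- free functions ----------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    if any(t.requires_grad for t in tensors):
        return Tensor(out_data, parents=tensors, backward=backward)
    return Tensor(out_data)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def backward(grad):
        g = np.zeros_like(table.data)
        np.add.at(g, ids, grad)
        return (g,)

    if table.requires_grad:
        return Tensor(out_data, parents=(table,), backward=backward)
    return Tensor(out_data)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; ``mask`` positions (False) get zero weight."""
    logits = x.data
    if mask is not None:
        logits = np.where(mask, logits, -1e30)
    m = logits.max(axis=axis, keepdims=True)
    e = np.exp(logits - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(grad):
        g = (grad - (grad * s).sum(axis=axis, keepdims=True)) * s
        return (g,)

    if x.requires_grad:
        return Tensor(s, parents=(x,), backward=backward)
    return Tensor(s)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with a fused analytic backward."""
    mu = x.data.mean(axis=-1, keepdims=True)
    centered = x.data - mu
    inv = 1.0 / np.sqrt((centered * centered).mean(axis=-1, keepdims=True) + eps)
    y = centered * inv
    out_data = y * gain.data + bias.data

    def backward(grad):
        d = x.data.shape[-1]
        gg = grad * gain.data
        gx = inv * (
            gg
            - gg.mean(axis=-1, keepdims=True)
            - y * (gg * y).mean(axis=-1, keepdims=True)
        )
        axes = tuple(range(grad.ndim - 1))
        return (gx, (grad * y).sum(axis=axes), grad.sum(axis=axes))

    if x.requires_grad or gain.requires_grad or bias.requires_grad:
        return Tensor(out_data, parents=(x, gain, bias), backward=backward)
    return Tensor(out_data)


def relu(x: Tensor) -> Tensor:
    return x.clip_min(0.0)
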