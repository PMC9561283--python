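"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough tensor machinery for the convolutional / attention-MIL models
in this package: broadcasting arithmetic, matmul with 2-D weights, the
activations, axis reductions, 1-D unfold (im2col) for convolution, max
pooling and a numerically stable softmax / softplus.  Everything is float64
and deterministic.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Tensor", "tanh", "sigmoid", "relu", "exp", "log", "softplus",
    "softmax", "concat", "unfold1d", "maxpool1d", "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward=None) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bwd
        return out

    def __matmul__(self, other):
        """Matrix product; the right operand must be 2-D (a weight matrix)."""
        other = self._wrap(other)
        if other.data.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            self._accum(g @ other.data.T)
            a = self.data.reshape(-1, self.data.shape[-1])
            gg = g.reshape(-1, g.shape[-1])
            other._accum(a.T @ gg)

        out._backward = bwd
        return out

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# ---------------------------------------------------------------------------
# elementwise functions


def _unary(x: Tensor, value: np.ndarray, dvalue: np.ndarray) -> Tensor:
    out = Tensor(value, parents=(x,))
    out._backward = lambda g: x._accum(g * dvalue)
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return _unary(x, y, 1.0 - y**2)


def sigmoid(x: Tensor) -> Tensor:
    y = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    return _unary(x, y, y * (1.0 - y))


def relu(x: Tensor) -> Tensor:
    return _unary(x, np.maximum(x.data, 0.0), (x.data > 0).astype(np.float64))


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    return _unary(x, y, y)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log(x.data), 1.0 / x.data)


def softplus(x: Tensor) -> Tensor:
    y = np.logaddexp(0.0, x.data)
    s = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    return _unary(x, y, s)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# structural ops


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


def unfold1d(x: Tensor, kernel: int) -> Tensor:
    """im2col for 'same' 1-D convolution: (B, L, C) -> (B, L, kernel*C)."""
    if kernel % 2 == 0:
        raise ValueError("kernel must be odd for 'same' padding")
    B, L, C = x.data.shape
    p = (kernel - 1) // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (0, 0)))
    cols = np.empty((B, L, kernel * C), dtype=np.float64)
    for j in range(kernel):
        cols[:, :, j * C : (j + 1) * C] = xp[:, j : j + L, :]
    out = Tensor(cols, parents=(x,))

    def bwd(g):
        gx = np.zeros_like(xp)
        for j in range(kernel):
            gx[:, j : j + L, :] += g[:, :, j * C : (j + 1) * C]
        x._accum(gx[:, p : p + L, :])

    out._backward = bwd
    return out


def maxpool1d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping max pooling along axis 1; a ragged tail is dropped."""
    B, L, C = x.data.shape
    Lc = (L // pool) * pool
    view = x.data[:, :Lc, :].reshape(B, Lc // pool, pool, C)
    y = view.max(axis=2)
    arg = view.argmax(axis=2)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        gwin = np.zeros((B, Lc // pool, pool, C), dtype=np.float64)
        b_idx, w_idx, c_idx = np.meshgrid(
            np.arange(B), np.arange(Lc // pool), np.arange(C), indexing="ij"
        )
        gwin[b_idx, w_idx, arg, c_idx] = g
        gx = np.zeros_like(x.data)
        gx[:, :Lc, :] = gwin.reshape(B, Lc, C)
        x._accum(gx)

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, computed stably from logits."""
    y = np.asarray(targets, dtype=np.float64).reshape(logits.data.shape)
    return (softplus(logits) - logits * y).mean()
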