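"""Layer modules on top of the autograd engine.

Initialization is Glorot-uniform from a NumPy Generator supplied by the
model, so a model seed fully determines the parameters, the dropout masks
and hence the training trajectory.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Dense", "Conv1d", "MaxPool1d", "Dropout",
           "GatedAttention", "Sequential", "ReLU", "Flatten"]


class Module:
    """Base class: parameter collection and train/eval mode."""

    training: bool = False

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                yield from (m for m in v if isinstance(m, Module))

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.weight = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """'Same'-padded 1-D convolution over (B, L, C_in) -> (B, L, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        self.kernel = kernel
        self.weight = _glorot(rng, kernel * c_in, c_out, (kernel * c_in, c_out))
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.unfold1d(x, self.kernel) @ self.weight + self.bias


class MaxPool1d(Module):
    def __init__(self, pool: int = 2) -> None:
        self.pool = pool

    def forward(self, x: Tensor) -> Tensor:
        return ag.maxpool1d(x, self.pool)


class Dropout(Module):
    """Inverted dropout; identity in eval mode, seeded mask in train mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * mask


class GatedAttention(Module):
    """Gated attention pooling over a bag of feature vectors.

    query_i = tanh(h_i V) * sigmoid(h_i U); score_i = query_i w; the
    attention weights are the softmax of the scores over bag members and the
    pooled vector is the weighted sum of the h_i.  Padded members are
    excluded by pushing their scores to -inf before the softmax.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator) -> None:
        self.V = _glorot(rng, n_in, hidden, (n_in, hidden))
        self.U = _glorot(rng, n_in, hidden, (n_in, hidden))
        self.w = _glorot(rng, hidden, 1, (hidden, 1))

    def forward(self, h: Tensor, mask: Optional[np.ndarray] = None
                ) -> tuple[Tensor, Tensor]:
        """h: (k, d) bag -> (pooled (1, d), weights (k, 1))."""
        query = ag.tanh(h @ self.V) * ag.sigmoid(h @ self.U)
        scores = query @ self.w  # (k, 1)
        if mask is not None:
            bias = np.where(np.asarray(mask, bool).reshape(-1, 1), 0.0, -1e30)
            scores = scores + bias
        weights = ag.softmax(scores, axis=0)
        pooled = (weights * h).sum(axis=0, keepdims=True)
        return pooled, weights


class Sequential(Module):
    def __init__(self, layers: Sequence[Module]) -> None:
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)
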