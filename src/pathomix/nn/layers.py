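"""Neural-network building blocks on top of :mod:`pathomix.nn.tensor`.

All fully connected blocks use uniform weight initialization
U(-1/sqrt(k), 1/sqrt(k)) with k the fan-in, and optional batch
normalization and dropout on hidden layers.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "BlockSparseLinear",
    "BatchNorm1d",
    "Dropout",
    "ReLU",
    "Sequential",
    "mlp",
]


class Module:
    """Base class: tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Tensor]:
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays but module has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = (
            Tensor(rng.uniform(-bound, bound, size=(out_features,)), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BlockSparseLinear(Module):
    """Linear map where disjoint input blocks feed disjoint output slices.

    Used for the chromosome-blocked first layer of the methylation
    sub-encoder: each chromosome's genes connect only to that chromosome's
    hidden units, so the parameter count is sum(n_b * h_b) rather than
    (sum n_b) * (sum h_b).
    """

    def __init__(self, block_in: Sequence[int], block_out: Sequence[int],
                 rng: np.random.Generator):
        super().__init__()
        if len(block_in) != len(block_out):
            raise ValueError("block_in and block_out must have equal length")
        self.block_in = list(block_in)
        self.block_out = list(block_out)
        self.weights = []
        self.biases = []
        for n_in, n_out in zip(block_in, block_out):
            bound = 1.0 / np.sqrt(n_in)
            self.weights.append(
                Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
            )
            self.biases.append(
                Tensor(rng.uniform(-bound, bound, size=(n_out,)), requires_grad=True)
            )

    @property
    def n_parameters(self) -> int:
        return sum(w.data.size + b.data.size for w, b in zip(self.weights, self.biases))

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import concat

        outs = []
        start = 0
        for n_in, w, b in zip(self.block_in, self.weights, self.biases):
            outs.append(x[:, start : start + n_in] @ w + b)
            start += n_in
        return concat(outs, axis=-1)


class BatchNorm1d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel()
            )
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = self.rng.random(x.shape) >= self.rate
        return x * Tensor(keep / (1.0 - self.rate))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def mlp(sizes: Sequence[int], rng: np.random.Generator, *, batch_norm: bool = False,
        dropout: float = 0.0, final_activation: bool = False) -> Sequential:
    """Fully connected stack with ReLU hidden activations."""
    layers: list[Module] = []
    for i in range(len(sizes) - 1):
        layers.append(Linear(sizes[i], sizes[i + 1], rng))
        is_last = i == len(sizes) - 2
        if not is_last or final_activation:
            if batch_norm:
                layers.append(BatchNorm1d(sizes[i + 1]))
            layers.append(ReLU())
            if dropout > 0:
                layers.append(Dropout(dropout, rng))
    return Sequential(*layers)
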