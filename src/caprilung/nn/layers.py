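"""Minimal neural-network building blocks over the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, layer_norm

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "cross_entropy"]


class Parameter(Tensor):
    """A tensor registered as trainable state of a :class:`Module`."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery (attribute order)."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match module parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.astype(np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) resampled into [-2 std, 2 std]."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` (B, K)."""
    m = logits.data.max(axis=-1, keepdims=True)  # constant shift for stability
    shifted = logits - m
    logZ = shifted.exp().sum(axis=-1, keepdims=True).log()
    logp = shifted - logZ
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()
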