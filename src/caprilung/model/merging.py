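"""Downsampling between stages: standard patch merging and the adaptive
salience-masked variant (ASAP).

ASAP scores each spatial position with a depthwise-3x3 + pointwise-1x1
salience head (sigmoid output), turns the score into a soft mask through a
steep sigmoid around a learnable threshold alpha (fixed slope 10), weights
the *raw* input by the mask, average-pools 2x2 and expands channels C -> 2C
with a 1x1 convolution.
"""

from __future__ import annotations

import numpy as np

from ..nn import LayerNorm, Linear, Module, Parameter, Tensor, concat
from ..nn.layers import trunc_normal

__all__ = ["PatchMerging", "ASAPMerging"]


class PatchMerging(Module):
    """Concatenate 2x2 neighbourhoods, normalize, project 4C -> 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor, hw: tuple[int, int]) -> Tensor:
        h, w = hw
        b = x.shape[0]
        if h % 2 or w % 2:
            raise ValueError("patch merging needs even spatial dims")
        x = x.reshape(b, h, w, self.dim)
        quads = [x[:, 0::2, 0::2, :], x[:, 1::2, 0::2, :],
                 x[:, 0::2, 1::2, :], x[:, 1::2, 1::2, :]]
        x = concat(quads, axis=-1)  # (B, H/2, W/2, 4C)
        x = self.reduction(self.norm(x))
        return x.reshape(b, (h // 2) * (w // 2), 2 * self.dim)


class ASAPMerging(Module):
    """Salience-masked adaptive downsampling (C -> 2C, H,W -> H/2,W/2)."""

    def __init__(self, dim: int, rng: np.random.Generator, alpha_init: float = 0.5,
                 slope: float = 10.0):
        self.dim = dim
        self.slope = slope  # fixed, non-learnable mask steepness
        self.norm = LayerNorm(dim)
        self.dw_weight = Parameter(trunc_normal(rng, (3, 3, dim)))
        self.dw_bias = Parameter(np.zeros(dim))
        self.pointwise = Linear(dim, 1, rng)
        self.alpha = Parameter(np.array(alpha_init))
        self.expand = Linear(dim, 2 * dim, rng)  # 1x1 conv C -> 2C

    def salience(self, x: Tensor, hw: tuple[int, int]) -> Tensor:
        """Sigmoid salience map (B, H, W, 1) from normalized features."""
        h, w = hw
        b = x.shape[0]
        xs = self.norm(x).reshape(b, h, w, self.dim)
        xp = xs.pad2d(1, 1, axes=(1, 2))
        acc = None
        for dy in range(3):
            for dx in range(3):
                term = xp[:, dy : dy + h, dx : dx + w, :] * self.dw_weight[dy, dx]
                acc = term if acc is None else acc + term
        conv = acc + self.dw_bias
        return self.pointwise(conv).sigmoid()

    def forward(self, x: Tensor, hw: tuple[int, int]) -> Tensor:
        h, w = hw
        b = x.shape[0]
        if h % 2 or w % 2:
            raise ValueError("adaptive merging needs even spatial dims")
        sal = self.salience(x, hw)
        mask = ((sal - self.alpha) * self.slope).sigmoid()  # (B, H, W, 1)
        raw = x.reshape(b, h, w, self.dim)
        weighted = raw * mask
        pooled = weighted.reshape(b, h // 2, 2, w // 2, 2, self.dim).mean(axis=(2, 4))
        out = self.expand(pooled)  # (B, H/2, W/2, 2C)
        return out.reshape(b, (h // 2) * (w // 2), 2 * self.dim)
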