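"""Frequency-aware MLP: band-split feed-forward replacing the uniform MLP.

The token grid is split along the frequency axis into low / mid / high bands
of heights floor(H/3), floor(H/3), H - 2*floor(H/3).  Slowly-varying low
frequencies get a bottleneck (C -> C/2 -> C, GELU), the mid band a
same-width transform (C -> C -> C, GELU), and the detail-rich high band an
expansion (C -> 2C -> C, SiLU); the bands are re-concatenated along
frequency and fused by a final C -> C linear layer.
"""

from __future__ import annotations

import numpy as np

from ..nn import Linear, Module, Tensor, concat

__all__ = ["FrequencyAwareMLP", "band_heights"]


def band_heights(h: int) -> tuple[int, int, int]:
    """Low/mid/high band heights (floor(H/3), floor(H/3), remainder)."""
    if h < 3:
        raise ValueError("frequency split needs height >= 3")
    third = h // 3
    return third, third, h - 2 * third


class FrequencyAwareMLP(Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        if dim % 2:
            raise ValueError("channel dim must be even for the C/2 bottleneck")
        self.dim = dim
        self.low_in = Linear(dim, dim // 2, rng)
        self.low_out = Linear(dim // 2, dim, rng)
        self.mid_in = Linear(dim, dim, rng)
        self.mid_out = Linear(dim, dim, rng)
        self.high_in = Linear(dim, 2 * dim, rng)
        self.high_out = Linear(2 * dim, dim, rng)
        self.fuse = Linear(dim, dim, rng)

    def forward(self, x: Tensor, hw: tuple[int, int]) -> Tensor:
        h, w = hw
        b = x.shape[0]
        xs = x.reshape(b, h, w, self.dim)
        h_low, h_mid, _ = band_heights(h)
        x_low = xs[:, :h_low]
        x_mid = xs[:, h_low : h_low + h_mid]
        x_high = xs[:, h_low + h_mid :]
        out_low = self.low_out(self.low_in(x_low).gelu())
        out_mid = self.mid_out(self.mid_in(x_mid).gelu())
        out_high = self.high_out(self.high_in(x_high).silu())
        fused = self.fuse(concat([out_low, out_mid, out_high], axis=1))
        return fused.reshape(b, h * w, self.dim)
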