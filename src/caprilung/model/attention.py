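"""Window attention: the standard multi-head variant and the axial
decomposed variant (ADA).

ADA keeps one shared linear projection producing Q, K, V, then attends
independently along the time axis (within each frequency row of a window)
and along the frequency axis (within each time column), scales logits by
1/sqrt(d_k), softmax-normalizes per axis, concatenates the two branch
outputs on channels and projects 2C -> C.  No relative-position bias is used
inside ADA; the standard window attention keeps its bias table.
"""

from __future__ import annotations

import numpy as np

from ..nn import Linear, Module, Parameter, Tensor, concat
from ..nn.layers import trunc_normal

__all__ = ["WindowAttention", "AxialDecomposedAttention"]


def relative_position_index(ws: int) -> np.ndarray:
    """Pairwise relative-position index for an ws x ws window, (N, N)."""
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # (2, N, N)
    rel = rel.transpose(1, 2, 0) + (ws - 1)
    return rel[:, :, 0] * (2 * ws - 1) + rel[:, :, 1]


class WindowAttention(Module):
    """Standard window-based multi-head self-attention with relative bias."""

    def __init__(self, dim: int, heads: int, window: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("heads must divide dim")
        self.dim = dim
        self.heads = heads
        self.window = window
        self.d_k = dim // heads
        self.scale = self.d_k**-0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias_table = Parameter(
            trunc_normal(rng, ((2 * window - 1) ** 2, heads))
        )
        self._rel_index = relative_position_index(window).reshape(-1)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """``x``: (B_, ws, ws, C) windows; ``mask``: (nW, N, N) additive."""
        b_, h, w, c = x.shape
        n = h * w
        qkv = self.qkv(x.reshape(b_, n, c))  # (B_, N, 3C)
        qkv = qkv.reshape(b_, n, 3, self.heads, self.d_k).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B_, heads, N, d)
        attn = (q * self.scale) @ k.transpose(0, 1, 3, 2)  # (B_, heads, N, N)
        bias = self.rel_bias_table[self._rel_index].reshape(n, n, self.heads)
        attn = attn + bias.transpose(2, 0, 1)
        if mask is not None:
            n_win = mask.shape[0]
            attn = attn.reshape(b_ // n_win, n_win, self.heads, n, n)
            attn = attn + Tensor(mask[None, :, None])
            attn = attn.reshape(b_, self.heads, n, n)
        out = attn.softmax(-1) @ v  # (B_, heads, N, d)
        out = out.transpose(0, 2, 1, 3).reshape(b_, n, c)
        return self.proj(out).reshape(b_, h, w, c)


class AxialDecomposedAttention(Module):
    """Per-axis (time and frequency) window attention with fused output."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("heads must divide dim")
        self.dim = dim
        self.heads = heads
        self.d_k = dim // heads
        self.scale = self.d_k**-0.5
        self.qkv = Linear(dim, 3 * dim, rng)  # shared projection for Q, K, V
        self.proj = Linear(2 * dim, dim, rng)

    def forward(
        self,
        x: Tensor,
        mask_t: np.ndarray | None = None,
        mask_f: np.ndarray | None = None,
    ) -> Tensor:
        """``x``: (B_, H, W, C); H is frequency, W is time.

        ``mask_t``: (nW, H, W, W) additive mask for the temporal branch,
        ``mask_f``: (nW, W, H, H) for the frequency branch (shifted windows).
        """
        b_, hh, ww, c = x.shape
        nh, dk = self.heads, self.d_k
        qkv = self.qkv(x)  # (B_, H, W, 3C)
        q, k, v = (qkv[..., i * c : (i + 1) * c] for i in range(3))

        def rearrange_t(m):  # F: (B_, H, W, C) -> (B_, H, heads, W, d)
            return m.reshape(b_, hh, ww, nh, dk).transpose(0, 1, 3, 2, 4)

        def rearrange_f(m):  # G: (B_, H, W, C) -> (B_, W, heads, H, d)
            return m.reshape(b_, hh, ww, nh, dk).transpose(0, 2, 3, 1, 4)

        qt, kt, vt = rearrange_t(q), rearrange_t(k), rearrange_t(v)
        qf, kf, vf = rearrange_f(q), rearrange_f(k), rearrange_f(v)

        logits_t = (qt * self.scale) @ kt.transpose(0, 1, 2, 4, 3)
        if mask_t is not None:
            n_win = mask_t.shape[0]
            logits_t = logits_t.reshape(b_ // n_win, n_win, hh, nh, ww, ww)
            logits_t = logits_t + Tensor(mask_t[None, :, :, None])
            logits_t = logits_t.reshape(b_, hh, nh, ww, ww)
        score_t = logits_t.softmax(-1) @ vt  # (B_, H, heads, W, d)
        score_t = score_t.transpose(0, 1, 3, 2, 4).reshape(b_, hh, ww, c)

        logits_f = (qf * self.scale) @ kf.transpose(0, 1, 2, 4, 3)
        if mask_f is not None:
            n_win = mask_f.shape[0]
            logits_f = logits_f.reshape(b_ // n_win, n_win, ww, nh, hh, hh)
            logits_f = logits_f + Tensor(mask_f[None, :, :, None])
            logits_f = logits_f.reshape(b_, ww, nh, hh, hh)
        score_f = logits_f.softmax(-1) @ vf  # (B_, W, heads, H, d)
        score_f = score_f.transpose(0, 3, 1, 2, 4).reshape(b_, hh, ww, c)

        return self.proj(concat([score_t, score_f], axis=-1))
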