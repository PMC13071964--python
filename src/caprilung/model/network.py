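"""Assembly of the hierarchical windowed-attention classifier.

Four stages of transformer blocks over a 4x4 patch embedding; alternate
blocks use a cyclic shift of half the window (with the usual additive
attention masks so shifted windows never attend across wrap-around seams).
The three ablation flags swap in axial decomposed attention, adaptive
salience-masked merging, and the frequency-aware MLP.
"""

from __future__ import annotations

import numpy as np

from ..nn import LayerNorm, Linear, Module, Tensor, no_grad
from .attention import AxialDecomposedAttention, WindowAttention
from .config import ModelConfig
from .fam import FrequencyAwareMLP
from .merging import ASAPMerging, PatchMerging

__all__ = ["CapriLungNet", "build_model", "window_partition", "window_reverse"]

_MASK_NEG = -100.0


def window_partition(x: Tensor, ws: int) -> Tensor:
    """(B, H, W, C) -> (B * nW, ws, ws, C), row-major window order."""
    b, h, w, c = x.shape
    x = x.reshape(b, h // ws, ws, w // ws, ws, c).transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // ws) * (w // ws), ws, ws, c)


def window_reverse(xw: Tensor, ws: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    b = xw.shape[0] // ((h // ws) * (w // ws))
    x = xw.reshape(b, h // ws, w // ws, ws, ws, xw.shape[-1])
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h, w, xw.shape[-1])


def _region_ids(h: int, w: int, ws: int, shift: int) -> np.ndarray:
    """Per-window region ids (nW, ws, ws) after a cyclic shift, as in the
    standard shifted-window scheme."""
    img = np.zeros((h, w), dtype=np.int64)
    cnt = 0
    for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
        for vs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            img[hs, vs] = cnt
            cnt += 1
    win = img.reshape(h // ws, ws, w // ws, ws).transpose(0, 2, 1, 3)
    return win.reshape(-1, ws, ws)


def shifted_masks(h: int, w: int, ws: int, shift: int):
    """Additive masks for shifted windows.

    Returns ``(full, temporal, frequency)``: full (nW, N, N) for standard
    window attention; temporal (nW, ws, ws, ws) restricting attention within
    each frequency row; frequency (nW, ws, ws, ws) within each time column.
    """
    reg = _region_ids(h, w, ws, shift)  # (nW, ws, ws)
    flat = reg.reshape(-1, ws * ws)
    full = np.where(flat[:, :, None] == flat[:, None, :], 0.0, _MASK_NEG)
    temporal = np.where(reg[:, :, :, None] == reg[:, :, None, :], 0.0, _MASK_NEG)
    freq_reg = reg.transpose(0, 2, 1)  # (nW, W, H)
    frequency = np.where(
        freq_reg[:, :, :, None] == freq_reg[:, :, None, :], 0.0, _MASK_NEG
    )
    return full, temporal, frequency


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor, hw=None) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class SwinBlock(Module):
    def __init__(
        self,
        dim: int,
        hw: tuple[int, int],
        heads: int,
        window: int,
        shift: int,
        cfg: ModelConfig,
        rng: np.random.Generator,
    ):
        self.dim = dim
        self.hw = hw
        self.window = window
        self.shift = shift
        self.use_ada = cfg.use_ada
        self.norm1 = LayerNorm(dim)
        if cfg.use_ada:
            self.attn = AxialDecomposedAttention(dim, heads, rng)
        else:
            self.attn = WindowAttention(dim, heads, window, rng)
        self.norm2 = LayerNorm(dim)
        if cfg.use_fam:
            self.ffn = FrequencyAwareMLP(dim, rng)
        else:
            self.ffn = Mlp(dim, int(dim * cfg.mlp_ratio), rng)
        if shift > 0:
            self._masks = shifted_masks(*hw, window, shift)
        else:
            self._masks = (None, None, None)

    def forward(self, x: Tensor) -> Tensor:
        h, w = self.hw
        b, L, c = x.shape
        shortcut = x
        x = self.norm1(x).reshape(b, h, w, c)
        if self.shift > 0:
            x = x.roll((-self.shift, -self.shift), axes=(1, 2))
        xw = window_partition(x, self.window)
        if self.use_ada:
            attn = self.attn(xw, mask_t=self._masks[1], mask_f=self._masks[2])
        else:
            attn = self.attn(xw, mask=self._masks[0])
        x = window_reverse(attn, self.window, h, w)
        if self.shift > 0:
            x = x.roll((self.shift, self.shift), axes=(1, 2))
        x = shortcut + x.reshape(b, L, c)
        return x + self.ffn(self.norm2(x), self.hw)


class CapriLungNet(Module):
    """Patch embedding, four block stages with downsampling, pooled head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        p, cin = cfg.patch, cfg.in_channels
        self.patch_proj = Linear(p * p * cin, cfg.embed_dim, rng)
        self.patch_norm = LayerNorm(cfg.embed_dim)
        self.stages: list[list[SwinBlock]] = []
        self.downsamples: list[Module] = []
        for i in range(cfg.n_stages):
            dim, side = cfg.stage_dim(i), cfg.stage_side(i)
            ws = cfg.stage_window(i)
            blocks = []
            for j in range(cfg.depths[i]):
                shift = 0 if (j % 2 == 0 or ws >= side) else ws // 2
                blocks.append(
                    SwinBlock(dim, (side, side), cfg.heads[i], ws, shift, cfg, rng)
                )
            self.stages.append(blocks)
            if i < cfg.n_stages - 1:
                if cfg.use_asap:
                    self.downsamples.append(
                        ASAPMerging(dim, rng, alpha_init=cfg.asap_alpha_init)
                    )
                else:
                    self.downsamples.append(PatchMerging(dim, rng))
        final_dim = cfg.stage_dim(cfg.n_stages - 1)
        self.head_norm = LayerNorm(final_dim)
        self.head = Linear(final_dim, cfg.num_classes, rng)

    def _embed(self, images: np.ndarray) -> Tensor:
        """(B, C, S, S) uint/float array -> (B, L, embed) tokens."""
        b, c, s, _ = images.shape
        p = self.cfg.patch
        g = s // p
        tokens = (
            images.reshape(b, c, g, p, g, p)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(b, g * g, c * p * p)
        )
        return self.patch_norm(self.patch_proj(Tensor(tokens)))

    def forward(self, images: np.ndarray) -> Tensor:
        if images.ndim != 4 or images.shape[1] != self.cfg.in_channels:
            raise ValueError("expected a (B, C, S, S) batch")
        if images.shape[2] != self.cfg.input_side:
            raise ValueError(
                f"input side {images.shape[2]} != configured {self.cfg.input_side}"
            )
        x = self._embed(np.asarray(images, dtype=np.float64))
        for i, blocks in enumerate(self.stages):
            for block in blocks:
                x = block(x)
            if i < len(self.downsamples):
                side = self.cfg.stage_side(i)
                x = self.downsamples[i](x, (side, side))
        x = self.head_norm(x).mean(axis=1)
        return self.head(x)

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Argmax class predictions without building a tape."""
        preds = []
        with no_grad():
            for lo in range(0, len(images), batch_size):
                logits = self.forward(images[lo : lo + batch_size])
                preds.append(np.argmax(logits.data, axis=-1))
        return np.concatenate(preds)


def build_model(cfg: ModelConfig, seed: int = 0) -> CapriLungNet:
    """Deterministically initialized network for the given configuration."""
    return CapriLungNet(cfg, np.random.default_rng(seed))


def save_checkpoint(net: CapriLungNet, path) -> None:
    """Weights + config as a compressed npz (config as a JSON string)."""
    import json
    from dataclasses import asdict

    np.savez_compressed(
        path, __config__=json.dumps(asdict(net.cfg)), **net.state_dict()
    )


def load_checkpoint(path) -> CapriLungNet:
    import json

    with np.load(path, allow_pickle=False) as archive:
        raw = json.loads(str(archive["__config__"]))
        for key in ("depths", "heads"):
            raw[key] = tuple(raw[key])
        cfg = ModelConfig(**raw)
        net = build_model(cfg, seed=0)
        net.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return net
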