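"""Parameter counting and an analytic multiply-accumulate (MAC) estimator.

The MAC walk counts matmul/convolution work only (projections, attention
score and value products, feed-forward layers, merging); normalization and
elementwise activations are ignored, matching the usual convention of FLOP
counters for transformers.
"""

from __future__ import annotations

from .config import ModelConfig
from .fam import band_heights
from .network import CapriLungNet

__all__ = ["count_parameters", "estimate_flops"]


def count_parameters(network: CapriLungNet) -> float:
    """Trainable scalar count in millions."""
    return network.num_parameters() / 1e6


def estimate_flops(network: CapriLungNet, input_side: int | None = None) -> float:
    """Per-forward MAC estimate in billions at the configured input size."""
    cfg = network.cfg
    if input_side is not None and input_side != cfg.input_side:
        cfg = ModelConfig(**{**cfg.__dict__, "input_side": input_side})
    macs = 0
    g = cfg.input_side // cfg.patch
    macs += g * g * (cfg.patch**2 * cfg.in_channels) * cfg.embed_dim
    for i in range(cfg.n_stages):
        dim, side, ws = cfg.stage_dim(i), cfg.stage_side(i), cfg.stage_window(i)
        tokens = side * side
        for _ in range(cfg.depths[i]):
            macs += tokens * dim * 3 * dim  # shared QKV projection
            if cfg.use_ada:
                macs += 4 * tokens * ws * dim  # two axial score+value products
                macs += tokens * 2 * dim * dim  # 2C -> C fusion
            else:
                macs += 2 * tokens * ws * ws * dim  # window score+value
                macs += tokens * dim * dim  # output projection
            if cfg.use_fam:
                low, mid, high = band_heights(side)
                macs += low * side * dim * dim  # C -> C/2 -> C
                macs += mid * side * 2 * dim * dim  # C -> C -> C
                macs += high * side * 4 * dim * dim  # C -> 2C -> C
                macs += tokens * dim * dim  # frequency fusion
            else:
                macs += tokens * 2 * int(dim * cfg.mlp_ratio) * dim
        if i < cfg.n_stages - 1:
            if cfg.use_asap:
                macs += tokens * 10 * dim  # depthwise 3x3 + pointwise salience
                macs += (tokens // 4) * dim * 2 * dim  # 1x1 expand
            else:
                macs += (tokens // 4) * 4 * dim * 2 * dim
    macs += cfg.stage_dim(cfg.n_stages - 1) * cfg.num_classes
    return macs / 1e9
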