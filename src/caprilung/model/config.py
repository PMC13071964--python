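"""Architecture configuration, including the three ablation flags."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["ModelConfig", "TINY_BACKBONE", "reduced_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Hierarchical windowed-transformer configuration.

    The defaults reconstruct the tiny backbone (embed 96, depths 2-2-6-2,
    heads 3-6-12-24, window 7, 4x4 patches on a 224x224 3-channel input).
    ``use_ada`` swaps window attention for axial decomposed attention,
    ``use_asap`` swaps patch merging for salience-masked adaptive pooling,
    ``use_fam`` swaps the per-block MLP for the frequency-aware MLP.
    """

    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    window: int = 7
    patch: int = 4
    num_classes: int = 4
    input_side: int = 224
    in_channels: int = 3
    use_ada: bool = False
    use_asap: bool = False
    use_fam: bool = False
    asap_alpha_init: float = 0.5
    mlp_ratio: float = 4.0
    drop_rate: float = 0.0

    def __post_init__(self):
        if len(self.depths) != len(self.heads):
            raise ValueError("depths and heads must have equal length")
        n_stages = len(self.depths)
        if self.input_side % (self.patch * 2 ** (n_stages - 1)) != 0:
            raise ValueError(
                "input_side must be divisible by patch * 2**(n_stages-1)"
            )
        for i, h in enumerate(self.heads):
            if self.stage_dim(i) % h != 0:
                raise ValueError(f"stage {i}: heads must divide channel dim")
        for i in range(n_stages):
            side = self.stage_side(i)
            ws = min(self.window, side)
            if side % ws != 0:
                raise ValueError(
                    f"stage {i}: side {side} not divisible by window {ws}"
                )
        if self.use_fam and self.stage_side(n_stages - 1) < 3:
            raise ValueError("frequency-aware MLP needs stage height >= 3")

    @property
    def n_stages(self) -> int:
        return len(self.depths)

    def stage_side(self, i: int) -> int:
        return self.input_side // self.patch // 2**i

    def stage_dim(self, i: int) -> int:
        return self.embed_dim * 2**i

    def stage_window(self, i: int) -> int:
        return min(self.window, self.stage_side(i))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("depths", "heads"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


TINY_BACKBONE = ModelConfig()


def reduced_config(**overrides) -> ModelConfig:
    """A depth-reduced configuration small enough for CPU training tests:
    embed 24, one block per stage, 96x96 input, window 6."""
    kwargs = dict(
        embed_dim=24,
        depths=(1, 1, 1, 1),
        heads=(2, 4, 8, 16),
        window=6,
        input_side=96,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)
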