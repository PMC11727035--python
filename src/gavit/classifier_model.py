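"""Full classifier: component blocks → attention gate → MSFM → dense head.

The forward contract takes a batch of [0, 1] images of a fixed side
(224 by default) and returns per-class probabilities.  Per block the image
is reduced to a token sequence; block token features are concatenated along
the feature dimension (all blocks must share one token grid), gated, mapped
back onto the (Hp, Wp) grid as channels, fused across scales by the MSFM,
flattened, and classified by two ReLU dense layers with dropout and a
softmax output layer.

Both the gate and the MSFM can be switched off in the config (ablation
arms): without the gate the concatenated tokens pass through unchanged;
without the MSFM the gated grid is flattened directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, concat, dropout, glorot_uniform, he_uniform, softmax
from .attention_gate import GateParams, TokenFeatures, gated_combine
from .component_block import ComponentBlock, EncoderConfig, PatchEmbedConfig
from .msfm import FusionConfig, init_msfm, msfm_forward
from .spectral_ops import HybridPoolConfig

__all__ = ["BlockConfig", "ModelConfig", "Model", "build_model",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class BlockConfig:
    backbone: str = "stub"
    patch: PatchEmbedConfig = field(default_factory=PatchEmbedConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)


@dataclass(frozen=True)
class ModelConfig:
    blocks: tuple[BlockConfig, ...] = (BlockConfig(), BlockConfig())
    gate_reduction: int = 8
    fusion: FusionConfig = field(default_factory=FusionConfig)
    head_widths: tuple[int, int] = (1024, 128)
    head_dropout: float = 0.5
    num_classes: int = 4
    image_side: int = 224
    use_gate: bool = True
    use_msfm: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.blocks) < 1:
            raise ValueError("at least one component block is required")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        grids = {b.patch.tokens_per_side for b in self.blocks}
        if len(grids) != 1:
            offenders = [f"block {i}: grid {b.patch.tokens_per_side}"
                         for i, b in enumerate(self.blocks)]
            raise ValueError("all blocks must share one token grid; got "
                             + "; ".join(offenders))

    # -- (de)serialisation for checkpoints and YAML configs ------------
    def to_dict(self) -> dict:
        return {
            "blocks": [{"backbone": b.backbone,
                        "patch": vars(b.patch).copy(),
                        "encoder": vars(b.encoder).copy()}
                       for b in self.blocks],
            "gate_reduction": self.gate_reduction,
            "fusion": {"branch_width": self.fusion.branch_width,
                       "hybrid": vars(self.fusion.hybrid).copy()},
            "head_widths": list(self.head_widths),
            "head_dropout": self.head_dropout,
            "num_classes": self.num_classes,
            "image_side": self.image_side,
            "use_gate": self.use_gate,
            "use_msfm": self.use_msfm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        blocks = tuple(
            BlockConfig(backbone=b.get("backbone", "stub"),
                        patch=PatchEmbedConfig(**b.get("patch", {})),
                        encoder=EncoderConfig(**b.get("encoder", {})))
            for b in d.get("blocks", [{}, {}]))
        fusion_d = d.get("fusion", {})
        fusion = FusionConfig(
            branch_width=fusion_d.get("branch_width", 64),
            hybrid=HybridPoolConfig(**fusion_d.get("hybrid", {})))
        return cls(blocks=blocks,
                   gate_reduction=d.get("gate_reduction", 8),
                   fusion=fusion,
                   head_widths=tuple(d.get("head_widths", (1024, 128))),
                   head_dropout=d.get("head_dropout", 0.5),
                   num_classes=d.get("num_classes", 4),
                   image_side=d.get("image_side", 224),
                   use_gate=d.get("use_gate", True),
                   use_msfm=d.get("use_msfm", True),
                   seed=d.get("seed", 0))


class Model:
    """All weights are constructed deterministically from ``cfg.seed``."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.blocks = [ComponentBlock(b.backbone, b.patch, b.encoder, rng)
                       for b in cfg.blocks]
        self.grid = self.blocks[0].grid
        self.d_total = sum(b.patch.hidden_dim for b in cfg.blocks)
        self.gate = GateParams.init(self.d_total, cfg.gate_reduction, rng)
        gated_dim = 3 * self.d_total if cfg.use_gate else self.d_total
        self.fusion_weights = init_msfm(cfg.fusion, gated_dim, rng)
        hp, wp = self.grid
        flat_dim = hp * wp * (cfg.fusion.out_channels if cfg.use_msfm
                              else gated_dim)
        w1, w2 = cfg.head_widths
        self.head = {
            "d1_w": Tensor(he_uniform(rng, (flat_dim, w1), flat_dim),
                           requires_grad=True),
            "d1_b": Tensor(np.zeros(w1), requires_grad=True),
            "d2_w": Tensor(he_uniform(rng, (w1, w2), w1),
                           requires_grad=True),
            "d2_b": Tensor(np.zeros(w2), requires_grad=True),
            "out_w": Tensor(glorot_uniform(rng, (w2, cfg.num_classes),
                                           w2, cfg.num_classes),
                            requires_grad=True),
            "out_b": Tensor(np.zeros(cfg.num_classes), requires_grad=True),
        }

    # -- parameters ----------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for i, blk in enumerate(self.blocks):
            out.update(blk.parameters(prefix=f"block{i}."))
        for k, t in self.gate.params.items():
            out[f"gate.{k}"] = t
        for k, t in self.fusion_weights.items():
            out[f"msfm.{k}"] = t
        for k, t in self.head.items():
            out[f"head.{k}"] = t
        return out

    @property
    def num_parameters(self) -> int:
        return sum(t.size for t in self.parameters().values())

    # -- forward -------------------------------------------------------
    def _check_images(self, images) -> Tensor:
        if not isinstance(images, Tensor):
            images = Tensor(np.asarray(images, dtype=np.float64))
        s = self.cfg.image_side
        if images.ndim != 4 or images.shape[1:] != (s, s, 3):
            raise ValueError(
                f"expected images of shape (B, {s}, {s}, 3), got {images.shape}")
        return images

    def forward_logits(self, images, training: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        images = self._check_images(images)
        rng = rng or np.random.default_rng(0)
        token_sets = [blk.forward(images, training, rng) for blk in self.blocks]
        tokens = TokenFeatures(
            concat([t.values for t in token_sets], axis=2), self.grid)
        if self.cfg.use_gate:
            tokens = gated_combine(tokens, self.gate)
        B = tokens.values.shape[0]
        hp, wp = self.grid
        grid = tokens.values.reshape(B, hp, wp, tokens.values.shape[2])
        if self.cfg.use_msfm:
            grid = msfm_forward(grid, self.fusion_weights, self.cfg.fusion)
        x = grid.reshape(B, -1)
        h = self.head
        x = (x @ h["d1_w"] + h["d1_b"]).relu()
        x = dropout(x, self.cfg.head_dropout, rng, training)
        x = (x @ h["d2_w"] + h["d2_b"]).relu()
        x = dropout(x, self.cfg.head_dropout, rng, training)
        return x @ h["out_w"] + h["out_b"]

    def forward(self, images, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Class probabilities (B, num_classes); rows sum to 1."""
        return softmax(self.forward_logits(images, training, rng), axis=-1)


def build_model(cfg: ModelConfig) -> Model:
    return Model(cfg)


def save_checkpoint(model: Model, path) -> None:
    arrays = {k: t.data for k, t in model.parameters().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode()))
        model = Model(cfg)
        params = model.parameters()
        for k, t in params.items():
            t.data[...] = data[k]
    return model
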