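"""One CNN→ViT component block.

A component block turns an image batch into a token sequence in three
stages: a convolutional backbone extracts a spatial feature map, the map is
bilinearly resized to a fixed side S and cut into non-overlapping P×P
patches that are linearly projected (plus learned position embeddings), and
a stack of pre-norm transformer encoder layers mixes the resulting tokens.

The backbone is a contract, not a fixed network: any callable mapping a
(B, 224, 224, 3) batch in [0, 1] to a (B, s, s, C) feature map satisfies
it.  A small three-stage strided-conv backbone ("stub", 224 → 28) is built
in so the whole pipeline runs without any pretrained-weights ecosystem;
the names ``efficientnet_b3`` / ``densenet121`` are reserved in the
registry for users who plug in their own implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import (Tensor, bilinear_resize, conv2d, dropout,
                      glorot_uniform, he_uniform, softmax, trunc_normal)
from .attention_gate import TokenFeatures

__all__ = [
    "BackboneContract",
    "PatchEmbedConfig",
    "EncoderConfig",
    "StubBackbone",
    "BACKBONE_REGISTRY",
    "build_backbone",
    "extract_features",
    "patchify_embed",
    "init_patch_embed",
    "init_encoder",
    "encoder_layer",
    "encode",
    "ComponentBlock",
]


@dataclass(frozen=True)
class PatchEmbedConfig:
    patch_size: int = 8
    hidden_dim: int = 32
    grid_side: int = 56  # feature map is resized to grid_side x grid_side first

    def __post_init__(self):
        if self.grid_side % self.patch_size != 0:
            raise ValueError(
                f"grid_side {self.grid_side} not divisible by patch_size "
                f"{self.patch_size}")

    @property
    def tokens_per_side(self) -> int:
        return self.grid_side // self.patch_size

    @property
    def num_tokens(self) -> int:
        return self.tokens_per_side ** 2


@dataclass(frozen=True)
class EncoderConfig:
    num_layers: int = 6
    num_heads: int = 2
    mlp_dim: int = 64
    dropout: float = 0.5

    def validate(self, hidden_dim: int) -> None:
        if hidden_dim % self.num_heads != 0:
            raise ValueError(
                f"hidden_dim {hidden_dim} not divisible by num_heads "
                f"{self.num_heads}")


# ---------------------------------------------------------------------
# backbone contract
# ---------------------------------------------------------------------

@dataclass
class BackboneContract:
    """A named image-batch → feature-map-batch callable."""

    fn: object            # callable (Tensor BxHxWx3, training) -> Tensor Bxsxsxc
    out_channels: int
    downsample: int       # spatial reduction factor (input side / output side)
    name: str = "custom"

    def __call__(self, images: Tensor, training: bool = False) -> Tensor:
        return self.fn(images, training)


class StubBackbone:
    """Three strided conv stages (stride 2 each, ReLU): side/8, e.g. 224 → 28."""

    CHANNELS = (8, 16, 32)

    def __init__(self, rng: np.random.Generator, in_channels: int = 3):
        self.params: dict[str, Tensor] = {}
        c_in = in_channels
        for i, c_out in enumerate(self.CHANNELS):
            w = he_uniform(rng, (3, 3, c_in, c_out), 9 * c_in)
            self.params[f"conv{i}_w"] = Tensor(w, requires_grad=True)
            self.params[f"conv{i}_b"] = Tensor(np.zeros(c_out), requires_grad=True)
            c_in = c_out
        self.out_channels = c_in

    def __call__(self, images: Tensor, training: bool = False) -> Tensor:
        x = images
        for i in range(len(self.CHANNELS)):
            x = conv2d(x, self.params[f"conv{i}_w"],
                       self.params[f"conv{i}_b"], stride=2).relu()
        return x


def _stub_factory(rng: np.random.Generator) -> BackboneContract:
    stub = StubBackbone(rng)
    contract = BackboneContract(stub, stub.out_channels, downsample=8, name="stub")
    contract.params = stub.params  # type: ignore[attr-defined]
    return contract


BACKBONE_REGISTRY: dict[str, object] = {"stub": _stub_factory}

_RESERVED = ("efficientnet_b3", "densenet121", "mobilenet")


def build_backbone(name: str, rng: np.random.Generator) -> BackboneContract:
    if name in BACKBONE_REGISTRY:
        return BACKBONE_REGISTRY[name](rng)
    if name in _RESERVED:
        raise KeyError(
            f"backbone {name!r} is a reserved name: register an implementation "
            f"in BACKBONE_REGISTRY to use pretrained CNNs")
    raise KeyError(f"unknown backbone {name!r}; registered: "
                   f"{sorted(BACKBONE_REGISTRY)}")


def extract_features(images: Tensor, backbone: BackboneContract,
                     training: bool = False) -> Tensor:
    """Run the backbone on a batch of [0, 1] images, checking the contract."""
    if not isinstance(images, Tensor):
        images = Tensor(np.asarray(images, dtype=np.float64))
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError(f"expected (B, H, W, 3) images, got {images.shape}")
    lo, hi = images.data.min(), images.data.max()
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"pixel values must lie in [0, 1]; got [{lo}, {hi}]")
    return backbone(images, training)


# ---------------------------------------------------------------------
# patch embedding
# ---------------------------------------------------------------------

def init_patch_embed(cfg: PatchEmbedConfig, in_channels: int,
                     rng: np.random.Generator) -> dict[str, Tensor]:
    patch_dim = cfg.patch_size ** 2 * in_channels
    return {
        "proj_w": Tensor(glorot_uniform(rng, (patch_dim, cfg.hidden_dim),
                                        patch_dim, cfg.hidden_dim),
                         requires_grad=True),
        "proj_b": Tensor(np.zeros(cfg.hidden_dim), requires_grad=True),
        "pos": Tensor(trunc_normal(rng, (cfg.num_tokens, cfg.hidden_dim)),
                      requires_grad=True),
    }


def patchify_embed(fmap: Tensor, cfg: PatchEmbedConfig,
                   weights: dict[str, Tensor]) -> TokenFeatures:
    """Resize a feature map to S×S, patch row-major, project, add positions."""
    B = fmap.shape[0]
    C = fmap.shape[3]
    S, P = cfg.grid_side, cfg.patch_size
    g = cfg.tokens_per_side
    x = bilinear_resize(fmap, S, S)
    # (B, g, P, g, P, C) -> (B, g, g, P, P, C) -> (B, N, P*P*C), row-major
    x = x.reshape(B, g, P, g, P, C).transpose((0, 1, 3, 2, 4, 5))
    x = x.reshape(B, g * g, P * P * C)
    tokens = x @ weights["proj_w"] + weights["proj_b"] + weights["pos"]
    return TokenFeatures(tokens, (g, g))


# ---------------------------------------------------------------------
# transformer encoder
# ---------------------------------------------------------------------

def _init_layer(rng: np.random.Generator, d: int, cfg: EncoderConfig
                ) -> dict[str, Tensor]:
    def dense(n_in, n_out):
        return Tensor(glorot_uniform(rng, (n_in, n_out), n_in, n_out),
                      requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return Tensor(np.ones(shape), requires_grad=True)

    def residual_dense(n_in, n_out):
        # residual-branch outputs start small so each layer is near-identity
        # at init; stabilizes optimization of the stack at high learning rates
        return Tensor(0.1 * glorot_uniform(rng, (n_in, n_out), n_in, n_out),
                      requires_grad=True)

    return {
        "ln1_g": ones(d), "ln1_b": zeros(d),
        "wq": dense(d, d), "bq": zeros(d),
        "wk": dense(d, d), "bk": zeros(d),
        "wv": dense(d, d), "bv": zeros(d),
        "wo": residual_dense(d, d), "bo": zeros(d),
        "ln2_g": ones(d), "ln2_b": zeros(d),
        "mlp_w1": dense(d, cfg.mlp_dim), "mlp_b1": zeros(cfg.mlp_dim),
        "mlp_w2": residual_dense(cfg.mlp_dim, d), "mlp_b2": zeros(d),
    }


def init_encoder(cfg: EncoderConfig, hidden_dim: int,
                 rng: np.random.Generator) -> list[dict[str, Tensor]]:
    cfg.validate(hidden_dim)
    return [_init_layer(rng, hidden_dim, cfg) for _ in range(cfg.num_layers)]


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered ** 2).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


def _mha(x: Tensor, w: dict[str, Tensor], num_heads: int,
         return_attn: bool = False):
    B, N, D = x.shape
    dh = D // num_heads
    q = (x @ w["wq"] + w["bq"]).reshape(B, N, num_heads, dh).transpose((0, 2, 1, 3))
    k = (x @ w["wk"] + w["bk"]).reshape(B, N, num_heads, dh).transpose((0, 2, 1, 3))
    v = (x @ w["wv"] + w["bv"]).reshape(B, N, num_heads, dh).transpose((0, 2, 1, 3))
    scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
    attn = softmax(scores, axis=-1)             # (B, h, N, N)
    mixed = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, N, D)
    out = mixed @ w["wo"] + w["bo"]
    return (out, attn) if return_attn else (out, None)


def encoder_layer(x: Tensor, layer_weights: dict[str, Tensor],
                  cfg: EncoderConfig, training: bool = False,
                  rng: np.random.Generator | None = None,
                  return_attn: bool = False, layer_index: int = 0):
    """Pre-norm transformer layer: x + MHA(LN(x)), then y + MLP(LN(y)).

    The MLP is Dense(mlp_dim)+GELU, Dense(hidden)+ — with dropout after each
    dense layer while training.  Raises if the attention softmax produced
    NaNs, naming the layer.
    """
    w = layer_weights
    rng = rng or np.random.default_rng(0)
    attn_out, attn = _mha(_layer_norm(x, w["ln1_g"], w["ln1_b"]),
                          w, cfg.num_heads, return_attn)
    if attn is not None and np.any(np.isnan(attn.data)):
        raise FloatingPointError(f"NaN attention in encoder layer {layer_index}")
    y = x + attn_out
    h = (_layer_norm(y, w["ln2_g"], w["ln2_b"]) @ w["mlp_w1"] + w["mlp_b1"]).gelu()
    h = dropout(h, cfg.dropout, rng, training)
    h = h @ w["mlp_w2"] + w["mlp_b2"]
    h = dropout(h, cfg.dropout, rng, training)
    z = y + h
    return (z, attn) if return_attn else z


def encode(x: Tensor, weights: list[dict[str, Tensor]], cfg: EncoderConfig,
           training: bool = False,
           rng: np.random.Generator | None = None) -> Tensor:
    for i, layer_w in enumerate(weights):
        x = encoder_layer(x, layer_w, cfg, training, rng, layer_index=i)
    return x


# ---------------------------------------------------------------------
# assembled block
# ---------------------------------------------------------------------

class ComponentBlock:
    """Backbone + patch embedding + encoder stack with one forward call."""

    def __init__(self, backbone_name: str, patch_cfg: PatchEmbedConfig,
                 enc_cfg: EncoderConfig, rng: np.random.Generator):
        self.backbone = build_backbone(backbone_name, rng)
        self.patch_cfg = patch_cfg
        self.enc_cfg = enc_cfg
        self.embed = init_patch_embed(patch_cfg, self.backbone.out_channels, rng)
        self.layers = init_encoder(enc_cfg, patch_cfg.hidden_dim, rng)

    @property
    def grid(self) -> tuple[int, int]:
        g = self.patch_cfg.tokens_per_side
        return (g, g)

    def forward(self, images: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> TokenFeatures:
        fmap = extract_features(images, self.backbone, training)
        tokens = patchify_embed(fmap, self.patch_cfg, self.embed)
        encoded = encode(tokens.values, self.layers, self.enc_cfg, training, rng)
        return TokenFeatures(encoded, tokens.grid)

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, t in getattr(self.backbone, "params", {}).items():
            out[f"{prefix}backbone.{k}"] = t
        for k, t in self.embed.items():
            out[f"{prefix}embed.{k}"] = t
        for i, layer in enumerate(self.layers):
            for k, t in layer.items():
                out[f"{prefix}enc{i}.{k}"] = t
        return out
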