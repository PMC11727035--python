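import numpy as np
import pytest

from gavit import (BlockConfig, EncoderConfig, FusionConfig, ModelConfig,
                   PatchEmbedConfig)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_model_config(seed: int = 0, **overrides) -> ModelConfig:
    """A small but fully wired model: 2 stub blocks, 3x3 token grid."""
    patch = PatchEmbedConfig(patch_size=8, hidden_dim=8, grid_side=24)
    enc = EncoderConfig(num_layers=2, num_heads=2, mlp_dim=16, dropout=0.5)
    defaults = dict(
        blocks=(BlockConfig("stub", patch, enc), BlockConfig("stub", patch, enc)),
        fusion=FusionConfig(branch_width=4),
        head_widths=(16, 8),
        num_classes=4,
        image_side=32,
        seed=seed,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture
def tiny_config():
    return tiny_model_config()


@pytest.fixture
def tiny_images(rng):
    return rng.random((2, 32, 32, 3))
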