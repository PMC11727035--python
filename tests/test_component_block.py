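"""CNN stub backbone, patch embedding, and transformer encoder behavior."""

import numpy as np
import pytest

from gavit import EncoderConfig, PatchEmbedConfig, extract_features
from gavit._tensor import Tensor
from gavit.component_block import (build_backbone, encode, encoder_layer,
                                   init_encoder, init_patch_embed,
                                   patchify_embed)

CFG = EncoderConfig(num_layers=2, num_heads=2, mlp_dim=16, dropout=0.5)


class TestBackbone:
    def test_stub_downsamples_224_to_28(self, rng):
        bb = build_backbone("stub", rng)
        out = extract_features(Tensor(rng.random((1, 224, 224, 3))), bb)
        assert out.shape == (1, 28, 28, 32)

    def test_batch_equals_stacked_singles(self, rng):
        bb = build_backbone("stub", rng)
        imgs = rng.random((2, 32, 32, 3))
        both = extract_features(Tensor(imgs), bb).data
        singles = [extract_features(Tensor(imgs[i:i + 1]), bb).data[0]
                   for i in range(2)]
        assert np.allclose(both, np.stack(singles))

    def test_zero_image_zero_bias_gives_zero_features(self, rng):
        bb = build_backbone("stub", rng)  # biases init to zero
        out = extract_features(Tensor(np.zeros((1, 32, 32, 3))), bb)
        assert np.all(out.data == 0)

    def test_out_of_range_pixels_rejected(self, rng):
        bb = build_backbone("stub", rng)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            extract_features(Tensor(np.full((1, 32, 32, 3), 2.0)), bb)

    def test_reserved_and_unknown_names(self, rng):
        with pytest.raises(KeyError, match="reserved"):
            build_backbone("efficientnet_b3", rng)
        with pytest.raises(KeyError, match="unknown"):
            build_backbone("no-such-net", rng)


class TestPatchEmbed:
    def test_default_geometry_49_tokens_of_32(self, rng):
        cfg = PatchEmbedConfig()  # S=56, P=8, hidden 32
        w = init_patch_embed(cfg, in_channels=4, rng=rng)
        fmap = Tensor(rng.random((1, 28, 28, 4)))
        tokens = patchify_embed(fmap, cfg, w)
        assert tokens.values.shape == (1, 49, 32)
        assert tokens.grid == (7, 7)

    def test_zero_weights_zero_positions_give_zero_tokens(self, rng):
        cfg = PatchEmbedConfig(patch_size=8, hidden_dim=4, grid_side=16)
        w = init_patch_embed(cfg, 2, rng)
        for t in w.values():
            t.data[...] = 0.0
        tokens = patchify_embed(Tensor(rng.random((2, 16, 16, 2))), cfg, w)
        assert np.all(tokens.values.data == 0)

    def test_token_k_matches_gather_flatten_project_oracle(self, rng):
        cfg = PatchEmbedConfig(patch_size=8, hidden_dim=5, grid_side=16)
        w = init_patch_embed(cfg, 3, rng)
        fmap = rng.normal(size=(1, 16, 16, 3))  # already S x S: no resize
        tokens = patchify_embed(Tensor(fmap), cfg, w).values.data
        for k in range(4):
            gi, gj = divmod(k, 2)  # row-major grid order
            patch = fmap[0, gi * 8:(gi + 1) * 8, gj * 8:(gj + 1) * 8, :]
            expected = patch.reshape(-1) @ w["proj_w"].data \
                + w["proj_b"].data + w["pos"].data[k]
            assert np.allclose(tokens[0, k], expected)

    def test_indivisible_grid_rejected_at_construction(self):
        with pytest.raises(ValueError, match="divisible"):
            PatchEmbedConfig(patch_size=8, grid_side=28)


class TestEncoderLayer:
    def test_zeroed_residual_branches_make_identity(self, rng):
        w = init_encoder(CFG, 8, rng)[0]
        for name in ("wo", "bo", "mlp_w2", "mlp_b2"):
            w[name].data[...] = 0.0
        x = rng.normal(size=(2, 5, 8))
        out = encoder_layer(Tensor(x), w, CFG, training=False)
        assert np.allclose(out.data, x)

    def test_attention_rows_sum_to_one(self, rng):
        w = init_encoder(CFG, 8, rng)[0]
        x = Tensor(rng.normal(size=(2, 6, 8)))
        _, attn = encoder_layer(x, w, CFG, return_attn=True)
        assert attn.data.shape == (2, 2, 6, 6)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_qk_projections_give_uniform_token_mean_mixing(self, rng):
        w = init_encoder(CFG, 8, rng)[0]
        w["wq"].data[...] = 0.0
        w["bq"].data[...] = 0.0
        w["wk"].data[...] = 0.0
        w["bk"].data[...] = 0.0
        x = Tensor(rng.normal(size=(1, 5, 8)))
        _, attn = encoder_layer(x, w, CFG, return_attn=True)
        assert np.allclose(attn.data, 1.0 / 5.0)

    def test_single_token_reduces_to_mlp_residual_scalar_oracle(self, rng):
        w = init_encoder(CFG, 4, rng)[0]
        x = rng.normal(size=(1, 1, 4))

        def ln(v, g, b):
            mu = v.mean()
            var = ((v - mu) ** 2).mean()
            return (v - mu) / np.sqrt(var + 1e-6) * g + b

        def gelu(v):
            from scipy.special import erf
            return v * 0.5 * (1 + erf(v / np.sqrt(2)))

        t = x[0, 0]
        n1 = ln(t, w["ln1_g"].data, w["ln1_b"].data)
        # one token: softmax over a single score is 1, so attention passes v
        v = n1 @ w["wv"].data + w["bv"].data
        y = t + v @ w["wo"].data + w["bo"].data
        n2 = ln(y, w["ln2_g"].data, w["ln2_b"].data)
        h = gelu(n2 @ w["mlp_w1"].data + w["mlp_b1"].data)
        expected = y + h @ w["mlp_w2"].data + w["mlp_b2"].data

        out = encoder_layer(Tensor(x), w, CFG, training=False)
        assert np.allclose(out.data[0, 0], expected)


class TestEncode:
    def test_stack_composition_and_shape(self, rng):
        weights = init_encoder(CFG, 8, rng)
        x = Tensor(rng.normal(size=(2, 4, 8)))
        full = encode(x, weights, CFG, training=False)
        assert full.shape == x.shape
        step = encoder_layer(Tensor(x.data), weights[0], CFG)
        step = encoder_layer(step, weights[1], CFG)
        assert np.allclose(full.data, step.data)

    def test_identity_initialised_stack_is_identity(self, rng):
        cfg = EncoderConfig(num_layers=6, num_heads=2, mlp_dim=16, dropout=0.5)
        weights = init_encoder(cfg, 8, rng)
        for w in weights:
            for name in ("wo", "bo", "mlp_w2", "mlp_b2"):
                w[name].data[...] = 0.0
        x = rng.normal(size=(1, 4, 8))
        assert np.allclose(encode(Tensor(x), weights, cfg).data, x)

    def test_eval_mode_bit_identical_despite_dropout_config(self, rng):
        weights = init_encoder(CFG, 8, rng)  # dropout 0.5 configured
        x = Tensor(rng.normal(size=(2, 4, 8)))
        a = encode(x, weights, CFG, training=False,
                   rng=np.random.default_rng(1))
        b = encode(x, weights, CFG, training=False,
                   rng=np.random.default_rng(2))
        assert np.array_equal(a.data, b.data)

    def test_training_mode_dropout_changes_output(self, rng):
        weights = init_encoder(CFG, 8, rng)
        x = Tensor(rng.normal(size=(2, 4, 8)))
        a = encode(x, weights, CFG, training=True, rng=np.random.default_rng(1))
        b = encode(x, weights, CFG, training=False)
        assert not np.allclose(a.data, b.data)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            init_encoder(EncoderConfig(num_heads=3), 8, np.random.default_rng(0))
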