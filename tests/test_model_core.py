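"""Architecture contracts: shapes, residual identities, attention oracle,
parameter accounting, determinism and gradient flow."""

import numpy as np
import pytest

from vesselseg import nn
from vesselseg.model_core import (
    BACKBONES,
    ConvBottleneck,
    FeatureMap,
    FuseCnnToTrans,
    FuseTransToCnn,
    ModelConfig,
    MultiHeadSelfAttention,
    PatchEmbed,
    TokenSequence,
    TransformerBlock,
    VesselSegNet,
    build_model,
    load_checkpoint,
    predict_proba,
    save_checkpoint,
    transformer_block_param_count,
)
from vesselseg.nn.tensor import Tensor


def feature_map(arr, stride=16):
    return FeatureMap(Tensor(np.asarray(arr, dtype=np.float32)), stride)


def token_sequence(arr, grid_h, grid_w):
    return TokenSequence(Tensor(np.asarray(arr, dtype=np.float32)), grid_h, grid_w)


class TestModelConfig:
    def test_embed_dim_head_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=65, n_heads=6)

    def test_all_branches_disabled_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(enable_cnn_branch=False, enable_trans_branch=False)

    def test_patch_stride_fixed(self):
        with pytest.raises(ValueError):
            ModelConfig(patch_stride=8)

    def test_tiny_preset_valid(self):
        cfg = ModelConfig.tiny()
        assert cfg.backbone_name == "tiny" and cfg.n_trans_blocks == 2

    def test_yaml_roundtrip(self, tmp_path):
        import yaml
        cfg = ModelConfig.tiny(n_heads=4)
        path = tmp_path / "model.yaml"
        from dataclasses import asdict
        path.write_text(yaml.safe_dump(asdict(cfg)))
        assert ModelConfig.from_yaml(path) == cfg


class TestBuildModel:
    def test_seeded_builds_identical(self):
        a = build_model(ModelConfig.tiny(), seed=3)
        b = build_model(ModelConfig.tiny(), seed=3)
        for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_trans_disabled_removes_attention_params(self):
        model = build_model(ModelConfig.tiny(enable_trans_branch=False))
        names = [k for k, _ in model.named_parameters()]
        assert not any("attn" in k or "qkv" in k or "cls_token" in k for k in names)

    def test_block_count_parameter_delta(self):
        # trans-only arms differ by exactly the closed-form per-block count
        small = build_model(ModelConfig.tiny(enable_cnn_branch=False,
                                             n_trans_blocks=2))
        large = build_model(ModelConfig.tiny(enable_cnn_branch=False,
                                             n_trans_blocks=4))
        per_block = transformer_block_param_count(64, 2, 4)
        assert large.n_parameters() - small.n_parameters() == 2 * per_block

    def test_ablation_param_monotonicity(self):
        full = build_model(ModelConfig.tiny()).n_parameters()
        for overrides in (dict(enable_fusion=False),
                          dict(enable_trans_branch=False),
                          dict(enable_cnn_branch=False)):
            ablated = build_model(ModelConfig.tiny(**overrides)).n_parameters()
            assert ablated < full, overrides


class TestConvBottleneck:
    def test_residual_identity_when_projection_zeroed(self, rng):
        nn.manual_seed(0)
        block = ConvBottleneck(8, 8).eval()
        block.conv_up.weight.data[...] = 0.0
        block.conv_up.bias.data[...] = 0.0
        x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)
        out = block(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_stage_transition_shapes(self, rng):
        nn.manual_seed(0)
        block = ConvBottleneck(64, 128, stride=2).eval()
        out = block(feature_map(rng.normal(size=(1, 64, 32, 32))))
        assert out.values.shape == (1, 128, 16, 16)
        assert out.stride == 32

    def test_finite_output(self, rng):
        nn.manual_seed(1)
        block = ConvBottleneck(4, 16).train()
        out = block(Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32)))
        assert np.isfinite(out.data).all()


class TestTransformerBlock:
    def test_identity_when_projections_zeroed(self, rng):
        nn.manual_seed(0)
        block = TransformerBlock(16, 2)
        block.attn.attn_out.weight.data[...] = 0.0
        block.attn.attn_out.bias.data[...] = 0.0
        block.mlp.fc_down.weight.data[...] = 0.0
        block.mlp.fc_down.bias.data[...] = 0.0
        t = rng.normal(size=(1, 5, 16)).astype(np.float32)
        out = block(token_sequence(t, 2, 2))
        np.testing.assert_allclose(out.values.data, t, atol=1e-6)

    def test_shape_preserved(self, rng):
        nn.manual_seed(0)
        block = TransformerBlock(32, 4)
        t = token_sequence(rng.normal(size=(2, 10, 32)), 3, 3)
        assert block(t).values.shape == (2, 10, 32)

    def test_uniform_attention_for_repeated_token(self, rng):
        nn.manual_seed(0)
        block = TransformerBlock(16, 2)
        row = rng.normal(size=16).astype(np.float32)
        t = np.tile(row, (1, 6, 1))
        block(token_sequence(t, 1, 5))
        np.testing.assert_allclose(block.attn.last_attn, 1.0 / 6, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        nn.manual_seed(2)
        block = TransformerBlock(8, 1)
        block(token_sequence(rng.normal(size=(2, 8, 8)), 7, 1))
        np.testing.assert_allclose(block.attn.last_attn.sum(axis=-1), 1.0,
                                   atol=1e-5)

    def test_attention_matches_brute_force_oracle(self, rng):
        # 4-token sequence, one head, J = 8, against a hand-rolled oracle
        nn.manual_seed(5)
        attn = MultiHeadSelfAttention(8, 1)
        x = rng.normal(size=(1, 4, 8)).astype(np.float32)
        out = attn(Tensor(x)).data

        w = attn.qkv.weight.data
        b = attn.qkv.bias.data
        q = x[0] @ w[:, :8] + b[:8]
        k = x[0] @ w[:, 8:16] + b[8:16]
        v = x[0] @ w[:, 16:] + b[16:]
        scores = q @ k.T / np.sqrt(8)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        weights = e / e.sum(axis=1, keepdims=True)
        expected = (weights @ v) @ attn.attn_out.weight.data + attn.attn_out.bias.data
        np.testing.assert_allclose(out[0], expected, atol=1e-5)
        np.testing.assert_allclose(attn.last_attn[0, 0], weights, atol=1e-5)


class TestPatchEmbed:
    def test_token_count_from_input_size(self, rng):
        # stride-16 map of a 128x128 input is 8x8 -> 64 tokens + class
        nn.manual_seed(0)
        embed = PatchEmbed(4, 16)
        out = embed(feature_map(rng.normal(size=(1, 4, 8, 8))))
        assert out.values.shape == (1, 65, 16)
        assert (out.grid_h, out.grid_w) == (8, 8)

    def test_small_input_token_shape(self, rng):
        # 32x32 input -> 2x2 grid -> 5 x J sequence
        nn.manual_seed(0)
        embed = PatchEmbed(4, 12)
        out = embed(feature_map(rng.normal(size=(1, 4, 2, 2))))
        assert out.values.shape == (1, 5, 12)

    def test_wrong_stride_rejected(self, rng):
        nn.manual_seed(0)
        embed = PatchEmbed(4, 12)
        with pytest.raises(ValueError, match="stride-16"):
            embed(feature_map(rng.normal(size=(1, 4, 8, 8)), stride=8))

    def test_toroidal_shift_permutes_token_multiset(self, rng):
        # zero-bordered features: a one-cell toroidal shift only permutes
        # the projected tokens
        nn.manual_seed(0)
        embed = PatchEmbed(3, 8)
        # two-cell zero border keeps every 3x3 neighbourhood intact when
        # the content wraps by one cell
        feats = np.zeros((1, 3, 8, 8), dtype=np.float32)
        feats[:, :, 2:-2, 2:-2] = rng.normal(size=(1, 3, 4, 4))
        shifted = np.roll(feats, 1, axis=2)
        tok_a = embed(feature_map(feats)).values.data[0, 1:]
        tok_b = embed(feature_map(shifted)).values.data[0, 1:]
        sort_a = tok_a[np.lexsort(tok_a.T)]
        sort_b = tok_b[np.lexsort(tok_b.T)]
        np.testing.assert_allclose(sort_a, sort_b, atol=1e-6)


class TestFusion:
    def test_cnn_to_trans_zeroed_projection_is_normalized_identity(self, rng):
        nn.manual_seed(0)
        fuse = FuseCnnToTrans(4, 8)
        fuse.proj.bias.data[...] = 0.0
        t_raw = rng.normal(size=(1, 5, 8)).astype(np.float32)
        t = token_sequence(t_raw, 2, 2)
        out = fuse(feature_map(rng.normal(size=(1, 4, 8, 8))), t)
        expected = fuse.norm(Tensor(t_raw)).data
        np.testing.assert_allclose(out.values.data, expected, atol=1e-6)

    def test_constant_field_gives_uniform_offset(self, rng):
        nn.manual_seed(0)
        fuse = FuseCnnToTrans(3, 8)
        fuse.proj.weight.data = rng.normal(size=(8, 3, 1, 1)).astype(np.float32)
        const = np.full((1, 3, 8, 8), 0.5, dtype=np.float32)
        t = token_sequence(np.zeros((1, 17, 8)), 4, 4)
        out = fuse(feature_map(const), t)
        # hand-computed: pooling a constant field is the constant, so every
        # spatial token receives W.sum(channel) * 0.5 + bias, then LayerNorm
        offset = fuse.proj.weight.data.sum(axis=(1, 2, 3)) * 0.5 + fuse.proj.bias.data
        spatial = out.values.data[0, 1:]
        for row in spatial:
            np.testing.assert_allclose(row, spatial[0], atol=1e-6)
        pre_norm = offset
        expected = (pre_norm - pre_norm.mean()) / np.sqrt(pre_norm.var() + 1e-5)
        np.testing.assert_allclose(spatial[0], expected, atol=1e-4)

    def test_misaligned_grid_rejected(self, rng):
        nn.manual_seed(0)
        fuse = FuseCnnToTrans(3, 8)
        t = token_sequence(np.zeros((1, 10, 8)), 3, 3)
        with pytest.raises(ValueError, match="multiple"):
            fuse(feature_map(rng.normal(size=(1, 3, 8, 8))), t)

    def test_trans_to_cnn_zeroed_projection_is_normalized_identity(self, rng):
        nn.manual_seed(0)
        fuse = FuseTransToCnn(8, 4).eval()
        fuse.proj.bias.data[...] = 0.0
        x_raw = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        t = token_sequence(rng.normal(size=(1, 5, 8)), 2, 2)
        out = fuse(t, feature_map(x_raw))
        # eval-mode BatchNorm with fresh running stats is x/sqrt(1+eps)
        np.testing.assert_allclose(out.values.data, x_raw, atol=1e-4)
        assert out.values.shape == x_raw.shape

    def test_constant_tokens_upsample_to_constant_field(self, rng):
        nn.manual_seed(0)
        fuse = FuseTransToCnn(8, 4).eval()
        t_raw = np.zeros((1, 17, 8), dtype=np.float32)
        t_raw[:, 1:, :] = 3.0                      # constant spatial tokens
        fuse.proj.weight.data = rng.normal(size=(4, 8, 1, 1)).astype(np.float32)
        x = np.zeros((1, 4, 16, 16), dtype=np.float32)
        out = fuse(token_sequence(t_raw, 4, 4), feature_map(x))
        per_channel = out.values.data[0].reshape(4, -1)
        assert np.ptp(per_channel, axis=1).max() < 1e-4


class TestForward:
    @pytest.mark.parametrize("size", [32, 118, 128])
    def test_shape_conservation(self, size, rng):
        model = build_model(ModelConfig.tiny(), seed=0)
        img = rng.uniform(0, 1, (1, 3, size, size)).astype(np.float32)
        prob = predict_proba(model, img)[0]
        assert prob.values.shape == (size, size)

    def test_shape_conservation_large(self, rng):
        model = build_model(ModelConfig.tiny(), seed=0)
        img = rng.uniform(0, 1, (1, 3, 256, 256)).astype(np.float32)
        assert predict_proba(model, img)[0].values.shape == (256, 256)

    def test_outputs_are_probabilities(self, rng):
        model = build_model(ModelConfig.tiny(), seed=1)
        img = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
        for prob in predict_proba(model, img):
            assert prob.values.min() >= 0.0 and prob.values.max() <= 1.0

    def test_eval_mode_is_bitwise_deterministic(self, rng):
        model = build_model(ModelConfig.tiny(), seed=2)
        img = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        a = predict_proba(model, img)[0].values
        b = predict_proba(model, img)[0].values
        np.testing.assert_array_equal(a, b)

    def test_non_rgb_rejected(self, rng):
        model = build_model(ModelConfig.tiny(), seed=0)
        with pytest.raises(ValueError, match="RGB"):
            model(Tensor(rng.normal(size=(1, 1, 64, 64)).astype(np.float32)))

    @pytest.mark.parametrize("overrides", [
        dict(enable_fusion=False),
        dict(enable_trans_branch=False),
        dict(enable_cnn_branch=False),
    ])
    def test_ablation_arms_run(self, overrides, rng):
        model = build_model(ModelConfig.tiny(**overrides), seed=0)
        img = rng.uniform(0, 1, (1, 3, 64, 64)).astype(np.float32)
        assert predict_proba(model, img)[0].values.shape == (64, 64)


class TestGradientFlow:
    def test_loss_decreases_after_one_small_step(self, small_phantom):
        from vesselseg.losses import LossConfig, combined_loss
        from vesselseg.pipeline import _standardize

        x = _standardize(small_phantom.image).transpose(2, 0, 1)[None]
        y = small_phantom.mask.astype(np.float32)[None, None]
        for seed in range(5):
            model = build_model(ModelConfig.tiny(), seed=seed)
            model.train()
            opt = nn.AdamW(model.parameters(), lr=1e-5, weight_decay=0.0)
            opt.zero_grad()
            loss0 = combined_loss(model(Tensor(x)).sigmoid(), y, LossConfig(k_percent=50))
            loss0.backward()
            opt.step()
            with nn.no_grad():
                loss1 = combined_loss(model(Tensor(x)).sigmoid(), y,
                                      LossConfig(k_percent=50))
            assert loss1.item() < loss0.item(), f"seed {seed}"


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        model = build_model(ModelConfig.tiny(), seed=4)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        assert restored.config == model.config
        img = rng.uniform(0, 1, (1, 3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(predict_proba(model, img)[0].values,
                                      predict_proba(restored, img)[0].values)
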