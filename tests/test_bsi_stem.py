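"""Dual-stream stem: shapes, attention normalization, scalar oracle, gradients."""

import numpy as np
import pytest

import pigpen as pp
from pigpen import nn
from pigpen.bsi_stem import descriptor_from_yaml, descriptor_to_yaml


def _views(rng, b=2, hw=32):
    return (
        rng.random((b, 3, hw, hw)).astype(np.float32),
        rng.random((b, 3, hw, hw)).astype(np.float32),
    )


class TestAttentionMap:
    def test_constant_input_gives_uniform_lambda_over_c(self):
        cfg = pp.BSIConfig(channels=8, lambda_mult=2.0)
        pre = np.full((1, 8, 4, 4), 0.7, np.float32)
        att = pp.attention_map(pre, cfg)
        assert np.allclose(att.data, 2.0 / 8, atol=1e-6)

    def test_lambda_zero_gives_zero_map(self, rng):
        cfg = pp.BSIConfig(channels=4, lambda_mult=0.0)
        att = pp.attention_map(rng.standard_normal((1, 4, 4, 4)).astype(np.float32), cfg)
        assert np.abs(att.data).max() == 0.0

    @pytest.mark.parametrize("axis", ["channel", "spatial"])
    @pytest.mark.parametrize("lam", [1.0, 2.0, 3.0])
    def test_sums_to_lambda_along_axis(self, rng, axis, lam):
        cfg = pp.BSIConfig(channels=6, lambda_mult=lam, softmax_axis=axis)
        att = pp.attention_map(rng.standard_normal((2, 6, 5, 5)).astype(np.float32), cfg)
        if axis == "channel":
            sums = att.data.sum(axis=1)
        else:
            sums = att.data.sum(axis=(2, 3))
        assert np.abs(sums - lam).max() < 1e-5

    def test_dominant_logit_takes_all_mass(self):
        cfg = pp.BSIConfig(channels=3, lambda_mult=2.0)
        pre = np.zeros((1, 3, 1, 1), np.float32)
        pre[0, 1] = 50.0
        att = pp.attention_map(pre, cfg).data[0, :, 0, 0]
        assert att[1] == pytest.approx(2.0, abs=1e-4)
        assert att[0] == pytest.approx(0.0, abs=1e-4)


class TestBsiForward:
    def test_output_shape_is_quarter_resolution(self, rng):
        cfg = pp.BSIConfig(channels=16, seed=0)
        x_in, x_sup = _views(rng, b=2, hw=64)
        out = pp.bsi_forward(x_in, x_sup, cfg)
        assert out.shape == (2, 16, 16, 16)

    def test_indivisible_input_rejected(self, rng):
        cfg = pp.BSIConfig(channels=4)
        bad = rng.random((1, 3, 30, 30)).astype(np.float32)
        with pytest.raises(ValueError, match="divisible by 4"):
            pp.bsi_forward(bad, bad, cfg)

    def test_lambda_zero_reduces_to_input_branch_with_zero_slice(self, rng):
        """With lambda=0 the modulated slice is exactly zero, so the output is
        the 3D conv + depth max of (0, input-branch features)."""
        cfg = pp.BSIConfig(channels=4, lambda_mult=0.0, seed=1)
        stem = pp.BSIStem(cfg)
        x_in, x_sup = _views(rng, b=1, hw=16)
        out = stem.forward(x_in, x_sup)
        feat_in = stem.conv_input(nn.Tensor(x_in))
        stacked = nn.stack([nn.Tensor(np.zeros_like(feat_in.data)), feat_in], axis=2)
        expected = nn.max_along(stem.conv_fuse3d(stacked), axis=2)
        assert np.allclose(out.data, expected.data, atol=1e-6)

    def test_scalar_oracle_with_unit_kernels(self):
        """1x1 branch convs + 1x1x1 fusion kernel against a from-scratch
        scalar computation of every step."""
        C = 3
        cfg = pp.BSIConfig(channels=C, lambda_mult=2.0, kernel_3d=(1, 1, 1), seed=0)
        stem = pp.BSIStem(cfg)
        rng = np.random.default_rng(7)
        stem.conv_input = nn.Conv2d(3, C, 1, stride=2, padding=0, rng=rng)
        stem.conv_suppressed = nn.Conv2d(3, C, 1, stride=2, padding=0, rng=rng)
        w_in = rng.standard_normal((C, 3)).astype(np.float32)
        b_in = rng.standard_normal(C).astype(np.float32)
        w_sup = rng.standard_normal((C, 3)).astype(np.float32)
        b_sup = rng.standard_normal(C).astype(np.float32)
        w3 = rng.standard_normal((C, C)).astype(np.float32)
        b3 = rng.standard_normal(C).astype(np.float32)
        stem.conv_input.w.data = w_in.reshape(C, 3, 1, 1)
        stem.conv_input.b.data = b_in
        stem.conv_suppressed.w.data = w_sup.reshape(C, 3, 1, 1)
        stem.conv_suppressed.b.data = b_sup
        stem.conv_fuse3d.w.data = w3.reshape(C, C, 1, 1, 1)
        stem.conv_fuse3d.b.data = b3

        x_in = rng.random((1, 3, 4, 4)).astype(np.float32)
        x_sup = rng.random((1, 3, 4, 4)).astype(np.float32)
        out = stem.forward(x_in, x_sup)

        # oracle: pure scalar numpy, no Tensor machinery
        def conv1x1s2(x, w, b):
            sub = x[0, :, ::2, ::2]  # 3 x 2 x 2
            return np.einsum("oc,cij->oij", w, sub) + b[:, None, None]

        f_in = conv1x1s2(x_in, w_in, b_in)
        f_sup = conv1x1s2(x_sup, w_sup, b_sup)
        silu = f_sup * (1 / (1 + np.exp(-f_sup)))
        e = np.exp(silu - silu.max(axis=0, keepdims=True))
        att = 2.0 * e / e.sum(axis=0, keepdims=True)
        mod = att * f_in
        stacked = np.stack([mod, f_in], axis=1)  # C x 2 x 2 x 2
        pos = stacked[:, :, 0, 0]  # spatial stride 2, kernel 1: keep (0, 0)
        fused = np.einsum("oc,cd->od", w3, pos) + b3[:, None]
        expected = fused.max(axis=1)  # depth max pool
        assert out.shape == (1, C, 1, 1)
        assert np.allclose(out.data[0, :, 0, 0], expected, atol=1e-5)

    def test_gradient_reaches_both_views(self, rng):
        cfg = pp.BSIConfig(channels=4, seed=2)
        stem = pp.BSIStem(cfg)
        x_in = nn.Tensor(rng.random((1, 3, 16, 16)).astype(np.float32), requires_grad=True)
        x_sup = nn.Tensor(rng.random((1, 3, 16, 16)).astype(np.float32), requires_grad=True)
        stem.forward(x_in, x_sup).sum().backward()
        assert np.abs(x_in.grad).sum() > 0
        assert np.abs(x_sup.grad).sum() > 0


class TestFusionVariants:
    @pytest.mark.parametrize("hw", [16, 32])
    def test_all_variants_share_output_shape(self, rng, hw):
        shapes = set()
        for fusion in ("3dconv", "addition", "concat2d"):
            cfg = pp.BSIConfig(channels=8, fusion=fusion, seed=0)
            x_in, x_sup = _views(rng, b=1, hw=hw)
            shapes.add(pp.bsi_forward(x_in, x_sup, cfg).shape)
        assert shapes == {(1, 8, hw // 4, hw // 4)}

    def test_addition_with_zero_modulation_pools_input(self, rng):
        cfg = pp.BSIConfig(channels=4, fusion="addition")
        f_in = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        out = pp.fuse_variant_forward(f_in, np.zeros_like(f_in), cfg)
        expected = nn.maxpool2d(nn.Tensor(f_in), 2)
        assert np.allclose(out.data, expected.data)

    def test_concat2d_identity_weights_recover_input(self, rng):
        """Fusion conv set to pick the input-feature channels at one tap
        reproduces those features at pooled resolution."""
        C = 3
        cfg = pp.BSIConfig(channels=C, fusion="concat2d", seed=0)
        stem = pp.BSIStem(cfg)
        w = np.zeros((C, 2 * C, 3, 3), np.float32)
        for c in range(C):
            w[c, C + c, 1, 1] = 1.0  # center tap on the input-feat half
        stem.conv_fuse2d.w.data = w
        stem.conv_fuse2d.b.data = np.zeros(C, np.float32)
        f_in = rng.standard_normal((1, C, 8, 8)).astype(np.float32)
        f_mod = rng.standard_normal((1, C, 8, 8)).astype(np.float32)
        out = pp.fuse_variant_forward(f_in, f_mod, cfg, weights=stem)
        assert np.allclose(out.data, f_in[:, :, ::2, ::2], atol=1e-6)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            pp.BSIConfig(fusion="bilinear").validate()


class TestStemDescriptor:
    def test_descriptor_lists_expected_layers(self):
        desc = pp.stem_replace_descriptor(pp.BSIConfig(channels=16))
        kinds = [(l["kind"], l.get("count", 1)) for l in desc["layers"]]
        assert ("conv2d", 2) in kinds
        assert any(k == "conv3d" for k, _ in kinds)
        assert any(k == "maxpool_depth" for k, _ in kinds)

    def test_round_trip_serialization(self):
        desc = pp.stem_replace_descriptor(pp.BSIConfig(channels=8, fusion="concat2d"))
        assert descriptor_from_yaml(descriptor_to_yaml(desc)) == desc

    def test_output_stride_is_four(self):
        for fusion in ("3dconv", "addition", "concat2d"):
            desc = pp.stem_replace_descriptor(pp.BSIConfig(fusion=fusion))
            assert desc["output_stride"] == 4
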