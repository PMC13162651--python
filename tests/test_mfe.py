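"""Micro-feature-enhancement block: patch geometry, gating, residuals."""

import numpy as np
import pytest

from ovosex import nn
from ovosex.mfe import (MFEModule, PromptGate, RegionEncoderDecoder,
                        channel_mean, merge_patches, split_into_patches)
from ovosex.nn import Tensor


def prompt_gate_oracle(v, prompt, w_trans, eps=1e-8):
    """Literal per-region implementation of the gating equations."""
    B, N, C = v.shape
    out = np.zeros_like(v)
    for b in range(B):
        for i in range(N):
            vi = v[b, i]
            e = np.exp(vi - vi.max())
            v_enh = vi * (e / e.sum())
            denom = np.linalg.norm(v_enh) * np.linalg.norm(prompt) + eps
            s = float(v_enh @ prompt) / denom
            m = max(0.0, s)
            out[b, i] = (v_enh * m) @ w_trans
    return out


class TestPatchGeometry:
    def test_default_patch_split_shape_and_flattened_dim(self, rng):
        x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        patches = split_into_patches(x, 2)
        assert patches.shape == (1, 4, 4, 3)          # N=4, Dp=P^2=4

    def test_single_patch_case(self, rng):
        x = rng.standard_normal((1, 7, 2, 2)).astype(np.float32)
        assert split_into_patches(x, 2).shape == (1, 1, 4, 7)

    @pytest.mark.parametrize("shape,P", [((2, 5, 8, 8), 2), ((1, 3, 12, 8), 4),
                                         ((3, 2, 6, 6), 3)])
    def test_split_merge_roundtrip_is_exact(self, shape, P, rng):
        x = rng.standard_normal(shape).astype(np.float32)
        back = merge_patches(split_into_patches(x, P), shape[2], shape[3], P)
        assert np.array_equal(back.data, x)

    def test_non_divisible_size_raises_with_dimensions(self):
        with pytest.raises(ValueError, match="H=5, W=4, P=2"):
            split_into_patches(np.zeros((1, 2, 5, 4), dtype=np.float32), 2)


class TestChannelMean:
    def test_matches_elementwise_loop(self, rng):
        patches = rng.standard_normal((2, 4, 4, 3)).astype(np.float32)
        out = channel_mean(patches).data
        for b in range(2):
            for n in range(4):
                for d in range(4):
                    assert out[b, n, d] == pytest.approx(
                        patches[b, n, d].mean(), abs=1e-6)

    def test_constant_input_preserved(self):
        patches = np.full((1, 2, 4, 5), 3.25, dtype=np.float32)
        assert np.allclose(channel_mean(patches).data, 3.25)


class TestEncoderDecoder:
    def test_zero_encoder_reduces_to_decoder_bias(self, rng):
        coder = RegionEncoderDecoder(4, 3, 6, rng=rng)
        coder.encoder.weight.data[:] = 0
        coder.encoder.bias.data[:] = 0
        coder.decoder.bias.data[:] = np.arange(6, dtype=np.float32)
        out = coder(rng.standard_normal((2, 5, 4)).astype(np.float32)).data
        assert np.allclose(out, np.arange(6), atol=1e-5)

    def test_output_restores_channel_dimension(self, rng):
        coder = RegionEncoderDecoder(4, 8, 17, rng=rng)
        out = coder(rng.standard_normal((3, 9, 4)).astype(np.float32))
        assert out.shape == (3, 9, 17)

    def test_hand_computed_matrix_algebra(self):
        # single region, Dp=2, latent=2: exact affine/LayerNorm arithmetic
        coder = RegionEncoderDecoder(2, 2, 3)
        coder.encoder.weight.data = np.array([[1., 0.], [0., 2.]], np.float32)
        coder.encoder.bias.data = np.array([0.5, -0.5], np.float32)
        coder.decoder.weight.data = np.array([[1., 1.], [2., 0.], [0., 3.]],
                                             np.float32)
        coder.decoder.bias.data = np.array([0.1, 0.2, 0.3], np.float32)
        x = np.array([[[1.0, 2.0]]], dtype=np.float32)
        h = np.array([1.0 * 1 + 0.5, 2.0 * 2 - 0.5])        # encoder affine
        mu, var = h.mean(), h.var()
        hn = (h - mu) / np.sqrt(var + 1e-5)                  # layer norm
        expect = np.array([hn @ [1, 1] + 0.1, hn @ [2, 0] + 0.2,
                           hn @ [0, 3] + 0.3])
        np.testing.assert_allclose(coder(x).data[0, 0], expect, atol=1e-6)


class TestPromptGate:
    def test_orthogonal_prompt_silences_region(self):
        gate = PromptGate(2)
        gate.prompt.data = np.array([1.0, 0.0], np.float32)
        gate.w_trans.data = np.eye(2, dtype=np.float32)
        # softmax-weighted v lies along the second axis -> cosine 0
        v = np.array([[[0.0, 5.0]]], dtype=np.float32)
        assert np.allclose(gate(v).data, 0.0, atol=1e-7)

    def test_parallel_prompt_identity_transform_passes_enhanced_feature(self):
        gate = PromptGate(3)
        gate.w_trans.data = np.eye(3, dtype=np.float32)
        v = np.array([[[2.0, 2.0, 2.0]]], dtype=np.float32)
        v_enh = v[0, 0] * (np.ones(3) / 3)                    # uniform softmax
        gate.prompt.data = v_enh.astype(np.float32)           # cosine = 1
        np.testing.assert_allclose(gate(v).data[0, 0], v_enh, atol=1e-6)

    def test_matches_per_region_loop_oracle(self, rng):
        gate = PromptGate(8, rng=rng)
        v = rng.standard_normal((1, 6, 8)).astype(np.float32)
        expect = prompt_gate_oracle(v.astype(np.float64),
                                    gate.prompt.data.astype(np.float64),
                                    gate.w_trans.data.astype(np.float64))
        np.testing.assert_allclose(gate(v).data, expect, atol=1e-5)

    def test_mask_bounded_by_unit_interval(self, rng):
        gate = PromptGate(5, rng=rng)
        v = Tensor(rng.standard_normal((2, 10, 5)).astype(np.float32))
        v_enh = v * nn.softmax(v, axis=-1)
        dot = (v_enh * gate.prompt).sum(axis=-1)
        norms = ((v_enh * v_enh).sum(axis=-1).sqrt()
                 * (gate.prompt * gate.prompt).sum(axis=-1).sqrt())
        sim = dot.data / (norms.data + 1e-8)
        mask = np.maximum(0.0, sim)
        assert ((mask >= 0.0) & (mask <= 1.0)).all()


class TestMFEForward:
    def test_output_shape_equals_input_shape(self, rng):
        m = MFEModule(channels=6, patch_size=2, latent_dim=4, seed=0)
        x = rng.standard_normal((2, 6, 8, 8)).astype(np.float32)
        assert m(x).shape == (2, 6, 8, 8)

    def test_anti_aligned_prompt_makes_block_identity(self, rng):
        # positive inputs give positive softmax-weighted features; a strictly
        # negative prompt then yields negative cosine for every region, the
        # sparse mask zeroes the enhancement, and the residual passes x.
        m = MFEModule(channels=4, patch_size=2, latent_dim=4, seed=0)
        m.coder.decoder.weight.data[:] = 0
        m.coder.decoder.bias.data[:] = 1.0        # all region features positive
        m.gate.prompt.data[:] = -1.0
        x = rng.uniform(0.1, 1.0, (1, 4, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(m(x).data, x, atol=1e-7)

    def test_gradient_reaches_every_named_parameter(self, rng):
        m = MFEModule(channels=6, patch_size=2, latent_dim=4, seed=3)
        x = Tensor(rng.standard_normal((2, 6, 8, 8)).astype(np.float32))
        (m(x).pow(2.0)).mean().backward()
        for name, p in m.named_parameters():
            assert p.grad is not None, name
            assert np.abs(p.grad).max() > 0, name

    def test_full_pipeline_matches_loop_oracle_on_region_features(self, rng):
        """The composed encode/decode + gate path equals the literal
        per-region equations on instances up to [2,16,8]."""
        m = MFEModule(channels=8, patch_size=2, latent_dim=4, seed=5)
        x = rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
        desc = channel_mean(split_into_patches(x, 2))
        region = m.coder(desc)
        got = m.gate(region).data
        expect = prompt_gate_oracle(region.data.astype(np.float64),
                                    m.gate.prompt.data.astype(np.float64),
                                    m.gate.w_trans.data.astype(np.float64))
        np.testing.assert_allclose(got, expect, atol=1e-5)
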