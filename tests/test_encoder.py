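"""Encoder: conv blocks, patch tokens, attention, weight sharing, ablations."""

import numpy as np
import pytest

import rst2g
from rst2g import nn
from rst2g.encoder import (CFormerEncoder, ConvBlock, DownBlock, EncoderConfig,
                           MultiHeadSelfAttention, VitBlock, mhsa, patchify,
                           unpatchify)
from oracles import convblock_eval_ref, mhsa_ref, randomize_module


def identity_bn(bn):
    bn._set_buffer("running_mean", np.zeros_like(bn.running_mean))
    bn._set_buffer("running_var", np.ones_like(bn.running_var) - bn.eps)


class TestConvBlock:
    def test_output_is_non_negative(self, rng):
        block = ConvBlock(2, 3, rng).eval()
        out = block(nn.Tensor(rng.normal(size=(2, 2, 6, 6)).astype(np.float32)))
        assert np.all(out.data >= 0)

    def test_zero_weights_identity_bn_gives_zero(self, rng):
        block = ConvBlock(1, 1, rng).eval()
        block.conv.weight.data[:] = 0
        block.conv.bias.data[:] = 0
        identity_bn(block.bn)
        out = block(nn.Tensor(rng.normal(size=(1, 1, 4, 4)).astype(np.float32)))
        assert np.allclose(out.data, 0)

    def test_all_ones_kernel_center_equals_window_sum(self, rng):
        block = ConvBlock(1, 1, rng).eval()
        block.conv.weight.data[:] = 1
        block.conv.bias.data[:] = 0
        identity_bn(block.bn)
        x = np.abs(rng.normal(size=(1, 1, 3, 3))).astype(np.float32)
        out = block(nn.Tensor(x))
        assert np.isclose(out.data[0, 0, 1, 1], x.sum(), rtol=1e-5)

    def test_matches_loop_oracle_in_eval_mode(self, rng):
        block = ConvBlock(2, 3, rng)
        randomize_module(block, rng)
        block.eval()
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        got = block(nn.Tensor(x)).data
        assert np.allclose(got, convblock_eval_ref(x, block), atol=1e-4)

    def test_channel_mismatch_raises(self, rng):
        block = ConvBlock(2, 3, rng)
        with pytest.raises(ValueError, match="channel"):
            block(nn.Tensor(np.zeros((1, 4, 4, 4), dtype=np.float32)))


class TestDownBlock:
    def test_halves_spatial_dims_and_maps_channels(self, rng):
        down = DownBlock(3, 8, rng).eval()
        out = down(nn.Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32)))
        assert out.shape == (2, 8, 4, 4)

    def test_max_pool_picks_window_maximum(self):
        x = nn.Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32))
        assert nn.max_pool2d(x).data.item() == 4.0

    def test_zero_main_branch_leaves_shortcut(self, rng):
        down = DownBlock(2, 4, rng).eval()
        for p in (down.block1.conv.weight, down.block1.conv.bias,
                  down.conv2.weight, down.conv2.bias):
            p.data[:] = 0
        identity_bn(down.block1.bn)
        identity_bn(down.bn2)
        x = nn.Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
        got = down(x)
        pooled = nn.max_pool2d(x)
        expect = down.bn_sc(down.shortcut(pooled)).relu()
        assert np.allclose(got.data, expect.data, atol=1e-6)

    def test_tiny_spatial_input_rejected(self, rng):
        down = DownBlock(1, 2, rng)
        with pytest.raises(ValueError):
            down(nn.Tensor(np.zeros((1, 1, 1, 1), dtype=np.float32)))


class TestPatchify:
    def test_shape_contract(self, rng):
        z = patchify(nn.Tensor(rng.normal(size=(2, 8, 4, 4)).astype(np.float32)))
        assert z.shape == (2, 16, 8)

    def test_round_trip_is_identity(self, rng):
        x = rng.normal(size=(2, 5, 3, 4)).astype(np.float32)
        z = patchify(nn.Tensor(x))
        assert np.array_equal(unpatchify(z, 3, 4).data, x)

    def test_tokens_follow_raster_order(self):
        x = np.arange(4, dtype=np.float32).reshape(1, 1, 2, 2)
        z = patchify(nn.Tensor(x))
        # token i = value at (i // W, i % W)
        assert np.array_equal(z.data[0, :, 0], [0.0, 1.0, 2.0, 3.0])

    def test_unpatchify_rejects_bad_factorisation(self, rng):
        z = nn.Tensor(rng.normal(size=(1, 6, 2)).astype(np.float32))
        with pytest.raises(ValueError):
            unpatchify(z, 2, 2)


class TestMHSA:
    def test_single_token_attention_weight_is_one(self, rng):
        attn = MultiHeadSelfAttention(8, 4, rng)
        z = nn.Tensor(rng.normal(size=(2, 1, 8)).astype(np.float32))
        out, alpha = attn(z, return_attention=True)
        assert np.allclose(alpha.data, 1.0)
        expect = (z.data @ attn.wv.data) @ attn.wo.data
        assert np.allclose(out.data, expect, atol=1e-5)

    def test_rows_sum_to_one_across_random_instances(self, rng):
        attn = MultiHeadSelfAttention(8, 4, rng)
        for _ in range(50):
            z = nn.Tensor(rng.normal(size=(2, 5, 8)).astype(np.float32))
            _, alpha = attn(z, return_attention=True)
            assert np.allclose(alpha.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_two_token_hand_case_matches_direct_evaluation(self):
        # D=2, H=1; projections chosen so the arithmetic is done by hand
        wq = nn.Tensor(np.eye(2, dtype=np.float32))
        wk = nn.Tensor(np.eye(2, dtype=np.float32))
        wv = nn.Tensor(np.eye(2, dtype=np.float32))
        wo = nn.Tensor(np.eye(2, dtype=np.float32))
        z = nn.Tensor(np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32))
        out = mhsa(z, wq, wk, wv, wo, n_heads=1)
        # scores/sqrt(2): row0 = [1,0]/sqrt2 -> softmax [s,1-s]
        s = np.exp(1 / np.sqrt(2)) / (np.exp(1 / np.sqrt(2)) + 1.0)
        expect0 = s * np.array([1.0, 0.0]) + (1 - s) * np.array([0.0, 1.0])
        assert np.allclose(out.data[0, 0], expect0, atol=1e-6)
        assert np.allclose(out.data[0, 1], expect0[::-1], atol=1e-6)

    @pytest.mark.parametrize("N,D,H", [(2, 2, 1), (4, 8, 2), (8, 8, 4)])
    def test_matches_per_head_loop_oracle(self, rng, N, D, H):
        attn = MultiHeadSelfAttention(D, H, rng)
        z = rng.normal(size=(2, N, D)).astype(np.float32)
        got = attn(nn.Tensor(z)).data
        expect = mhsa_ref(z.astype(np.float64), attn.wq.data, attn.wk.data,
                          attn.wv.data, attn.wo.data, H)
        assert np.allclose(got, expect, atol=1e-5)

    def test_indivisible_heads_rejected(self, rng):
        z = nn.Tensor(np.zeros((1, 2, 6), dtype=np.float32))
        w = nn.Tensor(np.eye(6, dtype=np.float32))
        with pytest.raises(ValueError):
            mhsa(z, w, w, w, w, n_heads=4)


class TestVitBlock:
    def test_preserves_shape(self, rng):
        vit = VitBlock(8, 4, 4, rng)
        z = nn.Tensor(rng.normal(size=(2, 6, 8)).astype(np.float32))
        assert vit(z).shape == (2, 6, 8)

    def test_zero_residual_branches_give_identity(self, rng):
        vit = VitBlock(8, 4, 4, rng)
        vit.attn.wo.data[:] = 0
        vit.fc2.weight.data[:] = 0
        vit.fc2.bias.data[:] = 0
        z = rng.normal(size=(2, 6, 8)).astype(np.float32)
        assert np.allclose(vit(nn.Tensor(z)).data, z, atol=1e-6)

    def test_default_transformer_depth_is_six(self):
        assert EncoderConfig().n_vit_layers == 6
        enc = CFormerEncoder(EncoderConfig(), np.random.default_rng(0))
        assert len(enc._vits) == 6


class TestCFormerEncoder:
    CFG = EncoderConfig(n_stages=2, channels=(8, 16), n_vit_layers=1,
                        n_heads=4, input_hw=(16, 16))

    def test_weight_sharing_gives_identical_pyramids(self, rng):
        enc = CFormerEncoder(self.CFG, rng).eval()
        x = nn.Tensor(rng.normal(size=(2, 1, 16, 16)).astype(np.float32))
        pyr = enc.encode_branches(x, x, x)
        for (sa, ba), (sb, bb) in [(pyr["pre"], pyr["post"]),
                                   (pyr["pre"], pyr["res"])]:
            assert np.array_equal(ba.data, bb.data)
            for a, b in zip(sa, sb):
                assert np.array_equal(a.data, b.data)

    def test_deepest_stage_resolution(self, rng):
        cfg = EncoderConfig(n_stages=4, channels=(8, 8, 8, 8), n_vit_layers=1,
                            n_heads=4, input_hw=(64, 64))
        enc = CFormerEncoder(cfg, rng).eval()
        skips, bott = enc(nn.Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert bott.shape[2:] == (4, 4)
        assert [s.shape[2] for s in skips] == [64, 32, 16, 8]

    def test_parameter_count_independent_of_branch_count(self, rng):
        enc = CFormerEncoder(self.CFG, rng).eval()
        before = enc.num_parameters()
        x = nn.Tensor(rng.normal(size=(1, 1, 16, 16)).astype(np.float32))
        enc(x)
        after_one = enc.num_parameters()
        enc.encode_branches(x, x, x)
        after_three = enc.num_parameters()
        assert before == after_one == after_three

    def test_indivisible_input_rejected_with_pad_hint(self, rng):
        with pytest.raises(ValueError, match="pad"):
            EncoderConfig(n_stages=4, channels=(8, 8, 8, 8), input_hw=(60, 60))

    def test_local_ablation_removes_3x3_kernels(self, rng):
        cfg_off = EncoderConfig(n_stages=2, channels=(8, 16), n_vit_layers=1,
                                n_heads=4, input_hw=(16, 16), use_local=False)
        enc = CFormerEncoder(cfg_off, rng)
        for name, p in enc.named_parameters():
            if "conv" in name and p.data.ndim == 4:
                assert p.data.shape[2:] == (1, 1), name
        assert enc.num_parameters() < CFormerEncoder(self.CFG, rng).num_parameters()

    def test_global_ablation_removes_transformer_parameters(self, rng):
        cfg_off = EncoderConfig(n_stages=2, channels=(8, 16), n_vit_layers=1,
                                n_heads=4, input_hw=(16, 16), use_global=False)
        enc = CFormerEncoder(cfg_off, rng)
        names = [n for n, _ in enc.named_parameters()]
        assert not any("vit" in n or "pos_embedding" in n for n in names)
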