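"""Architecture contracts: channel splitting, branch fusion, attention gates,
bottleneck and full-network shape behavior."""

import numpy as np
import pytest

from histonet.arch import (
    CBAM,
    ArchConfig,
    Bottleneck,
    ChannelAttention,
    HistoNet,
    SpatialAttention,
    SplitConv,
    build_network,
    spconv_fuse,
    split_channels,
)
from histonet.nn import Tensor


def t(arr):
    return Tensor(np.asarray(arr, dtype=np.float64))


# ------------------------------------------------------------- split_channels
class TestSplitChannels:
    def test_exact_halving(self, rng):
        x = t(rng.normal(size=(1, 64, 4, 4)))
        a, b = split_channels(x, 0.5)
        assert a.shape[1] == 32 and b.shape[1] == 32

    def test_ceiling_rule(self, rng):
        x = t(rng.normal(size=(1, 3, 4, 4)))
        a, b = split_channels(x, 0.5)
        assert a.shape[1] == 2 and b.shape[1] == 1

    def test_degenerate_alpha_one(self, rng):
        x = t(rng.normal(size=(1, 4, 2, 2)))
        a, b = split_channels(x, 1.0)
        assert a is x and b is None

    def test_concatenation_inverse(self, rng):
        x = t(rng.normal(size=(2, 7, 3, 3)))
        for alpha in (0.3, 0.5, 0.8):
            a, b = split_channels(x, alpha)
            back = np.concatenate([a.data, b.data], axis=1)
            assert np.array_equal(back, x.data)

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_invalid_alpha(self, alpha, rng):
        with pytest.raises(ValueError):
            split_channels(t(rng.normal(size=(1, 4, 2, 2))), alpha)


# ---------------------------------------------------------------- spconv_fuse
class TestFuse:
    def test_equal_inputs_identity(self, rng):
        x = t(rng.normal(size=(1, 4, 3, 3)))
        out = spconv_fuse(x, t(x.data.copy()))
        assert np.allclose(out.data, x.data)

    def test_hand_softmax_weights(self):
        # per-channel GAPs 2.0 and 0.0 -> weights e^2/(e^2+1), 1/(e^2+1)
        y_rep = t(np.full((1, 1, 2, 2), 2.0))
        y_red = t(np.zeros((1, 1, 2, 2)))
        out, (w_rep, w_red) = spconv_fuse(y_rep, y_red, return_weights=True)
        e2 = np.exp(2.0)
        assert np.allclose(w_rep.data, e2 / (e2 + 1), atol=1e-12)
        assert np.allclose(w_red.data, 1 / (e2 + 1), atol=1e-12)
        assert np.allclose(out.data, 2.0 * e2 / (e2 + 1))

    def test_zero_inputs(self):
        z = t(np.zeros((1, 2, 2, 2)))
        out, (w_rep, w_red) = spconv_fuse(z, t(np.zeros((1, 2, 2, 2))),
                                          return_weights=True)
        assert np.allclose(w_rep.data, 0.5) and np.allclose(w_red.data, 0.5)
        assert np.all(out.data == 0)

    def test_convexity_and_weight_sum(self, rng):
        for _ in range(20):
            a = t(rng.normal(size=(2, 5, 4, 4)))
            b = t(rng.normal(size=(2, 5, 4, 4)))
            out, (wa, wb) = spconv_fuse(a, b, return_weights=True)
            assert np.allclose(wa.data + wb.data, 1.0, atol=1e-12)
            lo = np.minimum(a.data, b.data)
            hi = np.maximum(a.data, b.data)
            assert np.all(out.data >= lo - 1e-12)
            assert np.all(out.data <= hi + 1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            spconv_fuse(t(rng.normal(size=(1, 2, 2, 2))),
                        t(rng.normal(size=(1, 3, 2, 2))))


# ------------------------------------------------------------------ spconv
class TestSplitConv:
    def test_shape_contract(self, rng):
        sc = SplitConv(64, 64, stride=1)
        out = sc(t(rng.normal(size=(1, 64, 14, 14))))
        assert out.shape == (1, 64, 14, 14)

    def test_stride_contract(self, rng):
        sc = SplitConv(64, 64, stride=2)
        out = sc(t(rng.normal(size=(1, 64, 14, 14))))
        assert out.shape == (1, 64, 7, 7)

    def test_weight_parameter_hand_sum(self):
        # C_in=C_out=64, alpha=0.5, groups=2, ignoring bias/normalization:
        # 9*32*64/2 + 32*64 + 32*64 = 13,312 (vs 36,864 for a plain 3x3)
        sc = SplitConv(64, 64)
        weights = (sc.conv_rep3.weight.data.size
                   + sc.conv_rep1.weight.data.size
                   + sc.conv_red.weight.data.size)
        assert weights == 13_312

    def test_group_incompatibility(self):
        with pytest.raises(ValueError):
            SplitConv(6, 6, alpha=0.5, groups=2)  # rep=3 not divisible by 2

    def test_alpha_one_skips_redundant_branch(self, rng):
        sc = SplitConv(8, 8, alpha=1.0, groups=2)
        assert not hasattr(sc, "conv_red")
        assert sc(t(rng.normal(size=(1, 8, 4, 4)))).shape == (1, 8, 4, 4)


# ---------------------------------------------------------------- attention
class TestChannelAttention:
    def test_zero_weights_give_half(self, rng):
        ca = ChannelAttention(8, 4)
        ca.w1.data[:] = 0
        ca.w2.data[:] = 0
        g = ca.gate(t(rng.normal(size=(2, 8, 3, 3))))
        assert np.allclose(g.data, 0.5)

    def test_constant_input_doubles_logit(self, rng):
        ca = ChannelAttention(8, 4, rng=rng)
        x = t(np.broadcast_to(rng.normal(size=(1, 8, 1, 1)), (1, 8, 3, 3)).copy())
        v = x.data[:, :, 0, 0]
        logit = ca._mlp(Tensor(v)).data * 2  # avg == max descriptor
        expect = 1 / (1 + np.exp(-logit))
        assert np.allclose(ca.gate(x).data.reshape(1, 8), expect, atol=1e-7)

    def test_open_interval(self, rng):
        ca = ChannelAttention(8, 2, rng=rng)
        g = ca.gate(t(rng.normal(size=(4, 8, 5, 5)))).data
        assert np.all(g > 0) and np.all(g < 1)

    def test_reduction_too_large(self):
        with pytest.raises(ValueError):
            ChannelAttention(8, 16)


class TestSpatialAttention:
    def test_zero_weights_uniform_half(self, rng):
        sa = SpatialAttention(7)
        sa.conv.weight.data[:] = 0
        sa.conv.bias.data[:] = 0
        g = sa.gate(t(rng.normal(size=(1, 4, 9, 9))))
        assert g.shape == (1, 1, 9, 9)
        assert np.allclose(g.data, 0.5)

    def test_shape_preserved_and_open_interval(self, rng):
        sa = SpatialAttention(3, rng=rng)
        g = sa.gate(t(rng.normal(size=(2, 6, 11, 11)))).data
        assert g.shape == (2, 1, 11, 11)
        assert np.all(g > 0) and np.all(g < 1)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            SpatialAttention(4)


class TestCBAM:
    def test_zero_weights_quarter_scaling(self, rng):
        cb = CBAM(8, 4)
        cb.channel.w1.data[:] = 0
        cb.channel.w2.data[:] = 0
        cb.spatial.conv.weight.data[:] = 0
        cb.spatial.conv.bias.data[:] = 0
        x = t(rng.normal(size=(1, 8, 5, 5)))
        out = cb(x)
        assert np.allclose(out.data, 0.25 * x.data, atol=1e-12)

    def test_shape_and_zero_propagation(self, rng):
        cb = CBAM(8, 4, rng=rng)
        x = t(rng.normal(size=(2, 8, 6, 6)))
        assert cb(x).shape == x.shape
        assert np.all(cb(t(np.zeros((1, 8, 4, 4)))).data == 0)

    def test_saturation_gives_exact_identity(self, rng):
        cb = CBAM(8, 4, rng=rng)
        cb.saturate()
        x = Tensor(rng.normal(size=(1, 8, 5, 5)).astype(np.float32))
        assert np.array_equal(cb(x).data, x.data)


# ----------------------------------------------------------------- bottleneck
class TestBottleneck:
    def test_residual_shape_preservation(self, tiny_cfg_factory, rng):
        cfg = ArchConfig(variant="htrec", cbam_reduction=42)
        blk = Bottleneck(cfg, 256, 64, stride=1, rng=rng)
        out = blk(t(rng.normal(size=(1, 256, 14, 14))))
        assert out.shape == (1, 256, 14, 14)

    def test_zero_transform_residual_passthrough(self, rng):
        cfg = ArchConfig(variant="htrec", base_width=8, input_size=64,
                         cbam_reduction=8)
        blk = Bottleneck(cfg, 32, 8, stride=1, rng=rng)
        blk.eval()
        blk.bn3.weight.data[:] = 0  # zero the transform branch pre-attention
        blk.bn3.bias.data[:] = 0
        x = t(rng.normal(size=(1, 32, 8, 8)))
        assert np.allclose(blk(x).data, np.maximum(x.data, 0), atol=1e-12)

    def test_stride_two_projection(self, rng):
        cfg = ArchConfig(variant="baseline")
        blk = Bottleneck(cfg, 256, 128, stride=2, rng=rng)
        assert blk.proj is not None and blk.proj.stride == 2
        out = blk(t(rng.normal(size=(1, 256, 14, 14))))
        assert out.shape == (1, 512, 7, 7)

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            Bottleneck(ArchConfig(variant="baseline"), 64, 64, stride=3)


# ---------------------------------------------------------------- full model
class TestBuildNetwork:
    def test_head_contract(self, tiny_cfg_factory):
        model = build_network(tiny_cfg_factory("baseline"))
        x = np.random.default_rng(0).normal(size=(2, 3, 64, 64)).astype(np.float32)
        assert model(x).shape == (2, 3)

    def test_stage_geometry(self, tiny_cfg_factory):
        model = build_network(tiny_cfg_factory("htrec"))
        model(np.zeros((1, 3, 64, 64), np.float32), capture_features=True)
        # input 64 -> stem/pool /4 -> stages /8 => 2x2 spatial, 4*base*8 channels
        assert model.last_features.shape == (1, 256, 2, 2)

    def test_bottleneck_count_matches_depths(self):
        cfg = ArchConfig(variant="baseline")
        model = build_network(cfg)
        assert len(model.blocks._order) == sum(cfg.stage_depths) == 16

    def test_forward_deterministic(self, tiny_cfg_factory, rng):
        model = build_network(tiny_cfg_factory("htrec"), seed=3)
        model.eval()
        x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        out1 = model(x).data.copy()
        out2 = model(x).data.copy()
        assert np.array_equal(out1, out2)

    def test_gating_saturation_recovers_unattended_logits(self, rng):
        cfg_att = ArchConfig(variant="htrec", base_width=8, input_size=64,
                             stage_depths=(1, 1, 1, 1), cbam_reduction=8)
        cfg_plain = ArchConfig(variant="res_sp", base_width=8, input_size=64,
                               stage_depths=(1, 1, 1, 1))
        attended = build_network(cfg_att, seed=5)
        plain = build_network(cfg_plain, seed=6)
        shared = {k: v for k, v in attended.state_dict().items() if "cbam" not in k}
        plain.load_state_dict(shared)
        for blk in attended.blocks._order:
            blk.cbam.saturate()
        attended.eval()
        plain.eval()
        x = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
        np.testing.assert_allclose(attended(x).data, plain(x).data, atol=1e-5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ArchConfig(variant="nope")
        with pytest.raises(ValueError):
            ArchConfig(variant="htrec", cbam_reduction=10_000)
        with pytest.raises(ValueError):
            ArchConfig(variant="baseline", input_size=100)
        with pytest.raises(ValueError):
            ArchConfig(variant="res_sp", spconv_alpha=0.0)

    def test_default_stage_depths_sum(self):
        assert sum(ArchConfig(variant="baseline").stage_depths) == 16

    def test_input_shape_validation(self, tiny_cfg_factory):
        model = build_network(tiny_cfg_factory("baseline"))
        with pytest.raises(ValueError):
            model(np.zeros((1, 1, 64, 64), np.float32))
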