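"""Split-attention block, ASPP, deformable convolution and DASPP contracts."""

import numpy as np
import pytest

from thyroseg import nn
from thyroseg.blocks import (
    ASPP,
    DASPP,
    BlockConfig,
    DeformableConv2d,
    DeformableConvSpec,
    DilationSet,
    SplitAttentionBlock,
)
from thyroseg.exceptions import ConfigurationError
from thyroseg.nn import functional as F
from thyroseg.nn.tensor import Tensor


def _t(rng, *shape):
    return Tensor(rng.normal(size=shape).astype(np.float32))


# ------------------------------------------------------------- split attention
class TestSplitAttention:
    def test_shape_contract_stride1(self, rng):
        blk = SplitAttentionBlock(BlockConfig(64, 64), rng=rng).eval()
        y = blk(_t(rng, 2, 64, 32, 32))
        assert y.shape == (2, 64, 32, 32)

    @pytest.mark.parametrize("hw", [(16, 16), (15, 17)])
    def test_stride2_halves_spatial_dims_ceil(self, rng, hw):
        blk = SplitAttentionBlock(BlockConfig(8, 16, stride=2), rng=rng).eval()
        y = blk(_t(rng, 1, 8, *hw))
        assert y.shape == (1, 16, (hw[0] + 1) // 2, (hw[1] + 1) // 2)

    def test_attention_weights_sum_to_one_across_radix(self, rng):
        for _ in range(20):
            radix = int(rng.choice([1, 2, 4]))  # must divide the split width
            blk = SplitAttentionBlock(BlockConfig(8, 8, radix=radix), rng=rng).eval()
            a = blk.attention_weights(_t(rng, 2, 8, 8, 8))
            np.testing.assert_allclose(a.data.sum(axis=1), 1.0, atol=1e-6)

    def test_radix1_attention_is_exactly_one(self, rng):
        blk = SplitAttentionBlock(BlockConfig(4, 4, radix=1), rng=rng).eval()
        a = blk.attention_weights(_t(rng, 1, 4, 6, 6))
        np.testing.assert_array_equal(a.data, 1.0)

    def test_channel_mismatch_and_bad_radix_raise(self, rng):
        blk = SplitAttentionBlock(BlockConfig(4, 8), rng=rng)
        with pytest.raises(ConfigurationError):
            blk(_t(rng, 1, 6, 8, 8))
        with pytest.raises(ConfigurationError):
            BlockConfig(4, 4, radix=0)

    def test_deterministic_and_batch_preserving(self, rng):
        blk = SplitAttentionBlock(BlockConfig(4, 8), rng=rng).eval()
        x = _t(rng, 3, 4, 8, 8)
        np.testing.assert_array_equal(blk(x).data, blk(x).data)
        assert blk(x).shape[0] == 3


# ------------------------------------------------------------------------ ASPP
class TestASPP:
    def test_reference_shape_and_fused_width(self, rng):
        aspp = ASPP(1024, DilationSet((1, 6, 12, 18), True), rng=rng).eval()
        y = aspp(_t(rng, 1, 1024, 16, 16))
        assert y.shape == (1, 512, 16, 16)

    @pytest.mark.parametrize("hw", [(1, 1), (5, 9)])
    def test_output_spatial_dims_match_input(self, rng, hw):
        aspp = ASPP(8, DilationSet((1, 2), False), rng=rng).eval()
        y = aspp(_t(rng, 2, 8, *hw))
        assert y.shape[2:] == hw

    def test_pool_branch_broadcast_of_constant_field_is_constant(self, rng):
        aspp = ASPP(4, rng=rng).eval()
        x = Tensor(np.full((1, 4, 10, 10), 2.0, dtype=np.float32))
        p = aspp.pool_proj(F.global_avg_pool(x))
        up = F.bilinear_resize(p, (10, 10)).data
        np.testing.assert_allclose(up, float(up[0, 0, 0, 0]), atol=1e-6)
        # interior of every dilated branch is also constant on a constant field
        for m in aspp.dilated:
            b = m(x).data[:, :, 4:6, 4:6]
            np.testing.assert_allclose(b, b[:, :, :1, :1] * np.ones_like(b), atol=1e-5)

    def test_dilation_rates_validation(self):
        with pytest.raises(ConfigurationError):
            DilationSet((6, 1, 12))
        with pytest.raises(ConfigurationError):
            DilationSet((2, 6))
        with pytest.raises(ConfigurationError):
            DilationSet((1, 6, 6))


# ------------------------------------------------------------------ deformable
def dense_conv_oracle(x, w, groups=1):
    """Brute-force 'same'-padded correlation (independent of the engine)."""
    B, Cin, H, W = x.shape
    Cout, cg, kh, kw = w.shape
    pad = (kh - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, Cout, H, W))
    cog = Cout // groups
    for b in range(B):
        for o in range(Cout):
            g = o // cog
            for i in range(H):
                for j in range(W):
                    out[b, o, i, j] = np.sum(
                        w[o] * xp[b, g * cg:(g + 1) * cg, i:i + kh, j:j + kw]
                    )
    return out


class TestDeformableConv:
    def test_zero_offsets_uniform_modulation_equal_dense_conv(self, rng):
        # freshly initialized predictors are zero => offsets 0, modulation uniform
        for _ in range(20):
            cin = int(rng.choice([2, 4]))
            cout = int(rng.choice([2, 4]))
            g = 2 if (cin % 2 == 0 and cout % 2 == 0 and rng.random() < 0.5) else 1
            dc = DeformableConv2d(DeformableConvSpec(cin, cout, groups=g), rng=rng).eval()
            x = rng.normal(size=(1, cin, 6, 7)).astype(np.float32)
            got = dc(Tensor(x)).data
            want = dense_conv_oracle(x, dc.weight.data, groups=g) + dc.bias.data.reshape(1, -1, 1, 1)
            assert np.abs(got - want).max() < 1e-5

    def test_integer_offset_equals_shifted_input_conv(self, rng):
        dc = DeformableConv2d(DeformableConvSpec(2, 3, groups=1), rng=rng).eval()
        dc.offset_conv.bias.data[0::2] = 1.0  # dy = +1 for every sampling point
        x = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        shifted = np.zeros_like(x)
        shifted[:, :, :-1] = x[:, :, 1:]  # zero-padded shift by one row
        got = dc(Tensor(x)).data
        want = dc.as_standard_conv(Tensor(shifted)).data
        # row 0 differs by construction: the shifted image zero-pads above,
        # while the deformed grid re-enters the original image there
        assert np.abs(got[:, :, 1:] - want[:, :, 1:]).max() < 1e-5

    def test_constant_input_fractional_offsets_interior_unchanged(self, rng):
        dc = DeformableConv2d(DeformableConvSpec(2, 2, groups=1), rng=rng).eval()
        x = Tensor(np.full((1, 2, 10, 10), 1.7, dtype=np.float32))
        base = dc(x).data
        dc.offset_conv.bias.data[:] = 0.4  # fractional everywhere
        frac = dc(x).data
        np.testing.assert_allclose(frac[:, :, 3:7, 3:7], base[:, :, 3:7, 3:7], atol=1e-5)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            DeformableConvSpec(4, 4, kernel=4)

    def test_differentiable_wrt_input_weights_offsets(self, rng):
        dc = DeformableConv2d(DeformableConvSpec(2, 2, groups=1), rng=rng)
        dc.offset_conv.bias.data[:] = 0.3
        x = Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32), requires_grad=True)
        dc(x).sum().backward()
        assert x.grad is not None and np.abs(x.grad).sum() > 0
        assert dc.weight.grad is not None and np.abs(dc.weight.grad).sum() > 0
        assert dc.offset_conv.weight.grad is not None


# ----------------------------------------------------------------------- DASPP
class TestDASPP:
    def test_reference_shape(self, rng):
        daspp = DASPP(1024, rng=rng).eval()
        y = daspp(_t(rng, 1, 1024, 16, 16))
        assert y.shape == (1, 512, 16, 16)

    def test_frozen_offsets_match_plain_conv_variant(self, rng):
        daspp = DASPP(32, DilationSet((1, 2, 4), True), rng=rng).eval()
        x = _t(rng, 2, 32, 12, 12)
        got = daspp(x).data
        want = daspp.forward_with_standard_convs(x).data
        assert np.abs(got - want).max() < 1e-5

    def test_every_branch_receives_gradient(self, rng):
        daspp = DASPP(16, DilationSet((1, 2), True), rng=rng).train()
        daspp.drop.p = 0.0
        # batch 2: batch norm of the pooled 1x1 branch is degenerate at batch 1
        x = _t(rng, 2, 16, 8, 8)
        daspp(x).sum().backward()
        branch_weights = [
            daspp.conv1.layers[0].weight,
            daspp.deform1.weight,
            daspp.dilated[0].layers[0].weight,
            daspp.pool_proj.layers[0].weight,
            daspp.parallel.weight,
            daspp.fuse.layers[0].weight,
        ]
        for w in branch_weights:
            assert w.grad is not None and np.abs(w.grad).sum() > 0

    def test_spatial_dims_preserved(self, rng):
        daspp = DASPP(8, DilationSet((1, 3), False), rng=rng).eval()
        assert daspp(_t(rng, 1, 8, 5, 7)).shape[2:] == (5, 7)
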