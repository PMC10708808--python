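"""Directional pooling, descriptor algebra, positional encoding, PABlock."""

import numpy as np
import pytest

from ipseg.nn.autograd import Tensor
from ipseg.pablock import (DirectionalDescriptor, PABlock, PABlockConfig,
                           SegmentationHead, compress, compressed_length,
                           pool_over_height, pool_over_width,
                           sinusoidal_encoding, split_descriptor)


class TestDirectionalPooling:
    def test_constant_map(self):
        d = pool_over_width(np.full((2, 3, 4), 0.7))
        assert d.direction == "height" and d.values.shape == (2, 3)
        np.testing.assert_allclose(d.values, 0.7)

    def test_hand_averages(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        np.testing.assert_allclose(pool_over_width(x).values, [[1.5, 3.5]])
        np.testing.assert_allclose(pool_over_height(x).values, [[2.0, 3.0]])

    def test_mean_consistency(self, rng):
        x = rng.random((3, 7, 5))
        for pool in (pool_over_width, pool_over_height):
            assert abs(pool(x).values.mean() - x.mean()) < 1e-12

    def test_transpose_symmetry(self, rng):
        x = rng.random((2, 6, 6))
        np.testing.assert_allclose(pool_over_height(x.transpose(0, 2, 1)).values,
                                   pool_over_width(x).values)


class TestSplitCompress:
    def test_split_then_concat_roundtrip(self, rng):
        z = DirectionalDescriptor("fused", rng.random((3, 9)))
        zh, zw = split_descriptor(z, 4, 5)
        assert (zh.length, zw.length) == (4, 5)
        np.testing.assert_array_equal(
            np.concatenate([zh.values, zw.values], axis=1), z.values)

    def test_split_validation(self, rng):
        z = DirectionalDescriptor("fused", rng.random((3, 5)))
        with pytest.raises(ValueError):
            split_descriptor(z, 0, 5)
        with pytest.raises(ValueError):
            split_descriptor(z, 3, 3)

    def test_compress_identity_at_r1(self, rng):
        z = DirectionalDescriptor("height", rng.random((2, 7)))
        np.testing.assert_allclose(compress(z, 1).values, z.values)

    def test_compress_112_by_64_bin_means(self, rng):
        vals = rng.random((3, 112))
        out = compress(DirectionalDescriptor("height", vals), 64)
        assert out.length == compressed_length(112, 64) == 2
        np.testing.assert_allclose(out.values[:, 0], vals[:, :56].mean(axis=1))
        np.testing.assert_allclose(out.values[:, 1], vals[:, 56:].mean(axis=1))

    def test_compress_constant_and_bounds(self, rng):
        z = DirectionalDescriptor("width", np.full((2, 13), 0.4))
        np.testing.assert_allclose(compress(z, 4).values, 0.4)
        z2 = DirectionalDescriptor("width", rng.random((2, 13)))
        out = compress(z2, 4).values
        assert out.min() >= z2.values.min() - 1e-12
        assert out.max() <= z2.values.max() + 1e-12

    def test_compress_rejects_bad_ratio(self, rng):
        z = DirectionalDescriptor("width", rng.random((2, 13)))
        with pytest.raises(ValueError):
            compress(z, 0)


class TestSinusoidalEncoding:
    def test_position_zero_pattern(self):
        pe = sinusoidal_encoding(5, d=512, base=1000.0)
        col0 = pe.values[:, 0]
        np.testing.assert_array_equal(col0[0::2], np.ones(256))   # odd i: cos
        np.testing.assert_array_equal(col0[1::2], np.zeros(256))  # even i: sin

    def test_last_row_slow_frequency_value(self):
        pe = sinusoidal_encoding(4, d=512, base=1000.0)
        # i = d = 512 (even): sin(p / base^{i/d}) = sin(1/1000) at p=1
        assert pe.values[511, 1] == pytest.approx(9.99999833e-4, rel=1e-9)

    def test_bounds_and_distinct_positions(self):
        for length in (2, 64, 512):
            pe = sinusoidal_encoding(length, d=512, base=1000.0)
            assert pe.values.min() >= -1.0 and pe.values.max() <= 1.0
            cols = np.unique(pe.values.T, axis=0)
            assert cols.shape[0] == length  # no positional collisions

    def test_validation(self):
        with pytest.raises(ValueError):
            sinusoidal_encoding(0)
        with pytest.raises(ValueError):
            sinusoidal_encoding(4, d=1)


@pytest.fixture
def block(rng):
    return PABlock(channels=6, cfg=PABlockConfig(r=4, d=8), rng=rng)


class TestPABlock:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            PABlockConfig(r=0)
        with pytest.raises(ValueError):
            PABlockConfig(gate="tanh")

    def test_fuse_shape_and_relu(self, block, rng):
        zh = Tensor(rng.standard_normal((2, 6, 5)))
        zw = Tensor(rng.standard_normal((2, 6, 7)))
        out = block.fuse(zh, zw)
        assert out.shape == (2, 6, 12)
        assert out.data.min() >= 0.0  # post-ReLU

    def test_fuse_identity_conv_norm_neutral(self, block, rng):
        """With an identity center-tap conv and neutral normalization the
        fusion reduces to ReLU(concat)."""
        w = np.zeros_like(block.fuse_conv.weight.data)
        for c in range(6):
            w[c, c, 1] = 1.0
        block.fuse_conv.weight.data = w
        block.fuse_conv.bias.data = np.zeros(6, dtype=np.float32)
        block.fuse_norm.running_mean[:] = 0.0
        block.fuse_norm.running_var[:] = 1.0 - block.fuse_norm.eps
        block.eval()
        zh = Tensor(rng.standard_normal((1, 6, 4)).astype(np.float32))
        zw = Tensor(rng.standard_normal((1, 6, 3)).astype(np.float32))
        expected = np.maximum(np.concatenate([zh.data, zw.data], axis=2), 0.0)
        np.testing.assert_allclose(block.fuse(zh, zw).data, expected,
                                   atol=1e-6)

    def test_fuse_all_negative_gives_zero(self, block, rng):
        block.fuse_conv.weight.data = np.zeros_like(block.fuse_conv.weight.data)
        block.fuse_conv.bias.data = np.full(6, -5.0, dtype=np.float32)
        block.fuse_norm.running_mean[:] = 0.0
        block.fuse_norm.running_var[:] = 1.0 - block.fuse_norm.eps
        block.eval()
        out = block.fuse(Tensor(rng.random((1, 6, 4))),
                         Tensor(rng.random((1, 6, 3))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_fuse_channel_mismatch(self, block, rng):
        with pytest.raises(ValueError):
            block.fuse(Tensor(rng.random((1, 6, 4))),
                       Tensor(rng.random((1, 5, 4))))

    def test_directional_constancy(self, block, rng):
        x = Tensor(rng.standard_normal((2, 6, 9, 7)).astype(np.float32))
        o_h, o_w = block.directional_maps(x)
        assert o_h.shape == o_w.shape == (2, 6, 9, 7)
        np.testing.assert_array_equal(
            o_h.data, np.broadcast_to(o_h.data[..., :1], o_h.shape))
        np.testing.assert_array_equal(
            o_w.data, np.broadcast_to(o_w.data[..., :1, :], o_w.shape))

    def test_restore_rejects_length_mismatch(self, block, rng):
        pe = sinusoidal_encoding(3, d=8).values
        with pytest.raises(ValueError):
            block.restore_h(pe, Tensor(rng.random((1, 6, 2))), 9)

    def test_forward_preserves_shape(self, block, rng):
        for shape in [(1, 6, 5, 5), (2, 6, 9, 4), (1, 6, 1, 7)]:
            x = Tensor(rng.standard_normal(shape).astype(np.float32))
            assert block(x).shape == shape

    def test_zero_input_zero_output(self, block):
        x = Tensor(np.zeros((1, 6, 5, 5), dtype=np.float32))
        np.testing.assert_array_equal(block(x).data, 0.0)

    def test_deterministic_repeat_through_three_blocks(self, rng):
        blocks = [PABlock(4, PABlockConfig(r=4, d=8), rng) for _ in range(3)]
        x = np.random.default_rng(3).standard_normal((2, 4, 6, 6)).astype(np.float32)

        def run():
            t = Tensor(x)
            for b in blocks:
                b.eval()
                t = b(t)
            return t.data

        np.testing.assert_array_equal(run(), run())

    def test_untrained_gate_near_half(self, block, rng):
        """Small-scale gate init keeps the fresh block close to Y = 1.5 X."""
        x = Tensor(rng.standard_normal((2, 6, 8, 8)).astype(np.float32))
        block.eval()
        y = block(x)
        gate = y.data / np.where(np.abs(x.data) < 1e-8, 1.0, x.data) - 1.0
        gate = gate[np.abs(x.data) > 1e-3]
        assert np.abs(gate - 0.5).mean() < 0.2


class TestSegmentationHead:
    def test_output_shape_and_upscale(self, rng):
        head = SegmentationHead(6, 2, rng)
        x = Tensor(rng.standard_normal((2, 6, 7, 7)).astype(np.float32))
        assert head(x, (28, 28)).shape == (2, 2, 28, 28)

    def test_no_resampling_when_sizes_match(self, rng):
        head = SegmentationHead(6, 2, rng)
        x = Tensor(rng.standard_normal((1, 6, 7, 7)).astype(np.float32))
        direct = head.conv(x).data
        np.testing.assert_array_equal(head(x, (7, 7)).data, direct)

    def test_zero_conv_gives_bias_valued_maps(self, rng):
        head = SegmentationHead(6, 3, rng)
        head.conv.weight.data = np.zeros_like(head.conv.weight.data)
        head.conv.bias.data = np.array([0.1, 0.2, 0.3], dtype=np.float32)
        out = head(Tensor(np.ones((1, 6, 5, 5), dtype=np.float32)), (10, 10))
        for k, b in enumerate([0.1, 0.2, 0.3]):
            np.testing.assert_allclose(out.data[0, k], b, atol=1e-6)

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            SegmentationHead(6, 1, rng)
        head = SegmentationHead(6, 2, rng)
        with pytest.raises(ValueError):
            head(Tensor(np.zeros((1, 6, 7, 7), dtype=np.float32)), (5, 7))
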