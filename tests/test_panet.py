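"""Backbone/ASPP contracts, multi-scale assembly, fusion, ablation identity."""

import numpy as np
import pytest

from ipseg.nn import functional as F
from ipseg.nn.autograd import Tensor
from ipseg.pablock import PABlockConfig
from ipseg.panet import (ASPP, ASPPConfig, BackboneConfig, PANet, PANetConfig,
                         build_backbone)

SMALL_ASPP = ASPPConfig(dilation_rates=(1, 2), branch_channels=8)


def small_config(**kw):
    defaults = dict(
        factors=(1.0,),
        backbone=BackboneConfig(name="tiny", output_stride=8,
                                feature_channels=16),
        aspp=SMALL_ASPP,
        pablock=PABlockConfig(r=4, d=8),
        n_pablocks=1,
    )
    defaults.update(kw)
    return PANetConfig(**defaults)


class TestBackbone:
    @pytest.mark.parametrize("size,os,expected", [
        (112, 8, 14), (112, 16, 7), (224, 16, 14), (56, 8, 7)])
    def test_output_stride_contract(self, size, os, expected):
        cfg = BackboneConfig(name="tiny", output_stride=os, feature_channels=16)
        net = build_backbone(cfg, np.random.default_rng(0))
        net.eval()
        out = net(Tensor(np.zeros((1, 1, size, size), dtype=np.float32)))
        assert out.shape == (1, 16, expected, expected)

    def test_seeded_construction_is_deterministic(self):
        cfg = BackboneConfig(name="tiny", feature_channels=16)
        a = build_backbone(cfg, np.random.default_rng(7))
        b = build_backbone(cfg, np.random.default_rng(7))
        for (ka, va), (kb, vb) in zip(sorted(a.state_dict().items()),
                                      sorted(b.state_dict().items())):
            assert ka == kb
            np.testing.assert_array_equal(va, vb)

    def test_tiny_backbone_is_fast_on_cpu(self):
        import time
        cfg = BackboneConfig(name="tiny", feature_channels=32)
        net = build_backbone(cfg, np.random.default_rng(0))
        net.eval()
        x = Tensor(np.zeros((1, 1, 112, 112), dtype=np.float32))
        net(x)  # warm-up
        t0 = time.perf_counter()
        net(x)
        assert time.perf_counter() - t0 < 1.0

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(name="vgg")
        with pytest.raises(ValueError):
            BackboneConfig(output_stride=4)


class TestASPP:
    def test_spatial_dims_preserved(self, rng):
        aspp = ASPP(16, SMALL_ASPP, np.random.default_rng(0))
        aspp.eval()
        x = Tensor(rng.standard_normal((2, 16, 9, 11)).astype(np.float32))
        assert aspp(x).shape == (2, 8, 9, 11)

    def test_dilation_exceeding_extent_rejected(self, rng):
        aspp = ASPP(16, ASPPConfig(dilation_rates=(6,), branch_channels=8),
                    np.random.default_rng(0))
        x = Tensor(np.zeros((1, 16, 7, 7), dtype=np.float32))
        with pytest.raises(ValueError):
            aspp(x)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ASPPConfig(dilation_rates=(2, 2))
        with pytest.raises(ValueError):
            ASPPConfig(dilation_rates=(0,))

    def test_constant_input_constant_output(self):
        aspp = ASPP(4, ASPPConfig(dilation_rates=(1,), branch_channels=4),
                    np.random.default_rng(0))
        aspp.eval()
        out = aspp(Tensor(np.full((1, 4, 9, 9), 0.5, dtype=np.float32)))
        interior = out.data[:, :, 3:-3, 3:-3]  # away from zero-padding halo
        np.testing.assert_allclose(
            interior, np.broadcast_to(interior[:, :, :1, :1], interior.shape),
            atol=1e-5)


class TestPANetAssembly:
    def test_multiscale_shape_contract(self, rng):
        cfg = small_config(factors=(1.0, 2.0, 4.0))
        model = PANet(cfg, np.random.default_rng(0))
        model.eval()
        h = w = 40
        rungs = [Tensor(rng.random((1, 1, int(f * h), int(f * w)))
                        .astype(np.float32)) for f in cfg.factors]
        per_scale, fused = model(rungs)
        assert [p.shape for p in per_scale] == [
            (1, 2, 40, 40), (1, 2, 80, 80), (1, 2, 160, 160)]
        assert fused.shape == (1, 2, 40, 40)

    def test_wrong_rung_count_rejected(self, rng):
        model = PANet(small_config(factors=(1.0, 2.0)), np.random.default_rng(0))
        with pytest.raises(ValueError):
            model([Tensor(rng.random((1, 1, 40, 40)).astype(np.float32))])

    def test_ablation_reduces_to_baseline_path(self, rng):
        """PABlocks off + single factor: the model equals backbone+ASPP+head,
        and the averaging-initialized fusion passes the map through exactly."""
        cfg = small_config(use_pablocks=False)
        model = PANet(cfg, np.random.default_rng(0))
        model.eval()
        x = Tensor(rng.random((1, 1, 40, 40)).astype(np.float32))
        per_scale, fused = model([x])
        baseline = model.baseline_forward(x)
        np.testing.assert_array_equal(per_scale[0].data, baseline.data)
        np.testing.assert_array_equal(fused.data, baseline.data)

    def test_averaging_fusion_of_identical_maps_is_identity(self, rng):
        cfg = small_config(factors=(1.0, 2.0, 4.0))
        model = PANet(cfg, np.random.default_rng(0))
        y = Tensor(rng.standard_normal((1, 2, 20, 20)).astype(np.float32))
        fused = model.fuse([y, y, y])
        np.testing.assert_allclose(fused.data, y.data, atol=1e-6)

    def test_fusion_class_count_mismatch_rejected(self, rng):
        model = PANet(small_config(factors=(1.0, 2.0)), np.random.default_rng(0))
        with pytest.raises(ValueError):
            model.fuse([Tensor(rng.random((1, 2, 20, 20)).astype(np.float32)),
                        Tensor(rng.random((1, 3, 20, 20)).astype(np.float32))])

    def test_shared_scale_weights_option(self, rng):
        cfg = small_config(factors=(1.0, 2.0), share_scale_weights=True)
        model = PANet(cfg, np.random.default_rng(0))
        assert model.branches[0] is model.branches[1]

    def test_invalid_factor_ladders_rejected(self):
        with pytest.raises(ValueError):
            small_config(factors=(2.0, 4.0))
        with pytest.raises(ValueError):
            small_config(factors=(1.0, 1.0))

    def test_deterministic_forward(self, rng):
        model = PANet(small_config(), np.random.default_rng(0))
        model.eval()
        x = rng.random((1, 1, 40, 40)).astype(np.float32)
        out1 = model([Tensor(x)])[1].data
        out2 = model([Tensor(x)])[1].data
        np.testing.assert_array_equal(out1, out2)


class TestGradientReachability:
    def test_every_parameter_receives_gradient(self, rng):
        """Composite fused + auxiliary loss reaches all learned parameters."""
        cfg = small_config(factors=(1.0, 2.0))
        model = PANet(cfg, np.random.default_rng(0))
        rungs = [Tensor(rng.random((2, 1, int(f * 48), int(f * 48)))
                        .astype(np.float32)) for f in cfg.factors]
        per_scale, fused = model(rungs)
        target = rng.integers(0, 2, (2, 48, 48))
        loss = F.softmax_cross_entropy(fused, target)
        for p in per_scale:
            t = rng.integers(0, 2, (2, p.shape[2], p.shape[3]))
            loss = loss + F.softmax_cross_entropy(p, t) * Tensor(np.float32(0.4))
        loss.backward()
        for name, param in model.named_parameters():
            assert param.grad is not None, name
            assert np.any(param.grad != 0), f"dead parameter: {name}"
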