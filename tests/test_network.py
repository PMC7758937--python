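import numpy as np
import pytest

from slowonset.augment import MiniBatch
from slowonset.network import (NetworkConfig, ResNet1D,
                               antialiased_downsample, build_model,
                               build_variant, forward, gaussian_kernel3)


def independent_tally(cfg: NetworkConfig) -> int:
    """Layer-by-layer arithmetic tally, independent of the model code.

    Convolutions (k * cin * cout weights + cout biases), one BN (2 * ch)
    before each block convolution plus the final BN, 1x1 projections with
    bias at the two width changes, and the bias-free output unit.
    """
    total = 0
    # stem
    c_in = cfg.input_shape[1]
    total += cfg.stem_kernel * c_in * cfg.stage_widths[0]
    total += cfg.stage_widths[0]
    cur = cfg.stage_widths[0]
    for w, n, k in zip(cfg.stage_widths, cfg.blocks_per_stage,
                       cfg.stage_kernels):
        for _ in range(n):
            total += 2 * cur            # bn1 over block input
            total += k * cur * w + w    # conv1
            total += 2 * w              # bn2
            total += k * w * w + w      # conv2
            if cur != w:
                total += cur * w + w    # projection, 1x1, bias
            cur = w
    total += 2 * cur                    # final BN
    total += cur                        # dense, no bias
    return total


class TestGaussianKernel:
    def test_reference_sigma_matches_high_precision_oracle(self):
        # independently evaluated: exp(-1/(2 s^2)) with s = 0.79577,
        # normalized; frozen to 10 decimal places
        w = gaussian_kernel3(0.79577)
        expected = np.array([0.2379555157, 0.5240889685, 0.2379555157])
        assert np.abs(w - expected).max() < 1e-9

    def test_flat_and_delta_limits(self):
        assert np.abs(gaussian_kernel3(1e6) - 1 / 3).max() < 1e-9
        assert np.abs(gaussian_kernel3(1e-3)
                      - np.array([0.0, 1.0, 0.0])).max() < 1e-9

    def test_symmetric_unit_sum_for_any_sigma(self):
        for sigma in [0.1, 0.5, 0.79577, 2.0, 10.0]:
            w = gaussian_kernel3(sigma)
            assert w[0] == w[2]
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel3(0.0)


class TestAntialiasedDownsample:
    def test_constant_preserved_at_half_length(self):
        x = np.full((2000, 10), 7.0)
        y = antialiased_downsample(x)
        assert y.shape == (1000, 10)
        assert np.abs(y - 7.0).max() < 1e-12

    def test_nyquist_attenuation(self):
        w = gaussian_kernel3(0.79577)
        x = np.tile(np.array([1.0, -1.0] * 500)[:, None], (1, 10))
        y = antialiased_downsample(x)
        expected = abs(2 * w[0] - w[1])
        interior = np.abs(y[1:-1])
        assert interior.max() == pytest.approx(expected, rel=1e-9)
        # >= 20x attenuation relative to DC (which passes unchanged)
        assert interior.max() < 1.0 / 20.0

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            antialiased_downsample(np.zeros((7, 10)))


class TestBuildModel:
    def test_reference_parameter_count(self):
        model = build_model()
        assert model.parameter_count == 165664
        assert model.parameter_count == independent_tally(NetworkConfig())

    def test_tally_matches_model_on_scaled_widths(self):
        for width in (8, 16):
            cfg = NetworkConfig().scaled(width)
            assert build_model(cfg).parameter_count == independent_tally(cfg)

    def test_narrower_model_has_fewer_parameters(self):
        assert build_model(NetworkConfig().scaled(16)).parameter_count \
            < build_model().parameter_count

    def test_temporal_lengths_halve_through_stages(self, tiny_net_cfg):
        model = ResNet1D(tiny_net_cfg, seed=0)
        x = np.random.default_rng(0).normal(size=(2, 64, 10))
        model.forward_logits(x, training=False)
        lengths = [b.conv2._x.shape[1] for b in model.blocks]
        # input 64: halved in blocks 2, 4, 6
        assert lengths == [64, 32, 32, 16, 16, 8]

    def test_output_is_probability(self, tiny_net_cfg):
        model = ResNet1D(tiny_net_cfg, seed=0)
        x = np.random.default_rng(1).normal(size=(4, 64, 10))
        p = model.predict_proba(x)
        assert p.shape == (4,)
        assert np.all((p > 0) & (p < 1))

    def test_misplaced_conv_count_rejected(self):
        with pytest.raises(ValueError, match="conv"):
            NetworkConfig(blocks_per_stage=(3, 2, 2))


class TestVariants:
    def test_baseline_flags(self):
        _, flags = build_variant(variant="baseline")
        assert flags.zscore == "per_sequence"
        assert flags.l2_lambda == 0.0
        assert flags.antialiased is False
        assert flags.discount is False
        assert flags.batch_size == 64

    def test_no_l2_same_architecture(self):
        full, _ = build_variant(variant="full")
        m, flags = build_variant(variant="no_l2")
        assert flags.l2_lambda == 0.0
        assert m.parameter_count == full.parameter_count

    @pytest.mark.parametrize("variant,bs", [("bs32", 32), ("bs64", 64)])
    def test_batch_size_variants(self, variant, bs):
        m, flags = build_variant(variant=variant)
        assert flags.batch_size == bs
        assert m.parameter_count == 165664

    def test_no_antialias_same_count_different_pooling(self):
        m, flags = build_variant(variant="no_antialias")
        assert m.parameter_count == 165664
        assert flags.antialiased is False
        # downsampling blocks carry a strided conv and max-pooled shortcut
        ds = [b for b in m.blocks if b.downsample]
        assert all(b.conv1.stride == 2 for b in ds)
        assert all(b.blur_main is None for b in ds)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_variant(variant="dropout")


class TestForward:
    def test_duplicate_windows_score_identically(self, tiny_net_cfg):
        model = ResNet1D(tiny_net_cfg, seed=0)
        x = np.random.default_rng(2).normal(size=(1, 64, 10))
        batch = MiniBatch(values=np.concatenate([x, x]),
                          labels=np.array([1, 1]), p=np.array([1.0, 1.0]))
        p = forward(model, batch)
        assert p[0] == p[1]
        assert np.all(np.isfinite(p))

    def test_gmp_matches_per_channel_temporal_max(self, tiny_net_cfg):
        model = ResNet1D(tiny_net_cfg, seed=0)
        x = np.random.default_rng(3).normal(size=(2, 64, 10))
        # recompute the feature map feeding the pooled head
        h = model.stem.forward(x, False)
        for b in model.blocks:
            h = b.forward(h, False)
        h = model.final_relu.forward(model.final_bn.forward(h, False), False)
        pooled = model.gmp.forward(h, False)
        assert np.array_equal(pooled, h.max(axis=1))

    def test_shape_mismatch_rejected(self, tiny_net_cfg):
        model = ResNet1D(tiny_net_cfg, seed=0)
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((2, 32, 10)))


def test_save_load_round_trip(tmp_path, tiny_net_cfg):
    model = ResNet1D(tiny_net_cfg, seed=5)
    x = np.random.default_rng(4).normal(size=(2, 64, 10))
    p1 = model.predict_proba(x)
    model.save(tmp_path / "w.npz")
    clone = ResNet1D.load(tmp_path / "w.npz", tiny_net_cfg)
    assert np.array_equal(clone.predict_proba(x), p1)
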