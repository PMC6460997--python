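"""Dilation-scheme analysis and network block contracts."""

import numpy as np
import pytest

from ndnseg import nn
from ndnseg.netspec import (
    NDN,
    DilationScheme,
    NetworkSpec,
    RnDBlock,
    SEBlock,
    ResidualBlock,
    build_rnd_block,
    count_parameters,
    gridding_coverage,
    hdc_coverage_survey,
    is_hole_free,
    receptive_field,
    validate_hdc,
)


class TestHdc:
    def test_canonical_scheme_distances(self):
        # backward recurrence by hand: M3=5, M2=max(5-4, 4-5, 2)=2,
        # M1=max(2-2, 2-2, 1)=1; both below K=3
        report = validate_hdc(DilationScheme((1, 2, 5), 3))
        assert report.max_distances == (1, 2, 5)
        assert report.coprime_ok and report.distance_ok and report.valid

    def test_common_divisor_rejected(self):
        report = validate_hdc(DilationScheme((2, 4), 3))
        assert not report.coprime_ok
        assert not report.valid

    def test_large_last_rate_rejected_by_distance(self):
        # M2 = max(9-4, 4-9, 2) = 5 >= K
        report = validate_hdc(DilationScheme((1, 2, 9), 3))
        assert report.max_distances[1] == 5
        assert not report.distance_ok

    def test_last_distance_equals_last_rate(self):
        for rates in [(1, 2, 5), (1, 1, 2), (3, 4, 5)]:
            assert validate_hdc(DilationScheme(rates)).max_distances[-1] == rates[-1]

    def test_empty_rates_rejected(self):
        with pytest.raises(ValueError):
            DilationScheme(())


class TestGriddingCoverage:
    def test_canonical_scheme_covers_contiguous_interval(self):
        cov = gridding_coverage(DilationScheme((1, 2, 5), 3))
        assert cov == set(range(-8, 9))

    def test_even_rates_leave_holes(self):
        cov = gridding_coverage(DilationScheme((2, 2, 2), 3))
        assert all(o % 2 == 0 for o in cov)
        assert not is_hole_free(DilationScheme((2, 2, 2), 3))

    def test_single_unit_rate(self):
        assert gridding_coverage(DilationScheme((1,), 3)) == {-1, 0, 1}

    def test_hdc_conditions_never_accept_a_holey_scheme(self):
        # soundness over the full rate cube: a scheme passing both HDC
        # conditions always has gap-free tap coverage.  The converse fails
        # for some schemes (the conditions are conservative); those
        # exceptions are characterized in the survey test below.
        rows = hdc_coverage_survey(max_rate=6, kernel=3)
        assert len(rows) == 216
        assert all(r["hole_free"] for r in rows if r["valid"])

    def test_survey_mismatches_are_only_conservative_rejections(self):
        rows = hdc_coverage_survey(max_rate=6, kernel=3)
        mismatches = [r for r in rows if r["valid"] != r["hole_free"]]
        assert mismatches, "the conditions are known to be conservative"
        assert all(r["hole_free"] and not r["valid"] for r in mismatches)


class TestReceptiveField:
    def test_single_conv(self):
        assert receptive_field([(3, 1, 1)]) == 3

    def test_rnd_scheme_analytic(self):
        # 1 + 2 * (1 + 2 + 5) = 17
        assert receptive_field([(3, r, 1) for r in (1, 2, 5)]) == 17

    def test_residual_two_convs(self):
        assert receptive_field([(3, 1, 1), (3, 1, 1)]) == 5

    def test_stride_multiplies_jump(self):
        # conv3 stride 2, then conv3: 1 + 2*1 + 2*2 = 7
        assert receptive_field([(3, 1, 2), (3, 1, 1)]) == 7


def _impulse_support(block, extent=40, channels=1):
    """Measured receptive field: nonzero extent of the response to a
    centered impulse with all conv weights set to one (BN at inference
    is affine with default running stats, preserving support)."""
    for p in block.parameters():
        if p.name.endswith("weight") and p.value.ndim == 5:
            p.value[...] = 1.0
        elif p.name.endswith("bias"):
            p.value[...] = 0.0
    x = np.zeros((extent, extent, 5, channels))
    x[extent // 2, extent // 2, 2, 0] = 1.0
    out = np.abs(block(x)).sum(axis=-1)
    nz = np.flatnonzero(out.sum(axis=(1, 2)))
    return int(nz[-1] - nz[0] + 1)


class TestBlocks:
    def test_residual_identity_with_zero_path(self, rng):
        block = ResidualBlock(3, 3, rng=rng)
        for p in block.path.parameters():
            p.value[...] = 0.0
        x = rng.normal(size=(4, 4, 4, 3))
        np.testing.assert_allclose(block(x), x)

    def test_residual_shape_and_param_count(self, rng):
        block = ResidualBlock(16, 16, rng=rng)
        x = rng.normal(size=(8, 8, 4, 16))
        assert block(x).shape == (8, 8, 4, 16)
        # two conv3 layers (27*16*16 + 16 each) plus two BN (2*16 each)
        assert count_parameters(block) == 2 * (27 * 16 * 16 + 16) + 2 * 2 * 16

    def test_residual_impulse_support(self, rng):
        assert _impulse_support(ResidualBlock(1, 1, rng=rng), extent=20) == 5

    def test_se_zero_excitation_halves_channels(self, rng):
        se = SEBlock(4, reduction=2, rng=rng)
        for p in se.parameters():
            p.value[...] = 0.0
        x = rng.normal(size=(4, 4, 4, 4))
        np.testing.assert_allclose(se(x), 0.5 * x)

    def test_se_scale_constant_over_space(self, rng):
        se = SEBlock(3, reduction=1, rng=rng)
        x = rng.normal(size=(5, 5, 5, 3)) + 2.0
        out = se(x)
        ratio = out / x
        for c in range(3):
            assert np.ptp(ratio[..., c]) < 1e-10
        assert out.shape == x.shape

    def test_rnd_refuses_invalid_scheme(self, rng):
        with pytest.raises(ValueError, match="HDC"):
            build_rnd_block(2, 2, DilationScheme((2, 4, 6)), rng=rng)
        block = build_rnd_block(
            2, 2, DilationScheme((2, 4, 6)), rng=rng, allow_invalid_scheme=True
        )
        assert isinstance(block, RnDBlock)

    def test_rnd_identity_with_zero_path(self, rng):
        block = RnDBlock(3, 3, rng=rng)
        for p in block.path.parameters():
            p.value[...] = 0.0
        x = rng.normal(size=(8, 8, 4, 3))
        np.testing.assert_allclose(block(x), x)

    def test_rnd_impulse_support_matches_analytic(self, rng):
        block = RnDBlock(1, 1, scheme=DilationScheme((1, 2, 5)), rng=rng)
        assert block.receptive_span == 17
        assert _impulse_support(block, extent=40) == 17


class TestNdn:
    def test_paper_scale_shapes(self, rng):
        spec = NetworkSpec(in_channels=4, classes=4, base_filters=16)
        net = NDN(spec, rng=rng)
        first_conv = net.enc_blocks[0].path.layers[0]
        assert first_conv.weight.size + first_conv.bias.size == 1744
        x = rng.normal(size=(96, 96, 48, 4))
        skips = []
        # bottleneck spatial size: three halvings of 96x96x48
        h = x[None]
        for lvl in range(3):
            h = net.enc_blocks[lvl].forward(h)
            h = net.enc_se[lvl].forward(h)
            h = net.pools[lvl].forward(h)
        assert h.shape[1:4] == (12, 12, 6)

    def test_binary_stage_head(self, rng):
        spec = NetworkSpec(in_channels=4, classes=2, base_filters=2)
        net = NDN(spec, rng=rng)
        x = rng.normal(size=(32, 32, 16, 4))
        out = net(x)
        assert out.shape == (32, 32, 16, 2)

    def test_indivisible_axis_is_named(self, rng):
        spec = NetworkSpec(in_channels=4, classes=2, base_filters=2)
        net = NDN(spec, rng=rng)
        with pytest.raises(ValueError, match="axis z"):
            net(np.zeros((16, 16, 12, 4)))

    def test_parameter_count_independent_of_input_size(self, rng):
        spec = NetworkSpec(in_channels=4, classes=2, base_filters=2)
        net = NDN(spec, rng=rng)
        n0 = net.n_params
        net(np.zeros((16, 16, 8, 4)))
        net(np.zeros((32, 32, 16, 4)))
        assert net.n_params == n0

    def test_conv_params_quadruple_when_filters_double(self, rng):
        small = NDN(NetworkSpec(in_channels=4, classes=2, base_filters=2), rng=rng)
        big = NDN(NetworkSpec(in_channels=4, classes=2, base_filters=4), rng=rng)
        # per-layer closed form: an interior conv C->C has 27 C^2 + C weights
        conv_s = small.enc_blocks[0].path.layers[3]
        conv_b = big.enc_blocks[0].path.layers[3]
        assert conv_s.weight.size == 27 * 2 * 2
        assert conv_b.weight.size == 27 * 4 * 4
        assert conv_b.weight.size == 4 * conv_s.weight.size

    def test_inference_is_deterministic(self, rng):
        spec = NetworkSpec(in_channels=4, classes=2, base_filters=2)
        net = NDN(spec, rng=rng)
        x = rng.normal(size=(16, 16, 8, 4))
        np.testing.assert_array_equal(net(x), net(x))
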