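"""The convolution primitive and the three composite blocks."""

import numpy as np
import pytest

from icnet.blocks import (
    AttentionBlock,
    ConvSpec,
    FCNBlock,
    MABlock,
    attention_block,
    conv2d,
    fcn_block,
    ma_block,
)
from icnet.engine import Sigmoid, Tanh

from conftest import brute_force_conv


class TestConv2d:
    def test_zero_input_gives_zero_output(self, rng):
        x = np.zeros((1, 4, 4, 1))
        w = rng.normal(size=(3, 3, 1, 2))
        y = conv2d(x, ConvSpec(3, 3, 1, 2, padding=1), w)
        assert np.all(y == 0.0)

    def test_sum_of_ones(self):
        y = conv2d(np.ones((1, 3, 3, 1)), ConvSpec(3, 3, 1, 1), np.ones((3, 3, 1, 1)))
        assert y.shape == (1, 1, 1, 1)
        assert y[0, 0, 0, 0] == pytest.approx(9.0)

    @pytest.mark.parametrize("shape,kshape", [
        ((1, 5, 5, 2), (3, 3, 2, 3)),
        ((2, 8, 8, 4), (3, 3, 4, 2)),
        ((1, 6, 7, 3), (1, 1, 3, 5)),
    ])
    def test_matches_direct_summation_oracle(self, rng, shape, kshape):
        x = rng.normal(size=shape)
        w = rng.normal(size=kshape)
        spec = ConvSpec(kshape[0], kshape[1], kshape[2], kshape[3])
        assert np.allclose(conv2d(x, spec, w), brute_force_conv(x, w), atol=1e-6)

    def test_output_size_contract(self):
        # v = n + 2p - f + 1 for stride 1
        assert ConvSpec(3, 3, 1, 1, padding=0).output_size(8) == 6
        assert ConvSpec(3, 3, 1, 1, padding=1).output_size(8) == 8
        assert ConvSpec(5, 5, 1, 1, padding=2).output_size(16) == 16

    def test_linearity_in_input(self, rng):
        x = rng.normal(size=(1, 5, 5, 2))
        w = rng.normal(size=(3, 3, 2, 1))
        spec = ConvSpec(3, 3, 2, 1)
        assert np.allclose(conv2d(3.0 * x, spec, w), 3.0 * conv2d(x, spec, w))

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channels"):
            conv2d(rng.normal(size=(1, 4, 4, 3)), ConvSpec(3, 3, 2, 1),
                   rng.normal(size=(3, 3, 2, 1)))

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            ConvSpec(0, 3, 1, 1)
        with pytest.raises(ValueError):
            ConvSpec(3, 3, 1, 1, padding=-1)


class TestMABlock:
    def test_zero_input_gives_zero_output(self):
        block = MABlock(1, 4, rng=np.random.default_rng(0))
        y = block(np.zeros((1, 4, 4, 1)), training=True)
        assert np.allclose(y, 0.0)

    def test_output_channels_and_spatial_preservation(self):
        block = MABlock(4, 16, rng=np.random.default_rng(0))
        y = block(np.random.default_rng(1).normal(size=(1, 8, 8, 4)))
        assert y.shape == (1, 8, 8, 16)

    def test_matches_stepwise_composition(self, rng):
        block = MABlock(1, 3, rng=np.random.default_rng(7))
        x = rng.normal(size=(1, 4, 4, 1))
        expected = block.conv2(np.maximum(0.0, block.bn(block.conv1(x))))
        assert np.allclose(ma_block(x, 3, block), expected, atol=1e-10)

    def test_invalid_filters(self):
        with pytest.raises(ValueError):
            MABlock(1, 0)


class TestFCNBlock:
    def test_branch_values_at_zero_input(self):
        block = FCNBlock(2, 4, rng=np.random.default_rng(0))
        x = np.zeros((1, 5, 5, 2))
        y1 = np.maximum(0.0, block.conv_relu(x))
        y2 = np.tanh(block.conv_tanh(y1))
        y3 = Sigmoid()(block.conv_sigmoid(y2))
        assert np.allclose(y1, 0.0)
        assert np.allclose(y2, 0.0)
        assert np.allclose(y3, 0.5)

    def test_intermediate_width_is_three_times_filters(self):
        block = FCNBlock(8, 8, rng=np.random.default_rng(0))
        y = block(np.random.default_rng(0).normal(size=(1, 8, 8, 8)))
        assert block.intermediate_width() == 24
        assert block._shapes == (8, 8, 8)
        assert y.shape == (1, 8, 8, 8)

    @pytest.mark.parametrize("parallel", [False, True])
    def test_branch_codomains(self, rng, parallel):
        block = FCNBlock(3, 5, rng=np.random.default_rng(2), parallel=parallel)
        x = rng.normal(size=(2, 6, 6, 3))
        y1 = np.maximum(0.0, block.conv_relu(x))
        y2 = np.tanh(block.conv_tanh(x if parallel else y1))
        y3 = Sigmoid()(block.conv_sigmoid(x if parallel else y2))
        assert (y1 >= 0).all()
        assert (np.abs(y2) < 1).all()
        assert ((y3 > 0) & (y3 < 1)).all()
        assert block(x).shape == (2, 6, 6, 5)

    def test_sequential_wiring_feeds_branches_in_chain(self, rng):
        block = FCNBlock(2, 3, rng=np.random.default_rng(5))
        x = rng.normal(size=(1, 4, 4, 2))
        y1 = np.maximum(0.0, block.conv_relu(x))
        y2 = np.tanh(block.conv_tanh(y1))
        y3 = Sigmoid()(block.conv_sigmoid(y2))
        y4 = np.concatenate([y1, y2, y3], axis=-1)
        expected = np.maximum(0.0, block.conv_merge(y4))
        assert np.allclose(fcn_block(x, 3, block), expected, atol=1e-10)


class TestAttentionBlock:
    def test_zeroed_mask_conv_gives_half_mask(self, rng):
        block = AttentionBlock(4, 4, 4, rng=np.random.default_rng(0))
        block.psi.weight.value[:] = 0.0
        block.psi.bias.value[:] = 0.0
        skip = rng.normal(size=(1, 4, 4, 4))
        gating = rng.normal(size=(1, 4, 4, 4))
        y = block(skip, gating)
        t = block.theta(skip)
        assert np.allclose(block.last_mask(), 0.5)
        assert np.allclose(y, 0.5 * t)

    def test_mask_strictly_inside_unit_interval(self, rng):
        block = AttentionBlock(8, 8, 8, rng=np.random.default_rng(1))
        block(rng.normal(size=(2, 4, 4, 8)), rng.normal(size=(2, 4, 4, 8)))
        mask = block.last_mask()
        assert ((mask > 0) & (mask < 1)).all()

    def test_output_never_exceeds_theta_features(self, rng):
        block = AttentionBlock(8, 8, 8, rng=np.random.default_rng(2))
        skip = rng.normal(size=(1, 4, 4, 8))
        y = block(skip, rng.normal(size=(1, 4, 4, 8)))
        t = block.theta(skip)
        assert (np.abs(y) <= np.abs(t) + 1e-12).all()

    def test_matches_stepwise_composition(self, rng):
        block = AttentionBlock(8, 8, 8, rng=np.random.default_rng(3))
        skip = rng.normal(size=(1, 4, 4, 8))
        gating = rng.normal(size=(1, 4, 4, 8))
        t = block.theta(skip)
        p = block.phi(gating)
        a = np.maximum(0.0, t + p)
        mask = Sigmoid()(block.psi(a))
        assert np.allclose(attention_block(skip, gating, 8, block), mask * t, atol=1e-6)

    def test_spatial_mismatch_raises(self, rng):
        block = AttentionBlock(2, 2, 2, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="spatial"):
            block(rng.normal(size=(1, 4, 4, 2)), rng.normal(size=(1, 8, 8, 2)))


@pytest.mark.parametrize("factory", [
    lambda: MABlock(2, 4, rng=np.random.default_rng(9)),
    lambda: FCNBlock(2, 4, rng=np.random.default_rng(9)),
])
def test_blocks_are_deterministic_given_weights(factory, rng):
    x = rng.normal(size=(1, 6, 6, 2))
    a, b = factory(), factory()
    assert np.array_equal(a(x), b(x))
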