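"""Neck contracts: channel transfer designs, SPP arithmetic, weighted
fusion, BiFPN/PANet shapes and parameter budgets, ECA behaviour and the
activation identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conedet import autograd as ag
from conedet.autograd import Tensor, no_grad
from conedet.backbone import FeatureMap, FeaturePyramid
from conedet.neck import (CHANNEL_DESIGNS, BiFPN, ChannelDesign, ECA,
                          BiFPNNeck, PANetNeck, SPP, bifpn_pass,
                          channel_transfer, eca_attention, eca_kernel_size,
                          hard_swish, panet_neck, spp, swish, weighted_fuse)


def make_pyramid(channels=(40, 112, 320), base_side=16, seed=0):
    rng = np.random.default_rng(seed)
    maps = []
    for i, c in enumerate(channels):
        side = base_side // (2 ** i)
        maps.append(FeatureMap(Tensor(rng.random(
            (1, c, side, side), dtype=np.float32)), 8 * 2 ** i))
    return FeaturePyramid(*maps)


# -- channel transfer --------------------------------------------------

@pytest.mark.parametrize("design_id", [1, 2, 3, 4])
def test_channel_transfer_designs(design_id):
    pyr = channel_transfer(make_pyramid(), ChannelDesign(design_id))
    assert pyr.channels == CHANNEL_DESIGNS[design_id]
    assert (pyr.p3.side, pyr.p4.side, pyr.p5.side) == (16, 8, 4)


def test_channel_design_table():
    assert CHANNEL_DESIGNS == {1: (128, 256, 512), 2: (256, 256, 256),
                               3: (128, 128, 128), 4: (64, 64, 64)}
    assert ChannelDesign().design_id == 3


def test_identity_one_by_one_conv_preserves_values():
    x = Tensor(np.random.default_rng(0).random((1, 4, 5, 5), dtype=np.float32))
    w = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1)
    out = ag.conv2d(x, Tensor(w))
    np.testing.assert_allclose(out.data, x.data, rtol=1e-6)


# -- SPP ---------------------------------------------------------------

def test_spp_channel_arithmetic():
    mod = SPP(128, (5, 9, 13))
    x = Tensor(np.random.default_rng(0).random((1, 128, 13, 13),
                                               dtype=np.float32))
    pooled = ag.concat([x] + [ag.maxpool2d_same(x, k) for k in (5, 9, 13)],
                       axis=1)
    assert pooled.shape == (1, 512, 13, 13)  # 4 x 128 pre-projection
    mod.eval()
    with no_grad():
        out = mod(x)
    assert out.shape == (1, 128, 13, 13)


def test_spp_constant_map_and_identity_pool():
    const = Tensor(np.full((1, 2, 6, 6), 3.5, dtype=np.float32))
    for k in (1, 3, 5):
        np.testing.assert_allclose(ag.maxpool2d_same(const, k).data, 3.5)
    fm = FeatureMap(const, 32)
    with pytest.raises(ValueError, match="odd"):
        spp(fm, pool_sides=(4,))


# -- weighted fusion ---------------------------------------------------

def test_weighted_fuse_against_elementwise_oracle():
    rng = np.random.default_rng(42)
    maps = [rng.random((1, 3, 2, 2)).astype(np.float32) for _ in range(3)]
    w = np.array([1.0, 2.0, 3.0])
    eps = 1e-4
    out = weighted_fuse(maps, w, eps=eps).data
    # brute-force elementwise evaluation of the fusion formula
    expected = np.zeros_like(maps[0])
    denom = eps + np.maximum(w, 0).sum()
    for c in range(3):
        for i in range(2):
            for j in range(2):
                expected[0, c, i, j] = sum(
                    max(wk, 0.0) / denom * m[0, c, i, j]
                    for wk, m in zip(w, maps))
    np.testing.assert_allclose(out, expected, rtol=1e-5)


def test_weighted_fuse_trivial_cases():
    a = np.random.default_rng(0).random((1, 2, 3, 3)).astype(np.float32)
    same = weighted_fuse([a, a], [1.0, 1.0]).data
    np.testing.assert_allclose(same, a, rtol=1e-3)       # equal inputs
    first = weighted_fuse([a, 5.0 * a], [1.0, 0.0]).data
    np.testing.assert_allclose(first, a, rtol=1e-3)      # weight (1, 0)
    zero = weighted_fuse([a, a], [-1.0, -2.0]).data      # all non-positive
    np.testing.assert_allclose(zero, 0.0)


@given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=4))
@settings(max_examples=50, deadline=None)
def test_fusion_coefficients_form_sub_convex_combination(weights):
    w = np.maximum(np.array(weights), 0.0)
    eps = 1e-4
    coeffs = w / (eps + w.sum())
    assert (coeffs >= 0).all()
    assert coeffs.sum() <= 1.0
    assert coeffs.sum() >= 1.0 - eps / (eps + w.sum()) - 1e-9


# -- BiFPN / PANet -----------------------------------------------------

def test_bifpn_preserves_channels_and_strides():
    pyr = make_pyramid((128, 128, 128))
    out = bifpn_pass(pyr)
    assert out.channels == (128, 128, 128)
    assert (out.p3.stride, out.p4.stride, out.p5.stride) == (8, 16, 32)


def test_bifpn_zero_init_propagates_zero():
    mod = BiFPN((8, 8, 8))
    for p in mod.parameters():
        p.data[...] = 0.0
    mod.eval()
    zero_pyr = make_pyramid((8, 8, 8))
    for m in zero_pyr.maps():
        m.values.data[...] = 0.0
    with no_grad():
        out = mod(zero_pyr)
    for m in out.maps():
        np.testing.assert_allclose(m.values.data, 0.0)


def test_panet_shapes_and_channel_doubling():
    pyr = make_pyramid()
    out = panet_neck(pyr)
    assert out.channels == (128, 256, 512)
    assert (out.p3.stride, out.p4.stride, out.p5.stride) == (8, 16, 32)
    # concatenation doubles channels at each merge pre-projection
    mod = PANetNeck((40, 112, 320))
    assert mod.td4.layers[0].conv.weight.shape[1] == 512   # 256 + 256
    assert mod.bu5.layers[0].conv.weight.shape[1] == 1024  # 512 + 512


def test_bifpn_neck_parameter_budget_below_panet():
    ebe = BiFPNNeck((40, 112, 320), ChannelDesign(3))
    pan = PANetNeck((40, 112, 320))
    assert ebe.num_parameters() < pan.num_parameters()
    assert BiFPN((128, 128, 128)).num_parameters() < pan.num_parameters()


# -- ECA ---------------------------------------------------------------

@pytest.mark.parametrize("channels,k", [(128, 3), (256, 5), (2, 1), (512, 5),
                                        (1024, 5), (64, 3)])
def test_eca_kernel_size_rule(channels, k):
    assert eca_kernel_size(channels) == k


def test_eca_kernel_size_properties():
    with pytest.raises(ValueError):
        eca_kernel_size(0)
    ks = [eca_kernel_size(c) for c in range(1, 4097)]
    assert all(k % 2 == 1 and k >= 1 for k in ks)
    assert all(b >= a for a, b in zip(ks, ks[1:]))  # non-decreasing in C


def test_eca_zero_kernel_halves_input():
    x = np.random.default_rng(0).random((1, 8, 4, 4)).astype(np.float32)
    out = eca_attention(x, weight=np.zeros(eca_kernel_size(8)))
    np.testing.assert_allclose(out.data, x / 2.0, rtol=1e-5)


def test_eca_hand_computed_chain():
    # 16-channel 1x1 map: GAP is the map itself; k(16)=3 conv + sigmoid
    rng = np.random.default_rng(2)
    x = rng.normal(size=16).reshape(1, 16, 1, 1).astype(np.float32)
    w = np.array([0.2, -0.1, 0.4], dtype=np.float32)
    assert eca_kernel_size(16) == 3
    g = x.ravel()
    padded = np.concatenate([[0.0], g, [0.0]])
    conv = np.array([padded[i:i + 3] @ w for i in range(16)])
    expected = x.ravel() / (1.0 + np.exp(-conv))
    out = eca_attention(x, weight=w)
    np.testing.assert_allclose(out.data.ravel(), expected, rtol=1e-5)


def test_eca_preserves_shape_and_scale_range():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(2, 32, 6, 6)).astype(np.float32)
    mod = ECA(32)
    mod.weight.data = rng.normal(size=mod.k).astype(np.float32)
    with no_grad():
        out = mod(Tensor(x))
    assert out.shape == x.shape
    scale = out.data / np.where(np.abs(x) < 1e-9, 1.0, x)
    mask = np.abs(x) > 1e-9
    assert (scale[mask] > 0.0).all() and (scale[mask] < 1.0).all()


# -- activations -------------------------------------------------------

def test_hard_swish_identities():
    assert hard_swish(0.0) == 0.0
    assert hard_swish(3.0) == 3.0
    for x in (3.0, 4.5, 10.0):
        assert hard_swish(x) == x          # Relu6 saturates
    for x in (-3.0, -5.0, -100.0):
        assert hard_swish(x) == 0.0


def test_hard_swish_monotone_and_bounded():
    xs = np.linspace(-1.0, 10.0, 2001)
    ys = hard_swish(xs)
    assert (np.diff(ys) >= -1e-12).all()    # monotone for x >= -1
    grid = np.linspace(-20, 20, 20001)
    assert hard_swish(grid).min() >= -0.375 - 1e-12
    assert hard_swish(-1.5) == pytest.approx(-0.375)


def test_swish_limits_and_hswish_approximation():
    assert swish(0.0) == 0.0
    assert swish(2.0, beta=1e6) == pytest.approx(2.0)  # beta -> inf at x > 0
    grid = np.linspace(-6.0, 6.0, 12001)
    dev = np.abs(hard_swish(grid) - swish(grid, beta=1.0))
    assert dev.max() <= 0.15


def test_tensor_activations_match_numpy_forms():
    x = np.linspace(-5, 5, 101).astype(np.float32)
    np.testing.assert_allclose(hard_swish(Tensor(x)).data, hard_swish(x),
                               atol=1e-6)
    np.testing.assert_allclose(swish(Tensor(x)).data, swish(x), atol=1e-6)
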