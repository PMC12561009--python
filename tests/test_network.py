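"""Architecture blocks: closed-form identities, oracles, accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gamsunet import nn
from gamsunet.network import (
    ChannelSqueezeExcite,
    GatedSkip,
    GAMSUNetPP,
    MSBlock,
    NestedUNet,
    NetworkConfig,
    ResidualConvUnit,
    SCSEBlock,
    SpatialSqueezeExcite,
    count_flops,
    count_parameters,
    forward,
    gated_skip,
    msblock_forward,
    rcu_forward,
)
from gamsunet.nn import autodiff as ad


def _zero_convs(module):
    """Zero every conv weight/bias; GN affine params keep their 1/0 init."""
    for name, p in module.named_parameters():
        if "weight" in name or "bias" in name or name.endswith(("fc.weight", "fc.bias")):
            if "gamma" not in name and "beta" not in name and "alpha" not in name:
                p.data = np.zeros_like(p.data)
    return module


# ---------------------------------------------------------------------------
# RCU
# ---------------------------------------------------------------------------

def test_rcu_zero_init_is_identity_on_nonnegative_input(rng):
    rcu = _zero_convs(ResidualConvUnit(4, 4))
    x = np.abs(rng.normal(size=(4, 8, 8))).astype(np.float32)
    np.testing.assert_allclose(rcu_forward(x, rcu), x, atol=1e-7)


def test_rcu_preserves_spatial_dims(rng):
    rcu = ResidualConvUnit(8, 8, dilation=2)
    x = rng.normal(size=(8, 32, 32)).astype(np.float32)
    assert rcu_forward(x, rcu).shape == (8, 32, 32)


def test_rcu_requires_projection_on_channel_change(rng):
    rcu = ResidualConvUnit(3, 6)
    assert not isinstance(rcu.proj, nn.Identity)
    x = rng.normal(size=(3, 8, 8)).astype(np.float32)
    assert rcu_forward(x, rcu).shape == (6, 8, 8)


def test_rcu_first_conv_matches_hand_convolution():
    """With GN bypassed, one path of the RCU is plain 3x3 convolution."""
    rcu = ResidualConvUnit(1, 1, leaky_slope=0.0)
    rcu.gn1 = nn.Identity()
    rcu.gn2 = nn.Identity()
    for p in (rcu.conv2.weight, rcu.conv2.bias, rcu.conv1.bias):
        p.data = np.zeros_like(p.data)
    k = np.arange(9, dtype=np.float32).reshape(1, 1, 3, 3)
    rcu.conv1.weight.data = k
    x = np.zeros((1, 3, 3), dtype=np.float32)
    x[0, 1, 1] = 1.0
    y = rcu_forward(x, rcu)
    # slope 0: ReLU(ReLU(conv(x)) * 0 + x) path collapses; check conv alone
    conv = ad.conv2d(nn.Tensor(x[None]), rcu.conv1.weight, rcu.conv1.bias, padding=1).data[0]
    expected = k[0, 0, ::-1, ::-1]  # correlation of a centered impulse flips the kernel
    np.testing.assert_allclose(conv[0], expected, atol=1e-6)
    assert np.all(y >= 0)


# ---------------------------------------------------------------------------
# attention blocks
# ---------------------------------------------------------------------------

def test_cse_zero_weights_halves_input(rng):
    block = _zero_convs(ChannelSqueezeExcite(4))
    x = rng.normal(size=(4, 6, 6)).astype(np.float32)
    from gamsunet.network import cse

    np.testing.assert_allclose(cse(x, block), 0.5 * x, atol=1e-7)


def test_cse_matches_scalar_oracle():
    """C=2 gates reproduce sigma(W2 relu(W1 mean)) computed by hand."""
    block = ChannelSqueezeExcite(2, reduction=1)
    w1 = np.array([[0.5, -0.3], [0.2, 0.7]], dtype=np.float32)
    w2 = np.array([[1.0, 0.4], [-0.6, 0.1]], dtype=np.float32)
    block.fc1.weight.data = w1.reshape(2, 2, 1, 1)
    block.fc2.weight.data = w2.reshape(2, 2, 1, 1)
    block.fc1.bias.data[:] = 0
    block.fc2.bias.data[:] = 0
    x = np.stack([np.full((4, 4), 2.0), np.full((4, 4), -1.0)]).astype(np.float32)
    means = np.array([2.0, -1.0])
    hidden = np.maximum(w1 @ means, 0.0)
    gates = 1.0 / (1.0 + np.exp(-(w2 @ hidden)))
    from gamsunet.network import cse

    out = cse(x, block)
    np.testing.assert_allclose(out[0], 2.0 * gates[0], rtol=1e-5)
    np.testing.assert_allclose(out[1], -1.0 * gates[1], rtol=1e-5)


def test_sse_zero_weights_halves_and_zero_input_stays_zero(rng):
    from gamsunet.network import sse

    block = _zero_convs(SpatialSqueezeExcite(3))
    x = rng.normal(size=(3, 5, 5)).astype(np.float32)
    np.testing.assert_allclose(sse(x, block), 0.5 * x, atol=1e-7)
    np.testing.assert_allclose(sse(np.zeros_like(x), SpatialSqueezeExcite(3)), 0.0)


def test_sse_elementwise_oracle():
    block = SpatialSqueezeExcite(1)
    block.fc.weight.data = np.ones((1, 1, 1, 1), dtype=np.float32)
    block.fc.bias.data[:] = 0
    x = np.array([[[0.5, -1.0], [2.0, 0.0]]], dtype=np.float32)
    from gamsunet.network import sse

    expected = x * (1.0 / (1.0 + np.exp(-x)))
    np.testing.assert_allclose(sse(x, block), expected, rtol=1e-6)


def test_scse_zero_init_identity_and_compositionality(rng):
    from gamsunet.network import cse, scse, sse

    block = _zero_convs(SCSEBlock(2))
    x = rng.normal(size=(2, 4, 4)).astype(np.float32)
    np.testing.assert_allclose(scse(x, block), x, atol=1e-7)  # 0.5x + 0.5x

    block2 = SCSEBlock(2)
    y = scse(x, block2)
    np.testing.assert_allclose(y, cse(x, block2.cse) + sse(x, block2.sse), atol=1e-6)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(arrays(np.float32, (2, 4, 4), elements=st.floats(-3, 3, width=32)),
       st.integers(0, 2**31 - 1))
def test_scse_bounded_and_sign_preserving(x, seed):
    """|SCSE(x)| <= 2|x| elementwise with the sign of x preserved."""
    block = SCSEBlock(2, rng=np.random.default_rng(seed))
    from gamsunet.network import scse

    y = scse(x, block)
    assert np.all(np.abs(y) <= 2 * np.abs(x) + 1e-6)
    nz = x != 0
    assert np.all(np.sign(y[nz]) == np.sign(x[nz]))


def test_msblock_is_scse_of_two_rcus(rng):
    block = MSBlock(4, 4, NetworkConfig(depth=2, widths=(4, 8), gn_groups=4))
    x = rng.normal(size=(4, 8, 8)).astype(np.float32)
    from gamsunet.network import scse

    manual = scse(rcu_forward(rcu_forward(x, block.rcu1), block.rcu2), block.scse)
    np.testing.assert_allclose(msblock_forward(x, block), manual, atol=1e-6)
    assert msblock_forward(x, block).shape == x.shape


def test_msblock_zero_init_identity(rng):
    block = _zero_convs(MSBlock(4, 4, NetworkConfig(depth=2, widths=(4, 8), gn_groups=4)))
    x = np.abs(rng.normal(size=(4, 8, 8))).astype(np.float32)
    np.testing.assert_allclose(msblock_forward(x, block), x, atol=1e-7)


# ---------------------------------------------------------------------------
# gated skips
# ---------------------------------------------------------------------------

def test_gated_skip_alpha_zero_is_equal_blend(rng):
    gate = GatedSkip(2, 2)
    gate.proj.weight.data = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1)
    gate.proj.bias.data[:] = 0
    xs = rng.normal(size=(2, 4, 4)).astype(np.float32)
    xu = rng.normal(size=(2, 4, 4)).astype(np.float32)
    np.testing.assert_allclose(gated_skip(xs, xu, gate), 0.5 * xs + 0.5 * xu, atol=1e-6)


def test_gated_skip_saturates_to_skip(rng):
    gate = GatedSkip(2, 2)
    gate.alpha.data[:] = 20.0
    xs = rng.normal(size=(2, 4, 4)).astype(np.float32)
    xu = rng.normal(size=(2, 4, 4)).astype(np.float32)
    np.testing.assert_allclose(gated_skip(xs, xu, gate), xs, atol=1e-6)


def test_gated_skip_scalar_arithmetic():
    gate = GatedSkip(1, 1)
    gate.alpha.data[:] = math.log(3.0)  # sigma = 0.75
    gate.proj.weight.data = np.ones((1, 1, 1, 1), dtype=np.float32)
    gate.proj.bias.data[:] = 0
    xs = np.full((1, 2, 2), 4.0, dtype=np.float32)
    xu = np.full((1, 2, 2), -2.0, dtype=np.float32)
    np.testing.assert_allclose(gated_skip(xs, xu, gate), 0.75 * 4.0 + 0.25 * -2.0, rtol=1e-5)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.floats(-8, 8), st.floats(-5, 5), st.floats(-5, 5))
def test_gated_skip_is_convex_combination(alpha, a, b):
    gate = GatedSkip(1, 1)
    gate.alpha.data[:] = alpha
    gate.proj.weight.data = np.ones((1, 1, 1, 1), dtype=np.float32)
    gate.proj.bias.data[:] = 0
    y = gated_skip(np.full((1, 2, 2), a, np.float32), np.full((1, 2, 2), b, np.float32), gate)
    lo, hi = min(a, b), max(a, b)
    assert np.all(y >= lo - 1e-4) and np.all(y <= hi + 1e-4)


def test_gated_skip_spatial_mismatch_raises(rng):
    gate = GatedSkip(2, 2)
    with pytest.raises(ValueError, match="spatial"):
        gated_skip(np.zeros((2, 8, 8), np.float32), np.zeros((2, 3, 3), np.float32), gate)


# ---------------------------------------------------------------------------
# assembled networks
# ---------------------------------------------------------------------------

def test_forward_shape_range_and_determinism(tiny_config):
    net = GAMSUNetPP(tiny_config, seed=5)
    x = np.random.default_rng(0).normal(size=(32, 32)).astype(np.float32)
    y1 = forward(net, x)
    y2 = forward(net, x)
    assert y1.shape == (32, 32)
    assert np.all((y1 > 0) & (y1 < 1))
    np.testing.assert_array_equal(y1, y2)


def test_forward_rejects_indivisible_dims():
    net = GAMSUNetPP(NetworkConfig(), seed=0)
    with pytest.raises(ValueError, match="divisible"):
        forward(net, np.zeros((250, 250), np.float32))


def test_network_gradients_are_finite(tiny_config, rng):
    net = GAMSUNetPP(tiny_config, seed=3)
    x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
    t = (rng.random((1, 1, 16, 16)) > 0.5).astype(np.float32)
    loss = ad.bce_with_logits(net.forward_logits(nn.Tensor(x)), t)
    loss.backward()
    for p in net.parameters():
        assert p.grad is not None and np.all(np.isfinite(p.grad))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(depth=1, widths=(8,))
    with pytest.raises(ValueError):
        NetworkConfig(depth=3, widths=(8, 8, 16))
    with pytest.raises(ValueError):
        NetworkConfig(depth=2, widths=(8, 16), dilation_second_conv=0)


def _enumerate_tiny_params(cfg: NetworkConfig) -> int:
    """Independent shape-by-shape enumeration for the depth-2 network."""
    w0, w1 = cfg.widths

    def conv(cin, cout, k):
        return k * k * cin * cout + cout

    def rcu(cin, cout):
        p = conv(cin, cout, 3) + conv(cout, cout, 3) + 4 * cout  # convs + 2 GN pairs
        if cin != cout:
            p += conv(cin, cout, 1)
        return p

    def msblock(cin, cout):
        hid = max(1, cout // cfg.scse_reduction)
        scse = conv(cout, hid, 1) + conv(hid, cout, 1) + conv(cout, 1, 1)
        return rcu(cin, cout) + rcu(cout, cout) + scse

    total = msblock(cfg.in_channels, w0) + msblock(w0, w1)  # encoder
    total += w0 + conv(w1, w0, 1)  # gate alpha + projection
    total += msblock(w0, w0)  # decoder column
    total += conv(w0, cfg.out_channels, 1)  # head
    return total


def test_count_parameters_matches_hand_enumeration(tiny_config):
    net = GAMSUNetPP(tiny_config, seed=0)
    assert count_parameters(net) == _enumerate_tiny_params(tiny_config)


def test_count_parameters_single_conv():
    conv = nn.Conv2d(1, 2, 3)
    assert sum(p.data.size for p in conv.parameters()) == 3 * 3 * 1 * 2 + 2


def test_count_flops_closed_form_and_scaling(tiny_config):
    # one 1x1 conv, 1->1 channel, on a 1x1 input: exactly 1 MAC
    conv = nn.Conv2d(1, 1, 1, bias=False)
    meter = nn.FlopMeter()
    with nn.count_flops_in(meter):
        conv(nn.Tensor(np.zeros((1, 1, 1, 1), np.float32)))
    assert meter.macs == 1.0

    net = GAMSUNetPP(tiny_config, seed=0)
    f32 = count_flops(net, (1, 32, 32))
    f16 = count_flops(net, (1, 16, 16))
    assert f32 / f16 == pytest.approx(4.0, rel=0.05)
    assert count_flops(net, (1, 32, 32), convention="flop") > f32


def test_parameter_count_independent_of_input_size(tiny_config):
    net = GAMSUNetPP(tiny_config, seed=0)
    before = count_parameters(net)
    net.forward_logits(np.zeros((1, 1, 16, 16), np.float32))
    net.forward_logits(np.zeros((1, 1, 32, 32), np.float32))
    assert count_parameters(net) == before


def test_nested_unet_forward_contract():
    nu = NestedUNet(widths=(4, 8), seed=0)
    y = nu.forward(np.zeros((16, 16), np.float32)).data
    assert y.shape == (1, 1, 16, 16)
    assert np.all((y > 0) & (y < 1))


# ---------------------------------------------------------------------------
# straight-line oracle
# ---------------------------------------------------------------------------

def _ref_conv(x, w, b, pad, dil=1):
    co, ci, kh, kw = w.shape
    h, wd = x.shape[1:]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((co, h, wd))
    for o in range(co):
        for i in range(ci):
            for p in range(kh):
                for q in range(kw):
                    out[o] += w[o, i, p, q] * xp[i, p * dil:p * dil + h, q * dil:q * dil + wd]
        out[o] += b[o]
    return out


def _ref_gn(x, gamma, beta, groups, eps=1e-5):
    c = x.shape[0]
    xg = x.reshape(groups, -1)
    mu = xg.mean(axis=1, keepdims=True)
    var = xg.var(axis=1, keepdims=True)
    xhat = ((xg - mu) / np.sqrt(var + eps)).reshape(x.shape)
    return xhat * gamma.reshape(c, 1, 1) + beta.reshape(c, 1, 1)


def _ref_lrelu(x, s=0.01):
    return np.where(x > 0, x, s * x)


def _ref_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _ref_rcu(x, rcu):
    h = _ref_lrelu(_ref_gn(_ref_conv(x, rcu.conv1.weight.data, rcu.conv1.bias.data, 1),
                           rcu.gn1.gamma.data, rcu.gn1.beta.data, rcu.gn1.num_groups))
    h = _ref_gn(_ref_conv(h, rcu.conv2.weight.data, rcu.conv2.bias.data,
                          rcu.conv2.padding, rcu.conv2.dilation),
                rcu.gn2.gamma.data, rcu.gn2.beta.data, rcu.gn2.num_groups)
    shortcut = x if isinstance(rcu.proj, nn.Identity) else _ref_conv(
        x, rcu.proj.weight.data, rcu.proj.bias.data, 0)
    return _ref_lrelu(h + shortcut)


def _ref_msblock(x, blk):
    h = _ref_rcu(_ref_rcu(x, blk.rcu1), blk.rcu2)
    mean = h.mean(axis=(1, 2))
    hid = np.maximum(blk.scse.cse.fc1.weight.data[:, :, 0, 0] @ mean
                     + blk.scse.cse.fc1.bias.data, 0)
    gates = _ref_sigmoid(blk.scse.cse.fc2.weight.data[:, :, 0, 0] @ hid
                         + blk.scse.cse.fc2.bias.data)
    cse_out = h * gates[:, None, None]
    smap = _ref_sigmoid(_ref_conv(h, blk.scse.sse.fc.weight.data, blk.scse.sse.fc.bias.data, 0))
    return cse_out + h * smap[0]


def _ref_pool(x):
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).max(axis=(2, 4))


def _ref_up2(x):
    c, h, w = x.shape
    out = np.zeros((c, 2 * h, 2 * w))
    for i in range(2 * h):
        si = (i + 0.5) / 2 - 0.5
        i0 = int(np.floor(si))
        fi = si - i0
        i0c, i1c = np.clip([i0, i0 + 1], 0, h - 1)
        for j in range(2 * w):
            sj = (j + 0.5) / 2 - 0.5
            j0 = int(np.floor(sj))
            fj = sj - j0
            j0c, j1c = np.clip([j0, j0 + 1], 0, w - 1)
            out[:, i, j] = ((1 - fi) * (1 - fj) * x[:, i0c, j0c]
                            + (1 - fi) * fj * x[:, i0c, j1c]
                            + fi * (1 - fj) * x[:, i1c, j0c]
                            + fi * fj * x[:, i1c, j1c])
    return out


def test_depth2_forward_matches_straight_line_reimplementation(tiny_config, rng):
    """Abstraction-free float64 replay of the whole depth-2 forward pass."""
    net = GAMSUNetPP(tiny_config, seed=9)
    x = rng.normal(size=(16, 16)).astype(np.float32)

    x00 = _ref_msblock(x[None].astype(np.float64), net.encoder[0][0])
    x10 = _ref_msblock(_ref_pool(x00), net.encoder[1][0])
    gate = net.gates[0][0]
    proj = _ref_conv(x10, gate.proj.weight.data, gate.proj.bias.data, 0)
    g = _ref_sigmoid(gate.alpha.data)[:, None, None]
    blended = g * x00 + (1 - g) * _ref_up2(proj)
    x01 = _ref_msblock(blended, net.decoder[0][0])
    logits = _ref_conv(x01, net.head.weight.data, net.head.bias.data, 0)
    expected = _ref_sigmoid(logits)[0]

    np.testing.assert_allclose(forward(net, x), expected, atol=1e-5)
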