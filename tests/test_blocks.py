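"""Block semantics: attention, activations, shuffles, and the closed-form
parameter arithmetic of every stage type."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pflyolo import autodiff as ad
from pflyolo import blocks as B
from pflyolo.autodiff import Tensor


# ---------------------------------------------------------------------------
# ECA
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("channels,expected", [(64, 3), (256, 5), (16, 3),
                                               (128, 5), (32, 3), (48, 3)])
def test_eca_kernel_size_adaptive_rule(channels, expected):
    assert B.eca_kernel_size(channels) == expected


def test_eca_kernel_size_rejects_nonpositive():
    with pytest.raises(ValueError):
        B.eca_kernel_size(0)


def test_eca_preserves_shape_and_weight_range(rng):
    eca = B.ECA(8, rng=rng)
    x = Tensor(rng.standard_normal((1, 8, 4, 4)))
    y = eca(x)
    assert y.shape == (1, 8, 4, 4)
    w = eca.attention_weights(x).data
    assert np.all((w > 0) & (w < 1))


def test_eca_identical_channels_get_identical_weights(rng):
    """Symmetry: channel-constant input produces equal gates for every
    channel whose 1-D window does not touch the zero padding."""
    eca = B.ECA(8, rng=rng)
    plane = rng.standard_normal((1, 1, 5, 5))
    x = Tensor(np.repeat(plane, 8, axis=1))
    w = eca.attention_weights(x).data
    p = eca.k // 2
    interior = w[0, p:8 - p]
    assert np.allclose(interior, interior[0])


def test_eca_unit_weights_leave_input_unchanged(rng):
    """If every gate is 1 the rescaling is the identity."""
    x = Tensor(rng.standard_normal((2, 4, 3, 3)))
    ones = Tensor(np.ones((2, 4, 1, 1), np.float32))
    assert np.array_equal(ad.mul(x, ones).data, x.data)


def test_eca_matches_hand_computed_pipeline(rng):
    """Brute-force oracle: GAP -> 1-D conv -> sigmoid -> rescale."""
    eca = B.ECA(4, rng=rng)
    x = rng.standard_normal((1, 4, 2, 2)).astype(np.float32)
    k = eca.weight.data
    gap = x.mean(axis=(2, 3))[0]
    padded = np.pad(gap, eca.k // 2)
    conv = np.array([padded[i:i + eca.k] @ k for i in range(4)])
    gates = 1 / (1 + np.exp(-conv))
    expected = x * gates[None, :, None, None]
    got = eca(Tensor(x)).data
    assert np.allclose(got, expected, atol=1e-6)


def test_eca_rejects_channel_mismatch(rng):
    with pytest.raises(ValueError):
        B.ECA(8, rng=rng).attention_weights(Tensor(np.zeros((1, 4, 2, 2))))


# ---------------------------------------------------------------------------
# Hardswish
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (3.0, 3.0), (1.0, 2 / 3),
                                        (0.0, 0.0), (-5.0, 0.0), (7.0, 7.0)])
def test_hardswish_branches(x, expected):
    assert B.hardswish_scalar(x) == pytest.approx(expected)
    assert float(ad.hardswish(Tensor(np.float32(x))).data) == pytest.approx(expected, abs=1e-6)


@given(st.floats(-10, 10))
@settings(deadline=None, max_examples=200)
def test_hardswish_continuous_and_piecewise_consistent(x):
    v = B.hardswish_scalar(x)
    if x <= -3:
        assert v == 0.0
    elif x >= 3:
        assert v == x
    else:
        assert v == pytest.approx(x * (x + 3) / 6)


def test_hardswish_continuity_at_knots():
    eps = 1e-7
    assert B.hardswish_scalar(-3 - eps) == pytest.approx(B.hardswish_scalar(-3 + eps), abs=1e-6)
    assert B.hardswish_scalar(3 - eps) == pytest.approx(B.hardswish_scalar(3 + eps), abs=1e-6)


@given(st.floats(-1.5, 20), st.floats(0, 1))
@settings(deadline=None, max_examples=200)
def test_hardswish_monotone_beyond_minimum(x, delta):
    """Hardswish decreases on (-3, -1.5) and is non-decreasing from its
    minimum at x = -1.5 (derivative (2x+3)/6 >= 0 there)."""
    assert B.hardswish_scalar(x + delta) >= B.hardswish_scalar(x) - 1e-12


def test_hardswish_minimum_location():
    assert B.hardswish_scalar(-1.5) == pytest.approx(-0.375)
    assert B.hardswish_scalar(-1.4) > -0.375 and B.hardswish_scalar(-1.6) > -0.375


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------

def test_channel_shuffle_reshape_transpose_oracle(rng):
    x = np.zeros((1, 4, 2, 2), np.float32)
    for c in range(4):
        x[0, c] = c
    y = B.channel_shuffle(Tensor(x), 2).data
    assert [int(y[0, c, 0, 0]) for c in range(4)] == [0, 2, 1, 3]


@pytest.mark.parametrize("groups", [1, 8])
def test_channel_shuffle_identity_cases(rng, groups):
    x = Tensor(rng.standard_normal((2, 8, 3, 3)))
    assert np.array_equal(B.channel_shuffle(x, groups).data, x.data)


@given(st.sampled_from([(12, 2), (12, 3), (12, 4), (24, 6), (8, 2)]))
@settings(deadline=None, max_examples=20)
def test_channel_shuffle_roundtrip_and_plane_preservation(cg):
    c, g = cg
    rng = np.random.default_rng(c * 31 + g)
    x = rng.standard_normal((1, c, 2, 3)).astype(np.float32)
    y = B.channel_shuffle(Tensor(x), g).data
    # inverse permutation restores the input
    z = B.channel_shuffle(Tensor(y), c // g).data
    assert np.array_equal(z, x)
    # multiset of channel planes preserved
    perm = B.shuffle_permutation(c, g)
    assert np.array_equal(y, x[:, perm])


def test_channel_shuffle_rejects_non_divisor(rng):
    with pytest.raises(ValueError):
        B.channel_shuffle(Tensor(np.zeros((1, 6, 2, 2))), 4)


# ---------------------------------------------------------------------------
# conv blocks and parameter arithmetic
# ---------------------------------------------------------------------------

def test_conv_block_stride_arithmetic(rng):
    conv = B.ConvBlock(3, 16, 3, 2, rng=rng)
    y = conv(Tensor(rng.standard_normal((1, 3, 64, 64))))
    assert y.shape == (1, 16, 32, 32)


@pytest.mark.parametrize("g,expected", [(1, 18560), (4, 4736)])
def test_grouped_conv_param_count(rng, g, expected):
    conv = B.ConvBlock(32, 64, 3, 2, g, rng=rng)
    assert conv.param_count() == expected
    assert conv.num_params() == expected


def test_ehconv_param_count_includes_eca(rng):
    eh = B.EHConv(32, 64, 3, 2, g=4, rng=rng)
    assert eh.param_count() == 4736 + 3  # grouped conv + bn + eca kernel
    assert eh.num_params() == eh.param_count()


def test_ehconv_gradient_reaches_every_parameter(rng):
    """Autodiff oracle: all trainable values receive nonzero gradients."""
    eh = B.EHConv(8, 16, 3, 2, g=4, rng=rng)
    x = Tensor(rng.standard_normal((2, 8, 8, 8)))
    out = eh(x)
    ad.sum_(ad.mul(out, out)).backward()
    for name, p in eh.named_parameters():
        assert p.grad is not None, name
        assert np.abs(p.grad).max() > 0, name


def test_ehconv_degenerates_to_conv_block(rng):
    """g=1, ECA forced open, SiLU->identity: EHConv(BN last) == Conv+BN."""
    eh = B.EHConv(4, 8, 3, 2, g=1, rng=np.random.default_rng(3))
    ref = B.ConvBlock(4, 8, 3, 2, 1, act="none", rng=np.random.default_rng(99))
    ref.weight.data = eh.conv.weight.data.copy()
    ref.gamma.data = eh.gamma.data.copy()
    ref.beta.data = eh.beta.data.copy()
    x = Tensor(np.random.default_rng(5).standard_normal((1, 4, 8, 8)))
    raw = eh.conv(x)
    gated = ad.batch_norm2d(raw, eh.gamma, eh.beta, np.zeros(8, np.float32),
                            np.ones(8, np.float32), training=True)
    expected = ref(Tensor(x.data))
    assert np.allclose(gated.data, expected.data, atol=1e-5)


# ---------------------------------------------------------------------------
# pyramid blocks
# ---------------------------------------------------------------------------

def test_sppf_preserves_spatial_size(rng):
    sppf = B.SPPF(16, 16, rng=rng)
    y = sppf(Tensor(rng.standard_normal((1, 16, 7, 7))))
    assert y.shape == (1, 16, 7, 7)


def test_esppf_shape_and_lighter_than_sppf(rng):
    esppf = B.ESPPF(16, 16, rng=rng)
    y = esppf(Tensor(rng.standard_normal((1, 16, 5, 5))))
    assert y.shape == (1, 16, 5, 5)
    assert esppf.param_count() < B.SPPF(16, 16, rng=rng).param_count()
    assert esppf.num_params() == esppf.param_count()


def test_esppf_calibrated_groups_param_count(rng):
    esppf = B.ESPPF(256, 256, rng=rng)
    assert esppf.cv1.g == 32 and esppf.cv2.g == 64
    assert esppf.param_count() == 3845


def test_c2f_shape_and_count(rng):
    c2f = B.C2f(32, 32, n=1, shortcut=True, rng=rng)
    y = c2f(Tensor(rng.standard_normal((1, 32, 6, 6))))
    assert y.shape == (1, 32, 6, 6)
    assert c2f.param_count() == 7360 == c2f.num_params()


# ---------------------------------------------------------------------------
# RC2f
# ---------------------------------------------------------------------------

def test_rc2f_output_shape(rng):
    rc = B.RC2f(32, 32, rng=rng)
    y = rc(Tensor(rng.standard_normal((2, 32, 5, 5))))
    assert y.shape == (2, 32, 5, 5)


def test_rc2f_rejects_indivisible_width():
    with pytest.raises(ValueError):
        B.RC2f(8, 8)  # hidden 6 -> not divisible into 4 groups


def test_rc2f_ladder_wiring(rng):
    """With every ladder transform zeroed, the output depends on x1 only:
    groups 2-4 of the stem output contribute nothing."""
    rc = B.RC2f(32, 32, rng=rng)
    for t in rc.ladder:
        t.weight.data[:] = 0
        t.gamma.data[:] = 0  # zero the BN too: Ti == 0 mapping
    x = Tensor(rng.standard_normal((1, 32, 4, 4)))
    y1 = rc(x).data
    # perturb the stem weights feeding groups 2-4 only
    q = rc.q
    rc.stem2.weight.data[q:] += 1.0
    y2 = rc(x).data
    assert np.allclose(y1, y2, atol=1e-5)


def test_rc2f_param_count_matches_introspection(rng):
    rc = B.RC2f(256, 256, rng=rng)
    assert rc.param_count() == rc.num_params()


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------

def test_detect_output_channels_and_grids(rng):
    d = B.Detect(60, (8, 16, 32), rng=rng)
    maps = [Tensor(rng.standard_normal((1, c, s, s))) for c, s in
            ((8, 8), (16, 4), (32, 2))]
    outs = d(maps)
    assert [o.shape for o in outs] == [(1, 124, 8, 8), (1, 124, 4, 4), (1, 124, 2, 2)]


def test_detect_rejects_wrong_scale_count(rng):
    d = B.Detect(4, (8, 16, 32), rng=rng)
    with pytest.raises(ValueError):
        d([Tensor(np.zeros((1, 8, 4, 4)))])


def test_pfdetect_channels_and_calibrated_count(rng):
    pf = B.PFDetect(60, rng=rng)
    assert pf.no == 124
    assert pf.param_count() == 59999
    assert pf.num_params() == 59999
    maps = [Tensor(rng.standard_normal((1, c, s, s))) for c, s in
            ((64, 8), (128, 4), (256, 2))]
    outs = pf(maps)
    assert [o.shape[1] for o in outs] == [124, 124, 124]


def test_dfl_expectation_bounds(rng):
    logits = Tensor(rng.standard_normal((1, 64, 5)))
    d = B.dfl_expectation(logits).data
    assert d.shape == (1, 4, 5)
    assert np.all((d >= 0) & (d <= B.REG_MAX - 1))


@pytest.mark.parametrize("block_factory,cin", [
    (lambda rng: B.ConvBlock(8, 16, 3, 1, 2, rng=rng), 8),
    (lambda rng: B.EHConv(8, 16, 3, 1, 4, rng=rng), 8),
    (lambda rng: B.C2f(16, 16, 2, True, rng=rng), 16),
    (lambda rng: B.RC2f(32, 16, rng=rng), 32),
    (lambda rng: B.SPPF(16, 16, rng=rng), 16),
    (lambda rng: B.ESPPF(16, 16, rng=rng), 16),
])
def test_stride1_blocks_preserve_batch_and_space(rng, block_factory, cin):
    blk = block_factory(rng)
    y = blk(Tensor(rng.standard_normal((3, cin, 6, 6))))
    assert y.shape[0] == 3 and y.shape[2:] == (6, 6)
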