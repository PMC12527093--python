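"""Architecture contracts: shapes, parameter accounting, attention semantics."""

import numpy as np
import pytest

import _naive
from lmcsleepnet import nn
from lmcsleepnet.model import (CBAM, BasicBlock, ChannelAttention, DSCConv,
                               LMCSleepNet, ModelConfig, MSDCStem, Prediction,
                               SpatialAttention, count_parameters, describe,
                               parameter_breakdown)

REDUCED = dict(stage_widths=(16, 32, 64, 128), stem_branch_channels=16,
               stem_fused_channels=16)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


def test_pinned_parameter_count():
    """The fully pinned network has exactly 1,492,840 trainable scalars."""
    net = LMCSleepNet(ModelConfig())
    assert count_parameters(net) == 1_492_840


def test_no_msdc_parameter_count():
    """Swapping the MSDC stem for a 7x7 stem gives 1,484,392 parameters."""
    assert count_parameters(LMCSleepNet(ModelConfig(use_msdc=False))) == 1_484_392


def test_imagenet_resnet18_baseline_count():
    """All ablation flags off with a 1000-way head reproduces standard ResNet18."""
    cfg = ModelConfig.for_variant("resnet18", num_classes=1000)
    assert count_parameters(LMCSleepNet(cfg)) == 11_689_512


def test_description_decomposes_and_sums():
    net = LMCSleepNet(ModelConfig())
    desc = describe(net)
    assert desc.total_parameters == count_parameters(net)
    groups = parameter_breakdown(net)
    assert sum(groups.values()) == desc.total_parameters
    # FC head: 512*5 + 5; CBAM: bottleneck MLP 2*512*32 + spatial 7x7x2+1
    assert groups["head"] == 512 * 5 + 5 == 2565
    assert groups["cbam"] == 2 * 512 * 32 + (7 * 7 * 2 + 1)
    # toggling one flag changes only that component's count
    no_cbam = parameter_breakdown(LMCSleepNet(ModelConfig(use_cbam=False)))
    assert no_cbam["cbam"] == 0
    assert no_cbam["body"] == groups["body"] and no_cbam["head"] == groups["head"]


def test_dsc_conv_weight_counts():
    """64->64 DSC: 9*64 depthwise + 64*64 pointwise = 4,672 weights
    (vs 36,864 for a dense 3x3), excluding batch-norm."""
    conv = DSCConv(64, 64)
    n_w = conv.depthwise.weight.size + conv.pointwise.weight.size
    assert n_w == 9 * 64 + 64 * 64 == 4672
    dense = nn.Conv2d(64, 64, 3, padding=1)
    assert dense.weight.size == 36_864


def test_batchnorm_parameter_count():
    assert sum(p.size for p in nn.BatchNorm2d(64).parameters()) == 128


def test_msdc_add_fusion_drops_fusion_conv():
    concat = LMCSleepNet(ModelConfig())
    add = LMCSleepNet(ModelConfig(msdc_fusion="add"))
    diff = count_parameters(concat) - count_parameters(add)
    assert diff == 192 * 64 + 2 * 64  # 1x1 fusion conv weights + its BN


# ---------------------------------------------------------------------------
# forward semantics
# ---------------------------------------------------------------------------


def test_msdc_stem_shapes_and_linearity(rng):
    stem = MSDCStem(3, 64, 64, (1, 2, 3), "concat", rng)
    x = rng.normal(size=(2, 3, 200, 32)).astype(np.float32)
    out = stem(x)
    assert out.shape == (2, 64, 100, 16)
    # bias-free convs + zero-shifted batch-norm: zero input -> zero output
    zero = stem(np.zeros_like(x))
    np.testing.assert_allclose(zero, 0.0, atol=1e-7)
    with pytest.raises(ValueError):
        stem(np.zeros((1, 3, 5, 5), dtype=np.float32))


def test_dsc_identity_factorisation(rng):
    """Centered-delta depthwise kernels + identity pointwise = identity map."""
    conv = DSCConv(4, 4, rng=rng)
    conv.depthwise.weight.data[...] = 0
    conv.depthwise.weight.data[:, 1, 1] = 1.0
    conv.pointwise.weight.data[...] = np.eye(4, dtype=np.float32)[:, :, None, None]
    conv.eval()  # running stats are identity at init
    x = rng.normal(size=(2, 4, 6, 6)).astype(np.float32)
    np.testing.assert_allclose(conv(x), x, atol=1e-4)


def test_residual_block_identity_and_stride(rng):
    block = BasicBlock(16, 16, stride=1, use_dsc=True, rng=rng)
    for _, p in block.branch.named_parameters():
        p.data[...] = 0
    block.eval()
    x = np.abs(rng.normal(size=(2, 16, 8, 8))).astype(np.float32)
    np.testing.assert_allclose(block(x), x, atol=1e-5)  # ReLU(0 + x) = x

    down = BasicBlock(64, 128, stride=2, use_dsc=True, rng=rng)
    y = down(rng.normal(size=(2, 64, 50, 8)).astype(np.float32))
    assert y.shape == (2, 128, 25, 4)


def test_residual_gradient_flows_through_shortcut(rng):
    block = BasicBlock(8, 8, stride=1, use_dsc=True, rng=rng)
    for _, p in block.branch.named_parameters():
        p.data[...] = 0
    x = np.abs(rng.normal(size=(2, 8, 6, 6))).astype(np.float32)
    block(x)
    dx = block.backward(np.ones((2, 8, 6, 6), dtype=np.float32))
    assert np.abs(dx).max() > 0.5  # identity path carries gradient


def test_channel_attention_matches_direct_evaluation(rng):
    ca = ChannelAttention(8, 4, rng)
    x = rng.normal(size=(3, 8, 5, 5)).astype(np.float32)
    got = ca(x)
    want = _naive.channel_attention(x, ca.w1.data.astype(np.float64),
                                    ca.w2.data.astype(np.float64))
    np.testing.assert_allclose(got, want, atol=1e-5)
    assert got.shape == x.shape

    # zero input: sigmoid(0) = 0.5 gates, output still zero
    np.testing.assert_array_equal(ca(np.zeros_like(x)), np.zeros_like(x))

    # constant-per-channel input: avg pool == max pool, gate = sigmoid(2*MLP(v))
    const = np.ones((1, 8, 4, 4), dtype=np.float32) * \
        rng.normal(size=(1, 8, 1, 1)).astype(np.float32)
    v = const[0, :, 0, 0]
    mlp = ca.w2.data @ np.maximum(ca.w1.data @ v, 0)
    gate = 1 / (1 + np.exp(-2 * mlp))
    np.testing.assert_allclose(ca(const)[0, :, 0, 0], v * gate, atol=1e-5)


def test_spatial_attention_matches_direct_evaluation(rng):
    sa = SpatialAttention(7, rng)
    x = rng.normal(size=(2, 6, 7, 5)).astype(np.float32)
    got = sa(x)
    want = _naive.spatial_attention(x, sa.conv.weight.data.astype(np.float64),
                                    sa.conv.bias.data.astype(np.float64))
    np.testing.assert_allclose(got, want, atol=1e-5)

    # single channel: mean map == max map == the channel itself
    x1 = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
    sa1 = SpatialAttention(3, rng)
    out = sa1(x1)
    assert out.shape == x1.shape


def test_cbam_is_sequential_composition(rng):
    cbam = CBAM(4, 2, 3, rng)
    x = rng.normal(size=(2, 4, 2, 2)).astype(np.float32)
    got = cbam(x)
    ca, sa = cbam.layers
    step1 = _naive.channel_attention(x, ca.w1.data.astype(np.float64),
                                     ca.w2.data.astype(np.float64))
    want = _naive.spatial_attention(step1.astype(np.float32),
                                    sa.conv.weight.data.astype(np.float64),
                                    sa.conv.bias.data.astype(np.float64))
    np.testing.assert_allclose(got, want, atol=1e-5)
    assert got.shape == x.shape
    np.testing.assert_array_equal(cbam(np.zeros_like(x)), np.zeros_like(x))


def test_attention_gradients_match_finite_differences(rng):
    from test_nn import numerical_grad

    x = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
    cbam = CBAM(4, 2, 3, rng)
    proj = rng.normal(size=x.shape).astype(np.float32)

    def loss():
        return float((cbam(x) * proj).sum())

    loss()
    dx = cbam.backward(proj)
    np.testing.assert_allclose(dx, numerical_grad(loss, x), atol=2e-2, rtol=2e-2)


# ---------------------------------------------------------------------------
# head and whole-network contracts
# ---------------------------------------------------------------------------


def test_classify_softmax_values():
    net = LMCSleepNet(ModelConfig(**REDUCED))
    net.fc.weight.data[...] = 0
    net.fc.bias.data[...] = 0
    pred = net.classify(np.zeros(128, dtype=np.float32))
    np.testing.assert_allclose(pred.probabilities, 0.2, atol=1e-7)

    net.fc.bias.data[...] = np.array([1, 0, 0, 0, 0], dtype=np.float32)
    pred = net.classify(np.zeros(128, dtype=np.float32))
    np.testing.assert_allclose(
        pred.probabilities,
        [0.4046, 0.1488, 0.1488, 0.1488, 0.1488], atol=1e-4)
    assert pred.label == 0
    assert isinstance(pred, Prediction)


@pytest.mark.parametrize("t,s", [(200, 32), (64, 32), (32, 48)])
def test_shape_contract_any_input_reaches_512_features(t, s, rng):
    net = LMCSleepNet(ModelConfig())
    x = rng.normal(size=(1, 3, t, s)).astype(np.float32)
    feats = net.features(x)
    assert feats.shape == (1, 512)
    probs = net.predict_proba(x)
    np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-6)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(dilations=(2, 1)).validate()
    with pytest.raises(ValueError):
        ModelConfig(cbam_reduction=7).validate()
    with pytest.raises(ValueError):
        ModelConfig(msdc_fusion="mul").validate()
    with pytest.raises(ValueError):
        ModelConfig.for_variant("nope")
    with pytest.raises(ValueError):
        LMCSleepNet(ModelConfig()).forward(np.full((1, 3, 64, 32), np.nan))
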