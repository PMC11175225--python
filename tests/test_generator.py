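"""Generator architecture: wiring oracles, residual identities, budgets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import correlate2d

from conftest import zero_parameters
from rdagan.errors import ConfigurationError, InvalidStateError
from rdagan.generator import (GeneratorSpec, RDAGANGenerator,
                              calibrate_growth_rate, count_parameters,
                              dense_feature_fusion, expected_parameter_count,
                              generator_forward, parameter_millions,
                              rdab_forward, rdb_dense_forward, shallow_extract,
                              upsample_reconstruct)
from rdagan.image import FeatureStack, InvalidInputError, RasterImage
from rdagan.nn.tensor import Tensor


def random_image(rng, h, w):
    return RasterImage(rng.random((h, w, 3), dtype=np.float32))


# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------

def test_spec_serialization_round_trip_is_identity():
    spec = GeneratorSpec(num_blocks=5, growth_rate=20, cbam_enabled=False)
    assert GeneratorSpec.from_json(spec.to_json()) == spec


def test_spec_rejects_invalid_configurations():
    with pytest.raises(ConfigurationError):
        GeneratorSpec(scale=3)          # not a power of two
    with pytest.raises(ConfigurationError):
        GeneratorSpec(num_blocks=0)
    with pytest.raises(ConfigurationError):
        GeneratorSpec(kernel_size=4)
    with pytest.raises(ConfigurationError):
        GeneratorSpec(cbam_position="sideways")


def test_default_spec_is_the_published_architecture():
    spec = GeneratorSpec()
    assert spec.num_blocks == 16
    assert spec.scale == 2


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def test_single_conv_parameter_count_closed_form(rng):
    from rdagan.nn import Conv2d
    conv = Conv2d(3, 64, 3, rng)
    assert count_parameters(conv) == 3 * 3 * 3 * 64 + 64 == 1792


def test_expected_count_matches_instantiated_module(tiny_spec):
    gen = RDAGANGenerator(tiny_spec, np.random.default_rng(0))
    assert count_parameters(gen) == expected_parameter_count(tiny_spec)


@pytest.mark.parametrize("overrides", [
    {"cbam_enabled": False},
    {"use_rdb": False},
    {"second_shallow_conv": True},
    {"scale": 4},
])
def test_expected_count_matches_across_ablations(tiny_spec, overrides):
    spec = tiny_spec.with_(**overrides)
    gen = RDAGANGenerator(spec, np.random.default_rng(0))
    assert count_parameters(gen) == expected_parameter_count(spec)


def test_default_generator_budget_is_calibrated():
    gen = RDAGANGenerator(GeneratorSpec(), np.random.default_rng(0))
    assert parameter_millions(gen) == 11.25
    assert len(gen.blocks) == 16


def test_growth_rate_calibration_recovers_the_default():
    assert calibrate_growth_rate(11.25) == GeneratorSpec().growth_rate


# ---------------------------------------------------------------------------
# shallow extraction
# ---------------------------------------------------------------------------

def test_shallow_extract_dims_and_channels(rng):
    spec = GeneratorSpec(num_blocks=1, convs_per_block=1, growth_rate=4,
                         base_channels=64, cbam_enabled=False,
                         head_kernel_size=3, second_shallow_conv=False)
    gen = RDAGANGenerator(spec, np.random.default_rng(0))
    f0 = shallow_extract(random_image(rng, 96, 96), gen)
    assert f0.channel_count == 64
    assert f0.spatial_dims == (96, 96)


def test_shallow_extract_zero_weights_on_zero_input(tiny_generator):
    zero_parameters(tiny_generator)
    f0 = shallow_extract(RasterImage(np.zeros((5, 5, 3))), tiny_generator)
    assert np.all(f0.values == 0)


def test_shallow_extract_single_pixel_input(tiny_generator, rng):
    f0 = shallow_extract(random_image(rng, 1, 1), tiny_generator)
    assert f0.spatial_dims == (1, 1)


def test_non_three_channel_input_is_rejected():
    with pytest.raises(InvalidInputError):
        RasterImage(np.zeros((4, 4, 2)))


# ---------------------------------------------------------------------------
# dense block wiring
# ---------------------------------------------------------------------------

def naive_dense_block(f_in, block):
    """Independent re-implementation: explicit concatenations, scipy convs."""
    def conv_same(x, w, b):
        cout, cin, k, _ = w.shape
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
        return np.stack([
            b[o] + sum(correlate2d(xp[c], w[o, c], mode="valid")
                       for c in range(cin))
            for o in range(cout)])

    feats = [f_in.astype(np.float64)]
    outputs = []
    for conv in block.convs:
        cat = np.concatenate(feats, axis=0)
        y = np.maximum(conv_same(cat, conv.weight.data.astype(np.float64),
                                 conv.bias.data.astype(np.float64)), 0.0)
        outputs.append(y)
        feats.append(y)
    cat = np.concatenate(feats, axis=0)
    w = block.lff.weight.data.astype(np.float64)[:, :, 0, 0]
    fused = np.einsum("oi,ihw->ohw", w, cat) + \
        block.lff.bias.data.astype(np.float64)[:, None, None]
    return fused, outputs


def test_dense_wiring_matches_naive_oracle_on_many_instances():
    spec = GeneratorSpec(num_blocks=1, convs_per_block=3, growth_rate=4,
                         base_channels=8, cbam_reduction=2,
                         head_kernel_size=3)
    for trial in range(20):
        gen = RDAGANGenerator(spec, np.random.default_rng(trial))
        block = gen.blocks[0]
        f_in = np.random.default_rng(1000 + trial).normal(
            size=(8, 8, 8)).astype(np.float32)
        fused, outputs = rdb_dense_forward(FeatureStack(f_in), block)
        ref_fused, ref_outputs = naive_dense_block(f_in, block.core)
        scale = np.abs(ref_fused).max()
        assert np.abs(fused.values - ref_fused).max() / scale < 1e-5
        for got, ref in zip(outputs, ref_outputs):
            s = max(np.abs(ref).max(), 1e-8)
            assert np.abs(got.values - ref).max() / s < 1e-5


def test_lff_channel_arithmetic():
    spec = GeneratorSpec(convs_per_block=6, growth_rate=32, base_channels=64)
    gen = RDAGANGenerator(spec.with_(num_blocks=1), np.random.default_rng(0))
    lff = gen.blocks[0].core.lff
    assert lff.weight.shape == (64, 64 + 6 * 32, 1, 1)


def test_dense_block_zero_weights_give_zero_fusion(tiny_generator, rng):
    zero_parameters(tiny_generator)
    f_in = FeatureStack(rng.normal(size=(16, 6, 6)).astype(np.float32))
    fused, _ = rdb_dense_forward(f_in, tiny_generator.blocks[0])
    assert np.all(fused.values == 0)


def test_dense_block_rejects_wrong_channel_count(tiny_generator):
    with pytest.raises(InvalidStateError):
        rdb_dense_forward(FeatureStack(np.zeros((5, 4, 4), dtype=np.float32)),
                          tiny_generator.blocks[0])


# ---------------------------------------------------------------------------
# full blocks and fusion
# ---------------------------------------------------------------------------

def test_rdab_zero_weights_is_identity_without_cbam(rng):
    spec = GeneratorSpec(num_blocks=1, convs_per_block=2, growth_rate=4,
                         base_channels=8, cbam_enabled=False,
                         head_kernel_size=3)
    gen = zero_parameters(RDAGANGenerator(spec, np.random.default_rng(0)))
    f = FeatureStack(rng.normal(size=(8, 5, 5)).astype(np.float32))
    out = rdab_forward(f, gen.blocks[0])
    np.testing.assert_array_equal(out.values, f.values)


def test_plain_residual_ablation_block(rng):
    spec = GeneratorSpec(num_blocks=1, use_rdb=False, base_channels=8,
                         cbam_enabled=False, cbam_reduction=2,
                         head_kernel_size=3)
    gen = RDAGANGenerator(spec, np.random.default_rng(0))
    core = gen.blocks[0].core
    assert core.conv1.weight.shape == (8, 8, 3, 3)
    assert core.conv2.weight.shape == (8, 8, 3, 3)
    f = FeatureStack(rng.normal(size=(8, 6, 6)).astype(np.float32))
    out = rdab_forward(f, gen.blocks[0])
    assert out.values.shape == f.values.shape


def test_block_chain_matches_explicit_sequential_application(tiny_generator, rng):
    x = Tensor(rng.random((1, 3, 8, 8), dtype=np.float32))
    f0 = tiny_generator.extract_shallow(x)
    f = f0
    outputs = []
    for block in tiny_generator.blocks:
        f = block(f)
        outputs.append(f)
    manual = tiny_generator.reconstruct(
        tiny_generator.fuse_blocks(f0, outputs))
    np.testing.assert_array_equal(manual.data, tiny_generator(x).data)


def test_global_fusion_channel_arithmetic():
    spec = GeneratorSpec()
    gen = RDAGANGenerator(spec.with_(num_blocks=16), np.random.default_rng(0))
    assert gen.gff1.weight.shape == (64, 16 * 64, 1, 1)


def test_global_residual_identity_with_zero_fusion_weights(tiny_generator, rng):
    zero_parameters(tiny_generator)
    f0 = FeatureStack(rng.normal(size=(16, 6, 6)).astype(np.float32))
    blocks = [FeatureStack(rng.normal(size=(16, 6, 6)).astype(np.float32))
              for _ in range(2)]
    out = dense_feature_fusion(f0, blocks, tiny_generator)
    np.testing.assert_array_equal(out.values, f0.values)


def test_fusion_is_deterministic_and_order_sensitive(tiny_generator, rng):
    f0 = FeatureStack(rng.normal(size=(16, 6, 6)).astype(np.float32))
    blocks = [FeatureStack(rng.normal(size=(16, 6, 6)).astype(np.float32))
              for _ in range(2)]
    a = dense_feature_fusion(f0, blocks, tiny_generator)
    b = dense_feature_fusion(f0, blocks, tiny_generator)
    np.testing.assert_array_equal(a.values, b.values)
    swapped = dense_feature_fusion(f0, blocks[::-1], tiny_generator)
    assert not np.array_equal(a.values, swapped.values)


def test_fusion_rejects_wrong_block_count(tiny_generator):
    f0 = FeatureStack(np.zeros((16, 6, 6), dtype=np.float32))
    with pytest.raises(InvalidStateError):
        dense_feature_fusion(f0, [f0], tiny_generator)


# ---------------------------------------------------------------------------
# reconstruction and end-to-end
# ---------------------------------------------------------------------------

def test_upsample_doubles_spatial_dims(tiny_generator, rng):
    fdf = FeatureStack(rng.normal(size=(16, 9, 11)).astype(np.float32))
    out = upsample_reconstruct(fdf, tiny_generator)
    assert out.shape == (18, 22, 3)


def test_scale_four_uses_two_stages(rng):
    spec = GeneratorSpec(num_blocks=1, convs_per_block=1, growth_rate=4,
                         base_channels=8, cbam_reduction=2, scale=4,
                         head_kernel_size=3)
    gen = RDAGANGenerator(spec, np.random.default_rng(0))
    assert len(gen.up_convs) == 2
    out = generator_forward(RasterImage(rng.random((6, 6, 3),
                                                   dtype=np.float32)), gen)
    assert out.shape == (24, 24, 3)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(h=st.integers(8, 128), w=st.integers(8, 128))
def test_shape_law_output_is_twice_input(h, w):
    spec = GeneratorSpec(num_blocks=1, convs_per_block=1, growth_rate=4,
                         base_channels=8, cbam_reduction=2,
                         head_kernel_size=3)
    gen = RDAGANGenerator(spec, np.random.default_rng(0))
    img = RasterImage(np.random.default_rng(0).random((h, w, 3),
                                                      dtype=np.float32))
    assert generator_forward(img, gen).shape == (2 * h, 2 * w, 3)


def test_forward_is_deterministic(tiny_spec, rng):
    img = random_image(rng, 12, 12)
    g1 = RDAGANGenerator(tiny_spec, np.random.default_rng(3))
    g2 = RDAGANGenerator(tiny_spec, np.random.default_rng(3))
    np.testing.assert_array_equal(generator_forward(img, g1).values,
                                  generator_forward(img, g2).values)


def test_ablated_generator_still_satisfies_shape_contract(rng):
    spec = GeneratorSpec(num_blocks=2, convs_per_block=2, growth_rate=4,
                         base_channels=8, cbam_enabled=False, use_rdb=False,
                         head_kernel_size=3)
    gen = RDAGANGenerator(spec, np.random.default_rng(0))
    out = generator_forward(random_image(rng, 10, 14), gen)
    assert out.shape == (20, 28, 3)


def test_every_parameter_receives_gradient(tiny_generator, rng):
    x = Tensor(rng.random((2, 3, 8, 8), dtype=np.float32))
    y = Tensor(rng.random((2, 3, 16, 16), dtype=np.float32))
    out = tiny_generator(x)
    diff = out - y
    (diff * diff).mean().backward()
    for name, p in tiny_generator.named_parameters():
        assert p.grad is not None, name
        assert np.isfinite(p.grad).all(), name
        assert np.any(p.grad != 0), f"identically-zero gradient at {name}"
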