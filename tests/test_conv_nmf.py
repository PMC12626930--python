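"""Convolutional NMF: patch algebra and reduction to the dense layer."""

import numpy as np
import pytest

from nmfnet.approx_backprop import (
    chain_through_reparam,
    normalization_backward,
    propagate_error,
    weight_update,
)
from nmfnet.conv_nmf import (
    ConvGeometry,
    cnmf_backward,
    cnmf_forward,
    extract_patches,
    fold_patches,
)
from nmfnet.nmf_dynamics import LayerConfig, LayerWeights, forward


def geom_1x1(c_in, c_out, groups=1):
    return ConvGeometry(1, 1, c_in, c_out, groups=groups)


def random_weights(rng, geom):
    return [
        LayerWeights(U=rng.normal(size=(geom.patch_size, geom.out_per_group)))
        for _ in range(geom.groups)
    ]


# -- patch extraction --------------------------------------------------------

def test_1x1_patches_are_channel_vectors(rng):
    x = rng.uniform(size=(2, 3, 4, 4))
    p = extract_patches(x, geom_1x1(3, 5))
    np.testing.assert_array_equal(p, x.transpose(0, 2, 3, 1).reshape(2, 16, 3))


def test_full_kernel_yields_single_patch(rng):
    x = rng.uniform(size=(1, 2, 2))
    p = extract_patches(x, ConvGeometry(2, 2, 1, 4))
    assert p.shape == (1, 4)
    np.testing.assert_array_equal(p[0], x.ravel())


def test_patches_match_brute_force_indexing(rng):
    # 4x4 single channel, 3x3 kernel, stride 1: four patches, hand-indexed
    x = rng.uniform(size=(1, 4, 4))
    g = ConvGeometry(3, 3, 1, 2)
    p = extract_patches(x, g)
    assert p.shape == (4, 9)
    for k, (oy, ox) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        np.testing.assert_array_equal(p[k], x[0, oy : oy + 3, ox : ox + 3].ravel())


def test_oversized_kernel_raises():
    with pytest.raises(ValueError, match="larger"):
        ConvGeometry(5, 5, 1, 1).out_shape(3, 3)


def test_fold_is_adjoint_of_extract(rng):
    # <extract(x), p> == <x, fold(p)> for random p: the scatter-add is exact
    g = ConvGeometry(3, 3, 2, 4, stride_h=1, stride_w=1, pad=1)
    x = rng.uniform(size=(2, 2, 5, 5))
    p = rng.normal(size=extract_patches(x, g).shape)
    lhs = float((extract_patches(x, g) * p).sum())
    rhs = float((x * fold_patches(p, g, (2, 5, 5))).sum())
    assert lhs == pytest.approx(rhs, rel=1e-12)


# -- forward -----------------------------------------------------------------

def test_spatially_constant_input_gives_constant_output(rng):
    g = ConvGeometry(2, 2, 1, 3, stride_h=2, stride_w=2)
    w = random_weights(rng, g)
    x = np.full((1, 1, 4, 4), 0.7)
    out = cnmf_forward(x, w, g, LayerConfig(n_iters=10))
    for c in range(3):
        assert np.ptp(out[0, c]) == pytest.approx(0.0, abs=1e-15)


def test_1x1_geometry_reduces_to_dense_layer_per_pixel(rng):
    g = geom_1x1(4, 3)
    w = random_weights(rng, g)
    x = rng.uniform(0.1, 1.0, size=(2, 4, 3, 3))
    cfg = LayerConfig(n_iters=12)
    out = cnmf_forward(x, w, g, cfg)
    for b in range(2):
        for yy in range(3):
            for xx in range(3):
                dense = forward(x[b, :, yy, xx], w[0], cfg).h
                np.testing.assert_allclose(out[b, :, yy, xx], dense, atol=1e-14)


def test_forward_matches_per_patch_loop_oracle(rng):
    g = ConvGeometry(2, 2, 2, 4, stride_h=1, stride_w=1)
    w = random_weights(rng, g)
    x = rng.uniform(0.1, 1.0, size=(1, 2, 3, 3))
    cfg = LayerConfig(n_iters=15)
    out = cnmf_forward(x, w, g, cfg)
    patches = extract_patches(x, g)[0]  # (P, S)
    for p, (oy, ox) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        np.testing.assert_allclose(
            out[0, :, oy, ox], forward(patches[p], w[0], cfg).h, atol=1e-12
        )


def test_all_zero_patch_outputs_uniform_init():
    g = ConvGeometry(2, 2, 1, 4, stride_h=2, stride_w=2)
    w = random_weights(np.random.default_rng(0), g)
    x = np.zeros((1, 1, 4, 4))
    x[0, 0, :2, :2] = 0.5  # only the top-left patch is active
    out = cnmf_forward(x, w, g, LayerConfig(n_iters=5))
    np.testing.assert_array_equal(out[0, :, 0, 1], 0.25)
    np.testing.assert_array_equal(out[0, :, 1, 0], 0.25)
    assert out[0, :, 0, 0].sum() == pytest.approx(1.0, abs=1e-12)


def test_output_positions_sum_to_one(rng):
    g = ConvGeometry(3, 3, 2, 6, stride_h=2, stride_w=2, pad=1, groups=2)
    w = random_weights(rng, g)
    x = rng.uniform(0.1, 1.0, size=(2, 2, 6, 6))
    out = cnmf_forward(x, w, g, LayerConfig(n_iters=10))
    # per group, each position's out-channel vector is a distribution
    sums = out.reshape(2, 2, 3, *out.shape[2:]).sum(axis=2)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
    assert (out >= 0).all()


def test_negative_input_rejected(rng):
    g = geom_1x1(2, 2)
    with pytest.raises(ValueError, match="non-negative"):
        cnmf_forward(-np.ones((1, 2, 2, 2)), random_weights(rng, g), g)


# -- backward ----------------------------------------------------------------

def test_zero_upstream_error_gives_zero_gradients(rng):
    g = ConvGeometry(2, 2, 1, 4, stride_h=1, stride_w=1)
    w = random_weights(rng, g)
    x = rng.uniform(0.1, 1.0, size=(1, 1, 3, 3))
    _, cache = cnmf_forward(x, w, g, LayerConfig(), return_cache=True)
    gmap, gU = cnmf_backward(cache, w, g, np.zeros((1, 4, 2, 2)))
    assert not gmap.any() and not gU[0].any()


def test_single_patch_geometry_equals_dense_backward(rng):
    g = ConvGeometry(3, 3, 2, 5)
    w = random_weights(rng, g)
    x = rng.uniform(0.1, 1.0, size=(1, 2, 3, 3))
    cfg = LayerConfig(n_iters=8)
    _, cache = cnmf_forward(x, w, g, cfg, return_cache=True)
    phi = rng.normal(size=5)
    gmap, gU = cnmf_backward(cache, w, g, phi.reshape(1, 5, 1, 1))

    state = forward(x.ravel(), w[0], cfg)
    dense_phi = propagate_error(state, w[0].W, phi)
    dense_gU = chain_through_reparam(weight_update(state, w[0].W, phi), w[0].U)
    dense_gmap = normalization_backward(x.ravel(), dense_phi)
    np.testing.assert_allclose(gmap.ravel(), dense_gmap, atol=1e-15)
    np.testing.assert_allclose(gU[0], dense_gU, atol=1e-15)


def test_overlapping_backward_matches_scatter_add_oracle(rng):
    g = ConvGeometry(2, 2, 2, 4, stride_h=1, stride_w=1)
    w = random_weights(rng, g)
    x = rng.uniform(0.1, 1.0, size=(2, 2, 3, 3))
    cfg = LayerConfig(n_iters=10)
    _, cache = cnmf_forward(x, w, g, cfg, return_cache=True)
    up = rng.normal(size=(2, 4, 2, 2))
    gmap, gU = cnmf_backward(cache, w, g, up)

    # brute force: dense backward per patch, scatter-added by hand
    oracle_map = np.zeros_like(x)
    oracle_dw = np.zeros_like(w[0].W)
    positions = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for b in range(2):
        for p, (oy, ox) in enumerate(positions):
            patch = x[b, :, oy : oy + 2, ox : ox + 2].ravel()
            state = forward(patch, w[0], cfg)
            phi = up[b, :, oy, ox]
            grad_patch = normalization_backward(
                patch, propagate_error(state, w[0].W, phi)
            )
            oracle_map[b, :, oy : oy + 2, ox : ox + 2] += grad_patch.reshape(2, 2, 2)
            oracle_dw += weight_update(state, w[0].W, phi)
    np.testing.assert_allclose(gmap, oracle_map, atol=1e-12)
    np.testing.assert_allclose(gU[0], chain_through_reparam(oracle_dw, w[0].U), atol=1e-12)


def test_groups_are_independent(rng):
    g = ConvGeometry(2, 2, 4, 6, stride_h=2, stride_w=2, groups=2)
    w = random_weights(rng, g)
    x = rng.uniform(0.1, 1.0, size=(1, 4, 4, 4))
    out = cnmf_forward(x, w, g, LayerConfig(n_iters=8))
    # permuting channels inside group 1 must not touch group 0's output
    x2 = x.copy()
    x2[:, [2, 3]] = x2[:, [3, 2]]
    out2 = cnmf_forward(x2, w, g, LayerConfig(n_iters=8))
    np.testing.assert_array_equal(out[:, :3], out2[:, :3])
    assert not np.array_equal(out[:, 3:], out2[:, 3:])


def test_geometry_validates_group_divisibility():
    with pytest.raises(ValueError, match="divisible"):
        ConvGeometry(3, 3, 4, 6, groups=4)
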