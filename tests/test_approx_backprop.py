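"""Single-step backward: transliteration, finite-difference and unrolled oracles."""

import numpy as np
import pytest

from nmfnet.approx_backprop import (
    approximate_gradients,
    chain_through_reparam,
    input_jacobian,
    normalization_backward,
    one_step_gradients,
    propagate_error,
    unrolled_oracle,
    weight_jacobian,
    weight_jacobian_entry,
    weight_update,
)
from nmfnet.nmf_dynamics import (
    LayerConfig,
    LayerWeights,
    forward,
    h_init,
    h_step,
    make_state,
)
from nmfnet.synthetic_data import make_gradcheck_instance

FD = 1e-6


def fd_grad(f, x, eps=FD):
    g = np.zeros_like(x, dtype=float)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


# -- transliteration oracles for the propagation formulas --------------------

def propagate_loops(h, x, W, phi):
    S, I = W.shape
    out = np.empty(S)
    for s in range(S):
        R = sum(W[s, j] * h[j] for j in range(I))
        out[s] = sum(phi[i] * W[s, i] * h[i] for i in range(I)) / R
    return out


def weight_update_loops(h, x, W, phi):
    S, I = W.shape
    out = np.empty((S, I))
    for s in range(S):
        R = sum(W[s, j] * h[j] for j in range(I))
        inner = sum(W[s, j] * h[j] * phi[j] for j in range(I))
        for i in range(I):
            out[s, i] = h[i] * x[s] / R**2 * (phi[i] * R - inner)
    return out


def test_error_propagation_matches_transliteration():
    x, U, phi = make_gradcheck_instance(8, 5, seed=2)
    w = LayerWeights(U=U)
    state = forward(x, w, LayerConfig(n_iters=10))
    np.testing.assert_allclose(
        propagate_error(state, w.W, phi),
        propagate_loops(state.h, state.x, w.W, phi),
        atol=1e-12,
    )
    np.testing.assert_allclose(
        weight_update(state, w.W, phi),
        weight_update_loops(state.h, state.x, w.W, phi),
        atol=1e-12,
    )


# -- exact nulls -------------------------------------------------------------

def test_constant_upstream_error_passes_through_and_nulls_weights():
    x, U, _ = make_gradcheck_instance(9, 6, seed=4)
    w = LayerWeights(U=U)
    state = forward(x, w, LayerConfig(n_iters=10))
    phi = np.full(6, 1.7)
    np.testing.assert_allclose(propagate_error(state, w.W, phi), 1.7, atol=1e-12)
    np.testing.assert_array_equal(weight_update(state, w.W, phi), 0.0)


def test_zero_upstream_error_gives_zero_everywhere():
    x, U, _ = make_gradcheck_instance(7, 4, seed=5)
    w = LayerWeights(U=U)
    cfg = LayerConfig(n_iters=8)
    gx, gU, _ = unrolled_oracle(x, w, cfg, np.zeros(4))
    assert not gx.any() and not gU.any()
    state = forward(x, w, cfg)
    np.testing.assert_array_equal(propagate_error(state, w.W, np.zeros(4)), 0.0)


def test_zero_input_nulls_weight_update(rng):
    w = LayerWeights(U=rng.normal(size=(5, 3)))
    state = make_state(rng.uniform(0.1, 1, size=3), np.zeros(5), w.W)
    np.testing.assert_array_equal(weight_update(state, w.W, rng.normal(size=3)), 0.0)


# -- one-step Jacobians vs finite differences --------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_one_step_jacobians_match_finite_differences(seed):
    S, I = 12, 7
    x, U, phi = make_gradcheck_instance(S, I, seed=seed)
    w = LayerWeights(U=U)
    cfg1 = LayerConfig(n_iters=1, normalize_input=False)
    state0 = make_state(h_init(I), x, w.W)

    J = input_jacobian(state0, w.W)
    Jfd = np.stack(
        [
            fd_grad(
                lambda xv, i=i: h_step(make_state(h_init(I), xv, w.W), w.W, cfg1).h[i], x
            )
            for i in range(I)
        ],
        axis=1,
    )
    np.testing.assert_allclose(J, Jfd, rtol=0, atol=1e-6 * max(1, np.abs(Jfd).max()))

    Jw = weight_jacobian(state0, w.W)
    for i in range(I):
        Jwfd = fd_grad(
            lambda Wv, i=i: h_step(make_state(h_init(I), x, Wv), Wv, cfg1).h[i], w.W
        )
        np.testing.assert_allclose(
            Jw[:, i, :], Jwfd, rtol=0, atol=1e-6 * max(1, np.abs(Jwfd).max())
        )


def test_jacobian_entries_vanish_for_inactive_units(rng):
    w = LayerWeights(U=rng.normal(size=(5, 3)))
    h = rng.uniform(0.1, 1, size=3)
    h[1] = 0.0
    state = make_state(h, rng.uniform(0.1, 1, size=5), w.W)
    assert not input_jacobian(state, w.W)[:, 1].any()


def test_single_active_unit_weight_entry_is_zero():
    # with one active component, W_si h_i = R_s and the bracket vanishes
    W = np.array([[0.6, 0.4], [0.4, 0.6]])
    state = make_state(np.array([1.0, 0.0]), np.array([0.3, 0.7]), W)
    assert weight_jacobian_entry(state, W, 0, 0, 0) == pytest.approx(0.0, abs=1e-15)


def test_contraction_of_weight_jacobian_equals_weight_update():
    x, U, phi = make_gradcheck_instance(6, 4, seed=11)
    w = LayerWeights(U=U)
    state = forward(x, w, LayerConfig(n_iters=5))
    Jw = weight_jacobian(state, w.W)
    np.testing.assert_allclose(
        np.einsum("sij,i->sj", Jw, phi), weight_update(state, w.W, phi), atol=1e-12
    )


def test_balanced_input_perturbations_conserve_activity(rng):
    # sum_i dh_i = sum_s dx_s * (sum_i h_i W_si / R_s) = sum_s dx_s at any
    # state with matched totals; for zero-sum perturbations the change is 0
    x, U, _ = make_gradcheck_instance(8, 5, seed=13)
    w = LayerWeights(U=U)
    state = forward(x, w, LayerConfig(n_iters=10))
    J = input_jacobian(state, w.W)
    dx = rng.normal(size=8)
    dx -= dx.mean()  # zero-sum perturbation
    assert (dx @ J).sum() == pytest.approx(0.0, abs=1e-12)


# -- reparameterization chain ------------------------------------------------

def test_chain_rule_nulls(rng):
    U = rng.normal(size=(5, 3))
    np.testing.assert_array_equal(chain_through_reparam(np.zeros((5, 3)), U), 0.0)
    const_cols = np.tile(rng.normal(size=3), (5, 1))
    np.testing.assert_allclose(
        chain_through_reparam(const_cols, np.abs(U)), 0.0, atol=1e-12
    )


@pytest.mark.parametrize("seed", range(5))
def test_composed_one_step_u_gradient_matches_finite_differences(seed):
    S, I = 12, 7
    x, U, phi = make_gradcheck_instance(S, I, seed=100 + seed)
    w = LayerWeights(U=U)
    cfg1 = LayerConfig(n_iters=1)
    state0 = make_state(h_init(I), x, w.W)  # x is already normalized
    _, gU = one_step_gradients(state0, w, phi)

    def loss(Uv):
        return float(phi @ forward(x, LayerWeights(U=Uv), cfg1).h)

    gUfd = fd_grad(loss, U)
    np.testing.assert_allclose(gU, gUfd, rtol=0, atol=1e-6 * max(1, np.abs(gUfd).max()))


# -- unrolled oracle ---------------------------------------------------------

def test_unrolled_oracle_matches_finite_differences():
    S, I, N = 6, 4, 7
    x, U, phi = make_gradcheck_instance(S, I, seed=21)
    xraw = x * 3.1  # unnormalized input exercises the normalization chain
    w = LayerWeights(U=U)
    cfg = LayerConfig(n_iters=N)
    gx, gU, stored = unrolled_oracle(xraw, w, cfg, phi)
    assert stored == N + 1

    def loss_u(Uv):
        return float(phi @ forward(xraw, LayerWeights(U=Uv), cfg).h)

    def loss_x(xv):
        return float(phi @ forward(xv, w, cfg).h)

    np.testing.assert_allclose(gU, fd_grad(loss_u, U), rtol=0, atol=1e-7)
    np.testing.assert_allclose(gx, fd_grad(loss_x, xraw), rtol=0, atol=1e-7)


def test_production_backward_stores_single_iterate():
    x, U, phi = make_gradcheck_instance(6, 4, seed=22)
    w = LayerWeights(U=U)
    cfg = LayerConfig(n_iters=25)
    _, _, n_prod = approximate_gradients(x, w, cfg, phi)
    _, _, n_oracle = unrolled_oracle(x, w, cfg, phi)
    assert n_prod == 1
    assert n_oracle == cfg.n_iters + 1


def test_multi_step_gradient_alignment():
    cfg = LayerConfig(n_iters=25)
    cosines = []
    for seed in range(30):
        x, U, phi = make_gradcheck_instance(12, 7, seed=300 + seed)
        w = LayerWeights(U=U)
        _, ga, _ = approximate_gradients(x, w, cfg, phi)
        _, ge, _ = unrolled_oracle(x, w, cfg, phi)
        cosines.append(
            float(ga.ravel() @ ge.ravel() / (np.linalg.norm(ga) * np.linalg.norm(ge)))
        )
    assert np.median(cosines) >= 0.8
    assert np.mean(np.array(cosines) > 0) >= 0.95


def test_normalization_backward_matches_finite_differences(rng):
    x = rng.uniform(0.2, 1.5, size=6)
    g = rng.normal(size=6)

    def f(xv):
        return float(g @ (xv / xv.sum()))

    np.testing.assert_allclose(normalization_backward(x, g), fd_grad(f, x), atol=1e-8)
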