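"""Single-step approximate backpropagation through the NMF h-dynamics.

The forward pass of an NMF layer iterates a multiplicative update N times.
Storing every iterate for exact reverse-mode differentiation costs N + 1
states per layer; instead, the backward pass here differentiates a *single*
update step evaluated at the layer's final state h(N):

    dh'_i/dx_s   = eps * h_i W_si / R_s
    dh'_i/dW_sj  = eps * h_i x_s / R_s * (delta_ij - W_si h_j / R_s)

contracted with the upstream error Phi to give the weight update

    delta_omega_si = h_i x_s / R_s^2 * (Phi_i R_s - sum_j W_sj h_j Phi_j)

and the propagated (downstream) error

    Phi_s = sum_i Phi_i W_si h_i / sum_j W_sj h_j.

These formulas are the exact Jacobian of one step taken *from* the state
they are evaluated at; using them at h(N) in place of unrolling all N steps
is the approximation.  All quantities follow the loss-gradient sign
convention (Phi = dL/dh; the descent direction is the negative).

An exact unrolled oracle (hand-written reverse-mode through all stored
iterates, cross-checkable against finite differences) is provided for
verification; it is never used by the production backward path.
"""

from __future__ import annotations

import numpy as np

from .nmf_dynamics import (
    HState,
    LayerConfig,
    LayerWeights,
    forward,
    normalize_input,
    reparameterize,
)


def _floored(R: np.ndarray, floor: float) -> np.ndarray:
    return np.maximum(R, floor)


def input_jacobian(
    state: HState, W: np.ndarray, epsilon: float = 1.0, floor: float = 1e-12
) -> np.ndarray:
    """Jacobian dh'_i/dx_s of one update step taken from ``state``.

    Returns an (..., S, I) array with entry (s, i) equal to
    ``eps * h_i W_si / R_s``.  Rows with ``h_i = 0`` are exactly zero
    (absorbing zeros have no sensitivity).
    """
    R = _floored(state.R, floor)
    return epsilon * W[..., :, :] * state.h[..., None, :] / R[..., :, None]


def weight_jacobian(
    state: HState, W: np.ndarray, epsilon: float = 1.0, floor: float = 1e-12
) -> np.ndarray:
    """Full one-step Jacobian dh'_i/dW_sj as an (S, I, I) array (single sample).

    ``J[s, i, j] = eps * h_i x_s / R_s * (delta_ij - W_si h_j / R_s)``.
    Intended for desk-scale verification; the production path uses the
    contracted form in :func:`weight_update`.
    """
    if state.h.ndim != 1:
        raise ValueError("weight_jacobian expects a single-sample state")
    R = _floored(state.R, floor)
    S, I = W.shape
    xR = state.x / R  # (S,)
    eye = np.eye(I)
    # (S, I, I): first I axis is i (output), second is j (the W column index)
    J = state.h[None, :, None] * xR[:, None, None] * (
        eye[None, :, :] - W[:, :, None] * state.h[None, None, :] / R[:, None, None]
    )
    return epsilon * J


def weight_jacobian_entry(
    state: HState, W: np.ndarray, i: int, s: int, j: int, epsilon: float = 1.0
) -> float:
    """Single entry dh'_i/dW_sj of the one-step Jacobian."""
    R = float(state.R[s])
    return float(
        epsilon
        * state.h[i]
        * state.x[s]
        / R
        * ((1.0 if i == j else 0.0) - W[s, i] * state.h[j] / R)
    )


def propagate_error(
    state: HState, W: np.ndarray, phi_upper: np.ndarray, floor: float = 1e-12
) -> np.ndarray:
    """Back-propagated error to the layer input.

    ``Phi_s = sum_i Phi_i W_si h_i / R_s`` with ``R_s = sum_j W_sj h_j``.
    A constant upstream error passes through unchanged (the weights cancel).
    """
    bad = (state.x > 0) & (state.R < floor)
    if bad.any():
        raise FloatingPointError("reconstruction denominator below floor")
    R = _floored(state.R, floor)
    return ((phi_upper * state.h) @ W.T) / R


def weight_update(
    state: HState, W: np.ndarray, phi_upper: np.ndarray, floor: float = 1e-12
) -> np.ndarray:
    """Loss gradient w.r.t. W from the final state (S x I), batch-summed.

    ``delta_omega_si = h_i x_s / R_s^2 * (Phi_i R_s - sum_j W_sj h_j Phi_j)``.
    Exactly zero when the upstream error is constant across components
    (the two terms cancel because ``sum_j W_sj h_j = R_s``).
    """
    bad = (state.x > 0) & (state.R < floor)
    if bad.any():
        raise FloatingPointError("reconstruction denominator below floor")
    R = _floored(state.R, floor)
    h = np.atleast_2d(state.h)
    x = np.atleast_2d(state.x)
    Rb = np.atleast_2d(R)
    phi = np.atleast_2d(phi_upper)
    # flatten any leading batch axes
    h = h.reshape(-1, h.shape[-1])
    x = x.reshape(-1, x.shape[-1])
    Rb = Rb.reshape(-1, Rb.shape[-1])
    phi = phi.reshape(-1, phi.shape[-1])
    # shift Phi by its first entry per sample: the bracket
    # Phi_i R_s - sum_j W_sj h_j Phi_j = sum_j W_sj h_j (Phi_i - Phi_j) is
    # invariant under the shift, and a constant Phi then yields 0 exactly
    phi = phi - phi[:, :1]
    c = (phi * h) @ W.T  # (B, S): sum_j W_sj h_j Phi_j
    return (x / Rb).T @ (phi * h) - (x * c / Rb**2).T @ h


def backward(
    state: HState, W: np.ndarray, phi_upper: np.ndarray, floor: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Production single-step backward at the final state.

    Returns ``(phi_lower, delta_omega)`` — the error propagated to the layer
    input (same shape as x) and the batch-summed W-gradient.  Touches only
    the one stored final state; assumes unit gain (eps = 1).
    """
    return (
        propagate_error(state, W, phi_upper, floor),
        weight_update(state, W, phi_upper, floor),
    )


def chain_through_reparam(delta_omega: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Convert a W-gradient into a U-gradient through the reparameterization.

    With ``W_si = |U_si| / n_i``, ``n_i = sum_k |U_ki|``, the exact chain
    rule is

        ``dL/dU_si = sign(U_si) / n_i * (delta_omega_si - sum_t W_ti delta_omega_ti)``

    — a projective normalization: a common mode added to a column of
    delta_omega leaves the U-gradient unchanged.  Entries with ``U_si = 0``
    use subgradient 0.
    """
    U = np.asarray(U, dtype=float)
    W = reparameterize(U)
    n = np.abs(U).sum(axis=0)  # (I,)
    col_mode = (W * delta_omega).sum(axis=0)  # (I,): sum_t W_ti dw_ti
    return np.sign(U) / n * (delta_omega - col_mode)


def normalization_backward(
    x_raw: np.ndarray, grad_wrt_normalized: np.ndarray
) -> np.ndarray:
    """Chain a gradient through the sum-to-1 input normalization.

    For ``xhat = x / sigma`` with ``sigma = sum_s x_s``:
    ``dL/dx_s = (g_s - sum_t g_t xhat_t) / sigma``.  All-zero samples get a
    zero gradient (the layer maps them to a constant).
    """
    x_raw = np.asarray(x_raw, dtype=float)
    g = np.asarray(grad_wrt_normalized, dtype=float)
    sigma = x_raw.sum(axis=-1, keepdims=True)
    safe = np.where(sigma > 0, sigma, 1.0)
    xhat = x_raw / safe
    out = (g - (g * xhat).sum(axis=-1, keepdims=True)) / safe
    return np.where(sigma > 0, out, 0.0)


def unrolled_oracle(
    x: np.ndarray,
    weights: LayerWeights,
    cfg: LayerConfig,
    phi_upper: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Exact gradients of the N-step forward by reverse mode through all iterates.

    Differentiates the full composed map — input normalization (if
    configured), N update steps, and the U -> W reparameterization — by
    storing every iterate and walking the chain rule backwards step by
    step.  Returns ``(exact phi_lower w.r.t. the raw x, exact U-gradient,
    number of stored iterates)``; the iterate count (N + 1) is the memory
    price the approximate backward avoids.

    Intended for desk-scale verification (S * I * N up to ~1e5).
    """
    x = np.asarray(x, dtype=float)
    W = weights.W
    eps = cfg.epsilon
    final, traj = forward(x, weights, cfg, record_trajectory=True)
    stored = len(traj)  # N + 1

    single = x.ndim == 1
    gh = np.atleast_2d(np.asarray(phi_upper, dtype=float)).copy()
    gW = np.zeros_like(W)
    gx_norm = np.zeros(np.atleast_2d(x).shape)

    # walk steps backwards: traj[t] -> traj[t+1]
    for t in range(len(traj) - 2, -1, -1):
        st = traj[t]
        h = np.atleast_2d(st.h)
        xn = np.atleast_2d(st.x)
        R = np.maximum(np.atleast_2d(st.R), cfg.floor)
        q = xn / R
        a = q @ W  # drive
        # h' = h + eps*h*(a - 1)
        ga = eps * gh * h
        gh = gh * (1.0 + eps * (a - 1.0))
        gq = ga @ W.T
        gW += np.einsum("bs,bi->si", q, ga)
        gx_norm += gq / R
        gR = -gq * xn / R**2
        gh += gR @ W
        gW += np.einsum("bs,bi->si", gR, h)

    # h(0) is a constant: the remaining gh does not reach x or W
    if cfg.normalize_input:
        gx = normalization_backward(np.atleast_2d(x), gx_norm)
    else:
        gx = gx_norm
    gU = chain_through_reparam(gW, weights.U)
    if single:
        gx = gx[0]
    return gx, gU, stored


def one_step_gradients(
    state: HState,
    weights: LayerWeights,
    phi_upper: np.ndarray,
    floor: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact gradients of a *single* update step taken from ``state``.

    The backward formulas are the true Jacobian of one step evaluated at
    the state the step starts from, so here (unlike the multi-step
    approximation) the returned ``(phi_lower w.r.t. state.x, U-gradient)``
    are exact for the map ``(x, U) -> h'``.
    """
    phi_lower, dw = backward(state, weights.W, np.asarray(phi_upper, dtype=float), floor)
    return phi_lower, chain_through_reparam(dw, weights.U)


def approximate_gradients(
    x: np.ndarray,
    weights: LayerWeights,
    cfg: LayerConfig,
    phi_upper: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Run the forward pass and the production single-step backward.

    Mirrors :func:`unrolled_oracle`'s interface (gradient w.r.t. the raw x,
    U-gradient, stored-iterate count) so the two routes are directly
    comparable; the count here is always 1 — only the final state is kept.
    """
    x = np.asarray(x, dtype=float)
    final = forward(x, weights, cfg)
    phi_lower, dw = backward(final, weights.W, np.asarray(phi_upper, dtype=float), cfg.floor)
    if cfg.normalize_input:
        phi_lower = normalization_backward(x, phi_lower)
    gU = chain_through_reparam(dw, weights.U)
    return phi_lower, gU, 1
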