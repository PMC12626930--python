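"""The in-network NMF layer: iterative h-dynamics with fixed weights.

A layer holds a non-negative, column-normalized weight matrix ``W`` (S x I)
derived from an unconstrained trainable matrix ``U`` via

    ``W_si = |U_si| / sum_k |U_ki|``

and maps a non-negative input vector ``x`` (length S) to latent activities
``h`` (length I) by iterating, from the uniform start ``h_i(0) = 1/I``,

    ``h_i <- h_i + eps * h_i * (sum_s x_s W_si / R_s - 1)``,
    ``R_s = sum_i W_si h_i``.

With unit gain (``eps = 1``) a step multiplies ``h_i`` by
``sum_s x_s W_si / R_s`` — one multiplicative KL-NMF H-update — and
conserves the total activity: ``sum_i h_i = sum_s x_s`` after every step.
Layer inputs are therefore normalized to sum 1 before the dynamics, so the
output h is itself a distribution over the I features.

All operations accept either a single vector or a batch (rows are
independent samples; results never depend on batch composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DENOM_FLOOR = 1e-12


@dataclass(frozen=True)
class LayerConfig:
    """Iteration count, update gain and numeric guards for one NMF layer.

    n_iters: number N of update steps (typically 15-100 in practice;
        the default 25 keeps CPU cost low).
    epsilon: update gain; 1 recovers the multiplicative KL update. Values
        other than 1 are supported in the forward pass only — the one-step
        backward formulas assume eps = 1.
    floor: lower bound applied to reconstruction denominators R_s.
    normalize_input: scale each input vector to sum 1 before the dynamics
        (the scale is dropped, not re-applied).
    h_floor: optional positive floor on h after each step (default 0, i.e.
        exact absorbing zeros), for experiments on the absorbing-zero effect.
    """

    n_iters: int = 25
    epsilon: float = 1.0
    floor: float = DENOM_FLOOR
    normalize_input: bool = True
    h_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        if self.h_floor < 0:
            raise ValueError("h_floor must be >= 0")


def reparameterize(U: np.ndarray) -> np.ndarray:
    """Map the unconstrained auxiliary matrix U to the layer weight W.

    ``W_si = |U_si| / sum_k |U_ki|``: elementwise absolute value enforces
    non-negativity, then each column (the S-indexed axis) is scaled to sum
    to 1.  Raises if a column of U is entirely zero (normalization
    undefined).
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be 2-D (S x I)")
    A = np.abs(U)
    norms = A.sum(axis=0)
    if (norms <= 0).any():
        raise ValueError(
            f"column(s) {np.flatnonzero(norms <= 0).tolist()} of U are all zero; "
            "normalization is undefined"
        )
    return A / norms


@dataclass(frozen=True)
class LayerWeights:
    """Trainable auxiliary matrix U (S x I) and its derived weight W.

    W is recomputed from U on construction; mutate U only by building a new
    LayerWeights (the optimizer updates U, never W directly).
    """

    U: np.ndarray
    W: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "W", reparameterize(U))

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class HState:
    """Layer activity state: h, the reconstruction denominators R, and x.

    ``h`` is (..., I), ``x`` is (..., S), ``R = h @ W.T`` is (..., S) and
    must be consistent with the W the state was produced under.  For a
    state reached with eps = 1 from a normalized input, ``h`` sums to 1
    along its last axis.
    """

    h: np.ndarray
    R: np.ndarray
    x: np.ndarray


def h_init(I: int, like: np.ndarray | None = None) -> np.ndarray:
    """Uniform initial activity ``h_i(0) = 1/I`` (sums to 1).

    With ``like`` given, broadcasts to the leading (batch) shape of that
    array.
    """
    if I < 1:
        raise ValueError("I must be >= 1")
    h = np.full(I, 1.0 / I)
    if like is not None:
        like = np.asarray(like)
        h = np.broadcast_to(h, like.shape[:-1] + (I,)).copy()
    return h


def make_state(h: np.ndarray, x: np.ndarray, W: np.ndarray) -> HState:
    """Build an HState with R recomputed from h and W."""
    h = np.asarray(h, dtype=float)
    x = np.asarray(x, dtype=float)
    return HState(h=h, R=h @ W.T, x=x)


def _check_reconstruction(R: np.ndarray, x: np.ndarray, floor: float) -> None:
    bad = (x > 0) & (R < floor)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise FloatingPointError(
            f"reconstruction collapse: R below floor {floor} at index "
            f"{tuple(idx.tolist())} while the input is positive"
        )


def h_step(state: HState, W: np.ndarray, cfg: LayerConfig) -> HState:
    """One update step of the h-dynamics.

    ``h_i <- h_i + eps * h_i * (sum_s x_s W_si / R_s - 1)``; R is refreshed
    from the new h.  Raises on reconstruction collapse (R below the floor
    where x is positive).
    """
    _check_reconstruction(state.R, state.x, cfg.floor)
    ratio = state.x / np.maximum(state.R, cfg.floor)
    drive = ratio @ W  # (..., I): sum_s x_s W_si / R_s
    h_new = state.h + cfg.epsilon * state.h * (drive - 1.0)
    if cfg.h_floor > 0:
        h_new = np.maximum(h_new, cfg.h_floor)
    else:
        h_new = np.maximum(h_new, 0.0)
    return HState(h=h_new, R=h_new @ W.T, x=state.x)


def normalize_input(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each sample of x to sum 1; returns (x_normalized, sums).

    All-zero samples are left at zero (their sum is returned as 0); the
    dynamics map them to the uniform init by convention, handled by the
    caller.
    """
    x = np.asarray(x, dtype=float)
    sums = x.sum(axis=-1, keepdims=True)
    safe = np.where(sums > 0, sums, 1.0)
    return x / safe, sums[..., 0]


def forward(
    x: np.ndarray,
    weights: LayerWeights | np.ndarray,
    cfg: LayerConfig = LayerConfig(),
    record_trajectory: bool = False,
) -> HState | tuple[HState, list[HState]]:
    """Run the h-dynamics for N steps from the uniform init.

    Returns the final state; with ``record_trajectory`` also returns all
    N + 1 states (used by the exact unrolled oracle — the production
    backward pass never needs them).
    """
    W = weights.W if isinstance(weights, LayerWeights) else np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("layer input must be non-negative")
    if x.shape[-1] != W.shape[0]:
        raise ValueError(f"input has {x.shape[-1]} features, W expects {W.shape[0]}")
    if cfg.normalize_input:
        x, _ = normalize_input(x)
    state = make_state(h_init(W.shape[1], like=x), x, W)
    trajectory = [state] if record_trajectory else None
    for _ in range(cfg.n_iters):
        state = h_step(state, W, cfg)
        if trajectory is not None:
            trajectory.append(state)
    if record_trajectory:
        return state, trajectory
    return state
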