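"""Offline KL-NMF with multiplicative updates.

Decomposes a non-negative matrix ``X`` (M samples x S features) into
``X ~ H @ W.T`` with ``W`` (S x I) column-normalized and ``H`` (M x I),
both non-negative, by alternating multiplicative updates that descend the
Kullback-Leibler divergence ``D(X || WH) = sum_{mu,s} X_ms ln(X_ms / R_ms)``
where ``R_ms = sum_j W_sj h_mj``.

This is the reference factorization used as a correctness baseline for the
in-network NMF dynamics: a single H-update here coincides with one step of
the layer dynamics at unit gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Denominators in multiplicative updates are floored at this value before
#: division.  The updates are absorbing at zero, so the floor only guards
#: against 0/0 without materially changing limits.
DENOM_FLOOR = 1e-12


@dataclass(frozen=True)
class FactorPair:
    """Non-negative factor pair ``(W, H)`` of rank ``I``.

    ``W`` is S x I (features x components), ``H`` is M x I (samples x
    components).  After column normalization each column of ``W`` sums to 1.
    """

    W: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        H = np.asarray(self.H, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "H", H)
        if W.ndim != 2 or H.ndim != 2:
            raise ValueError("W and H must be 2-D arrays")
        if W.shape[1] != H.shape[1]:
            raise ValueError(
                f"rank mismatch: W has {W.shape[1]} components, H has {H.shape[1]}"
            )
        if not (np.isfinite(W).all() and np.isfinite(H).all()):
            raise ValueError("factors must be finite")
        if (W < 0).any() or (H < 0).any():
            raise ValueError("factors must be non-negative")

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    def reconstruction(self) -> np.ndarray:
        """M x S reconstruction ``R_ms = sum_j W_sj h_mj``."""
        return self.H @ self.W.T


def validate_nonneg_matrix(X: np.ndarray) -> np.ndarray:
    """Validate and return the factorization target as a float array."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix (samples x features)")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    return X


def _check_dims(X: np.ndarray, F: FactorPair) -> None:
    M, S = X.shape
    if F.W.shape[0] != S or F.H.shape[0] != M:
        raise ValueError(
            f"dimension mismatch: X is {M}x{S}, W is {F.W.shape[0]}x{F.W.shape[1]}, "
            f"H is {F.H.shape[0]}x{F.H.shape[1]}"
        )


def kl_divergence(X: np.ndarray, F: FactorPair) -> float:
    """Kullback-Leibler reconstruction divergence, log term only.

    ``D = sum_{mu,s} X_ms ln(X_ms / sum_j W_sj h_mj)`` with the convention
    ``0 * ln(0/r) = 0``.  Raises if the reconstruction vanishes where X is
    positive (degenerate factors make the divergence infinite).
    """
    X = validate_nonneg_matrix(X)
    _check_dims(X, F)
    R = F.reconstruction()
    pos = X > 0
    if (R[pos] <= 0).any():
        mu, s = np.argwhere(pos & (R <= 0))[0]
        raise ValueError(
            f"reconstruction is zero at ({mu}, {s}) where X is positive; "
            "factors are degenerate"
        )
    out = np.zeros_like(X)
    out[pos] = X[pos] * np.log(X[pos] / R[pos])
    return float(out.sum())


def update_h(X: np.ndarray, F: FactorPair) -> FactorPair:
    """One multiplicative H-update: ``h_mi <- h_mi sum_s W_si X_ms / R_ms``."""
    X = validate_nonneg_matrix(X)
    _check_dims(X, F)
    R = F.reconstruction()
    bad = (X > 0) & (R < DENOM_FLOOR)
    if bad.any():
        mu, s = np.argwhere(bad)[0]
        raise ValueError(f"zero reconstruction denominator at sample {mu}, feature {s}")
    H_new = F.H * ((X / np.maximum(R, DENOM_FLOOR)) @ F.W)
    return FactorPair(W=F.W, H=H_new)


def update_w(X: np.ndarray, F: FactorPair) -> FactorPair:
    """One multiplicative W-update followed by column normalization.

    ``W_si <- W_si sum_mu h_mi X_ms / R_ms`` then ``W_si <- W_si / sum_j W_ji``.
    """
    X = validate_nonneg_matrix(X)
    _check_dims(X, F)
    R = F.reconstruction()
    bad = (X > 0) & (R < DENOM_FLOOR)
    if bad.any():
        mu, s = np.argwhere(bad)[0]
        raise ValueError(f"zero reconstruction denominator at sample {mu}, feature {s}")
    W_new = F.W * ((X / np.maximum(R, DENOM_FLOOR)).T @ F.H)
    col_sums = W_new.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValueError(
            f"column(s) {np.flatnonzero(col_sums <= 0).tolist()} collapsed to zero; "
            "cannot normalize"
        )
    return FactorPair(W=W_new / col_sums, H=F.H)


def _random_init(M: int, S: int, rank: int, rng: np.random.Generator) -> FactorPair:
    # strictly positive start: multiplicative updates cannot escape zeros
    W = rng.uniform(0.1, 1.1, size=(S, rank))
    H = rng.uniform(0.1, 1.1, size=(M, rank))
    W /= W.sum(axis=0)
    return FactorPair(W=W, H=H)


def factorize(
    X: np.ndarray,
    rank: int,
    n_iters: int = 200,
    seed: int = 0,
    init: FactorPair | None = None,
) -> tuple[FactorPair, np.ndarray]:
    """Alternate H/W multiplicative updates from a seeded positive init.

    Returns the final factors and the divergence trace: ``trace[0]`` is the
    divergence of the initial factors and ``trace[t]`` the value after the
    t-th (H then W) update pair.  The trace is non-increasing in practice.
    """
    X = validate_nonneg_matrix(X)
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(X.shape):
        warnings.warn(
            f"rank {rank} exceeds min(M, S) = {min(X.shape)}: overcomplete "
            "factorization",
            stacklevel=2,
        )
    F = init if init is not None else _random_init(*X.shape, rank, np.random.default_rng(seed))
    _check_dims(X, F)
    trace = np.empty(n_iters + 1)
    trace[0] = kl_divergence(X, F)
    for t in range(1, n_iters + 1):
        F = update_h(X, F)
        F = update_w(X, F)
        trace[t] = kl_divergence(X, F)
    return F, trace
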