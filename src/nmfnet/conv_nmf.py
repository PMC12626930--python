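"""Convolutional NMF: the dense NMF layer applied patch-wise with shared weights.

The linear reconstruction of NMF is replaced by a convolution: at every
output position the receptive-field patch (flattened channel-then-row-then-
column) is normalized to sum 1 and run through the iterative h-dynamics
with the layer's shared column-normalized weights, and the resulting h
becomes the output channel vector at that position.  Channel groups split
the layer into independent sub-layers, each with its own weight matrix.

Functions here are the functional core; `nmfnet.layers.CNMF2d` wraps them
as a trainable module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import approx_backprop as ab
from .nmf_dynamics import HState, LayerConfig, LayerWeights, forward


@dataclass(frozen=True)
class ConvGeometry:
    """Kernel/stride/padding/channel geometry of one convolutional layer.

    Padding is zero-fill, applied symmetrically.  Output position (0, 0) is
    the top-left kernel placement; positions are enumerated row-major with
    0-based indexing.
    """

    kernel_h: int
    kernel_w: int
    in_channels: int
    out_channels: int
    stride_h: int = 1
    stride_w: int = 1
    pad: int = 0
    groups: int = 1

    def __post_init__(self) -> None:
        for name in ("kernel_h", "kernel_w", "in_channels", "out_channels", "stride_h", "stride_w", "groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError(
                f"in_channels ({self.in_channels}) and out_channels "
                f"({self.out_channels}) must be divisible by groups ({self.groups})"
            )

    @property
    def in_per_group(self) -> int:
        return self.in_channels // self.groups

    @property
    def out_per_group(self) -> int:
        return self.out_channels // self.groups

    @property
    def patch_size(self) -> int:
        """S of the per-group dense problem: kh * kw * in_channels_per_group."""
        return self.kernel_h * self.kernel_w * self.in_per_group

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        oh = (h + 2 * self.pad - self.kernel_h) // self.stride_h + 1
        ow = (w + 2 * self.pad - self.kernel_w) // self.stride_w + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"kernel {self.kernel_h}x{self.kernel_w} larger than padded "
                f"input {h + 2 * self.pad}x{w + 2 * self.pad}"
            )
        return oh, ow


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        return x[None], True
    if x.ndim != 4:
        raise ValueError("feature map must be (C, H, W) or (B, C, H, W)")
    return x, False


def extract_patches(feature_map: np.ndarray, geom: ConvGeometry) -> np.ndarray:
    """im2col: (B, C, H, W) -> (B, P, S) receptive-field patch matrix.

    Row p is the flattened patch at output position p (row-major over
    positions); flattening order within a patch is channel, then kernel
    row, then kernel column.  Uses all channels of the given map — callers
    handling groups slice channels first.
    """
    x, squeeze = _as_batch(feature_map)
    B, C, H, W = x.shape
    oh, ow = geom.out_shape(H, W)
    if geom.pad:
        x = np.pad(x, ((0, 0), (0, 0), (geom.pad,) * 2, (geom.pad,) * 2))
    win = sliding_window_view(x, (geom.kernel_h, geom.kernel_w), axis=(2, 3))
    win = win[:, :, :: geom.stride_h, :: geom.stride_w]  # (B, C, oh, ow, kh, kw)
    patches = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh * ow, -1)
    out = np.ascontiguousarray(patches)
    return out[0] if squeeze else out


def fold_patches(
    patches: np.ndarray, geom: ConvGeometry, in_shape: tuple[int, int, int]
) -> np.ndarray:
    """col2im scatter-add: the adjoint of :func:`extract_patches`.

    Sums overlapping patch entries back onto a (B, C, H, W) map (padding
    contributions are discarded).
    """
    C, H, W = in_shape
    B = patches.shape[0]
    oh, ow = geom.out_shape(H, W)
    Hp, Wp = H + 2 * geom.pad, W + 2 * geom.pad
    out = np.zeros((B, C, Hp, Wp))
    p6 = patches.reshape(B, oh, ow, C, geom.kernel_h, geom.kernel_w)
    for dy in range(geom.kernel_h):
        for dx in range(geom.kernel_w):
            out[
                :,
                :,
                dy : dy + oh * geom.stride_h : geom.stride_h,
                dx : dx + ow * geom.stride_w : geom.stride_w,
            ] += p6[:, :, :, :, dy, dx].transpose(0, 3, 1, 2)
    if geom.pad:
        out = out[:, :, geom.pad : geom.pad + H, geom.pad : geom.pad + W]
    return out


def _as_group_weights(
    weights: LayerWeights | Sequence[LayerWeights], geom: ConvGeometry
) -> list[LayerWeights]:
    ws = [weights] if isinstance(weights, LayerWeights) else list(weights)
    if len(ws) != geom.groups:
        raise ValueError(f"expected {geom.groups} weight group(s), got {len(ws)}")
    for g, w in enumerate(ws):
        if w.W.shape != (geom.patch_size, geom.out_per_group):
            raise ValueError(
                f"group {g}: weight shape {w.W.shape} does not match geometry "
                f"({geom.patch_size}, {geom.out_per_group})"
            )
    return ws


@dataclass
class CNMFCache:
    """Per-group forward state kept for the single-step backward."""

    raw_patches: list[np.ndarray]  # (B*P, S_g) before normalization
    states: list[HState]  # final dynamics state per group, batch-flattened
    in_shape: tuple[int, int, int]
    batch: int
    out_hw: tuple[int, int]

    @property
    def stored_iterates_per_group(self) -> int:
        """Iterates retained per group for the backward pass (always 1)."""
        return 1


def cnmf_forward(
    feature_map: np.ndarray,
    weights: LayerWeights | Sequence[LayerWeights],
    geom: ConvGeometry,
    cfg: LayerConfig = LayerConfig(),
    return_cache: bool = False,
) -> np.ndarray | tuple[np.ndarray, CNMFCache]:
    """Patch-wise NMF dynamics over a non-negative feature map.

    Each patch is normalized to sum 1 and run N steps from the uniform
    init; the output at each position is h(N) (so the out-channel vector at
    every position sums to 1 at unit gain).  All-zero patches yield the
    uniform init vector directly — the dynamics are undefined at zero input
    and the uniform start is their continuous anchor.
    """
    x, squeeze = _as_batch(feature_map)
    if (x < 0).any():
        raise ValueError("CNMF input must be non-negative")
    B, C, H, W = x.shape
    if C != geom.in_channels:
        raise ValueError(f"input has {C} channels, geometry expects {geom.in_channels}")
    ws = _as_group_weights(weights, geom)
    oh, ow = geom.out_shape(H, W)
    P = oh * ow
    out = np.empty((B, geom.out_channels, oh, ow))
    raw_list: list[np.ndarray] = []
    state_list: list[HState] = []
    cg, Ig = geom.in_per_group, geom.out_per_group
    for g in range(geom.groups):
        sub = x[:, g * cg : (g + 1) * cg]
        patches = extract_patches(sub, geom).reshape(B * P, -1)
        state = forward(patches, ws[g], cfg)
        h = state.h
        zero = patches.sum(axis=1) == 0
        if zero.any():
            h = h.copy()
            h[zero] = 1.0 / Ig
        out[:, g * Ig : (g + 1) * Ig] = (
            h.reshape(B, oh, ow, Ig).transpose(0, 3, 1, 2)
        )
        if return_cache:
            raw_list.append(patches)
            state_list.append(state)
    result = out[0] if squeeze else out
    if return_cache:
        return result, CNMFCache(raw_list, state_list, (C, H, W), B, (oh, ow))
    return result


def cnmf_backward(
    cache: CNMFCache,
    weights: LayerWeights | Sequence[LayerWeights],
    geom: ConvGeometry,
    upstream: np.ndarray,
    floor: float = 1e-12,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Single-step approximate backward through the patch-wise dynamics.

    Per patch, the error is propagated and the weight gradient accumulated
    from the final state only; weight gradients are summed over all
    positions and samples (shared weights), input errors from overlapping
    patches are scatter-added at each input pixel, and the Jacobian of the
    per-patch sum-to-1 normalization is included.  Returns the input error
    map and one U-gradient per group.
    """
    up, squeeze = _as_batch(upstream)
    ws = _as_group_weights(weights, geom)
    B = cache.batch
    oh, ow = cache.out_hw
    P = oh * ow
    C, H, W = cache.in_shape
    cg, Ig = geom.in_per_group, geom.out_per_group
    grad_map = np.zeros((B, C, H, W))
    u_grads: list[np.ndarray] = []
    for g in range(geom.groups):
        phi = (
            up[:, g * Ig : (g + 1) * Ig]
            .transpose(0, 2, 3, 1)
            .reshape(B * P, Ig)
        )
        state = cache.states[g]
        phi_norm = ab.propagate_error(state, ws[g].W, phi, floor)
        dw = ab.weight_update(state, ws[g].W, phi, floor)
        u_grads.append(ab.chain_through_reparam(dw, ws[g].U))
        grad_raw = ab.normalization_backward(cache.raw_patches[g], phi_norm)
        grad_map[:, g * cg : (g + 1) * cg] = fold_patches(
            grad_raw.reshape(B, P, -1), geom, (cg, H, W)
        )
    return (grad_map[0] if squeeze else grad_map), u_grads
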