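"""Network builders: block variants, the four-block net, widths and groups.

Four block variants are supported, each ending in a rectifier so the next
block's NMF module (if any) receives non-negative input:

- ``cnn``:       convolution -> [batchnorm] -> ReLU
- ``cnmf``:      convolutional NMF -> [batchnorm] -> ReLU
- ``cnn_1x1``:   convolution -> 1x1 convolution -> [batchnorm] -> ReLU
- ``cnmf_1x1``:  convolutional NMF -> 1x1 convolution -> [batchnorm] -> ReLU

The 1x1 mixing layer carries unconstrained (signed) weights: it locally
remixes the purely additive NMF features, including subtraction — the
cortical-column-analog interaction the NMF module itself cannot express.

The default classification net stacks four blocks that reduce a 28x28
input to 1x1 with channel progression 32 -> 64 -> 96 -> 10; batch
normalization appears in the first two blocks only, and the final 1x1
output is read as the class-score vector.  Width multipliers scale the
channel progression; channel groups split interior layers into independent
sub-layers at fixed width.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .conv_nmf import ConvGeometry
from .layers import (
    CNMF2d,
    Conv2d,
    BatchNorm2d,
    Flatten,
    Module,
    Parameter,
    ReLU,
    Sequential,
)
from .nmf_dynamics import LayerConfig

VARIANTS = ("cnn", "cnmf", "cnn_1x1", "cnmf_1x1")

#: base channel progression of the four-block net (final entry is the head)
BASE_CHANNELS = (32, 64, 96, 10)


@dataclass(frozen=True)
class BlockSpec:
    """One processing block: main module, optional 1x1 mix, norm, rectifier."""

    variant: str
    geom: ConvGeometry
    mix_channels: int | None = None
    mix_groups: int = 1
    batchnorm: bool = True
    activation: bool = True
    n_iters: int = 25

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        has_mix = self.variant.endswith("_1x1")
        if has_mix != (self.mix_channels is not None):
            raise ValueError("mix_channels must be given exactly for *_1x1 variants")

    @property
    def uses_nmf(self) -> bool:
        return self.variant.startswith("cnmf")

    @property
    def out_channels(self) -> int:
        return self.mix_channels if self.mix_channels is not None else self.geom.out_channels


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a block stack for a fixed input geometry."""

    blocks: tuple[BlockSpec, ...]
    in_channels: int = 3
    input_hw: int = 28
    n_classes: int = 10
    width_multiplier: int = 1
    groups: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a model needs at least one block")
        c = self.in_channels
        hw = (self.input_hw, self.input_hw)
        for b in self.blocks:
            if b.geom.in_channels != c:
                raise ValueError(
                    f"block expects {b.geom.in_channels} input channels, gets {c}"
                )
            hw = b.geom.out_shape(*hw)
            c = b.out_channels
        if hw != (1, 1):
            raise ValueError(
                f"blocks must reduce the {self.input_hw}x{self.input_hw} input to "
                f"1x1, got {hw[0]}x{hw[1]}"
            )
        if c != self.n_classes:
            raise ValueError(f"final block emits {c} channels, expected {self.n_classes}")


def _block_geometry(input_hw: int, n_blocks: int) -> list[tuple[int, int, int]]:
    """(kernel, stride, pad) per block halving the extent, final block collapsing it."""
    plan = []
    hw = input_hw
    for _ in range(n_blocks - 1):
        plan.append((3, 2, 1))
        hw = (hw + 2 * 1 - 3) // 2 + 1
    plan.append((hw, 1, 0))  # collapse the remaining extent
    return plan


def make_model_spec(
    variant: str = "cnmf_1x1",
    width: int = 1,
    groups: int = 1,
    in_channels: int = 3,
    input_hw: int = 28,
    n_classes: int = 10,
    n_iters: int = 25,
    channels: tuple[int, ...] = BASE_CHANNELS,
    grouped_blocks: tuple[int, ...] | None = None,
    group_nmf_only: bool = False,
    name: str = "",
) -> ModelSpec:
    """Build the standard block-stack spec for one variant/width/groups choice.

    Channel counts are ``channels`` scaled by ``width``.  For ``*_1x1``
    variants every block's 1x1 layer keeps the block width and the final
    1x1 maps to ``n_classes``; variants without the mix layer map to
    ``n_classes`` directly in the last block.  Groups apply to interior
    blocks only (``grouped_blocks``, default all but the first and last):
    the stem sees the raw image channels and the head emits class scores,
    neither of which is generally divisible.  With ``group_nmf_only`` the
    1x1 mixing layers stay dense while the NMF modules are grouped.
    """
    if width < 1 or groups < 1:
        raise ValueError("width and groups must be >= 1")
    n_blocks = len(channels)
    if grouped_blocks is None:
        grouped_blocks = tuple(range(1, n_blocks - 1))
    has_mix = variant.endswith("_1x1")
    scaled = [c * width for c in channels]
    plan = _block_geometry(input_hw, n_blocks)
    blocks = []
    c_in = in_channels
    for b, ((k, s, p), c_out) in enumerate(zip(plan, scaled)):
        last = b == n_blocks - 1
        g = groups if b in grouped_blocks else 1
        module_out = c_out if (has_mix or not last) else n_classes
        geom = ConvGeometry(
            kernel_h=k,
            kernel_w=k,
            in_channels=c_in,
            out_channels=module_out,
            stride_h=s,
            stride_w=s,
            pad=p,
            groups=g,
        )
        mix = (n_classes if last else c_out) if has_mix else None
        blocks.append(
            BlockSpec(
                variant=variant,
                geom=geom,
                mix_channels=mix,
                mix_groups=1 if (group_nmf_only or last or mix is None) else g,
                # normalize in the first two blocks only; the last block's
                # output is read directly as class scores (no norm, no ReLU)
                batchnorm=b < 2 and not last,
                activation=not last,
                n_iters=n_iters,
            )
        )
        c_in = blocks[-1].out_channels
    return ModelSpec(
        blocks=tuple(blocks),
        in_channels=in_channels,
        input_hw=input_hw,
        n_classes=n_classes,
        width_multiplier=width,
        groups=groups,
        name=name or f"{variant}_w{width}_g{groups}",
    )


def build_model(spec: ModelSpec, seed: int = 0) -> Sequential:
    """Instantiate the executable model for a spec (seeded initialization)."""
    rng = np.random.default_rng(seed)
    modules: list[Module] = []
    for b, block in enumerate(spec.blocks):
        if block.uses_nmf:
            modules.append(
                CNMF2d(block.geom, LayerConfig(n_iters=block.n_iters), rng=rng, name=f"b{b}.cnmf")
            )
        else:
            modules.append(Conv2d(block.geom, rng=rng, name=f"b{b}.conv"))
        if block.mix_channels is not None:
            mix_geom = ConvGeometry(
                kernel_h=1,
                kernel_w=1,
                in_channels=block.geom.out_channels,
                out_channels=block.mix_channels,
                groups=block.mix_groups,
            )
            modules.append(Conv2d(mix_geom, rng=rng, name=f"b{b}.mix1x1"))
        if block.batchnorm:
            modules.append(BatchNorm2d(block.out_channels, name=f"b{b}.bn"))
        if block.activation:
            modules.append(ReLU())
    modules.append(Flatten())
    return Sequential(*modules)


def count_parameters(spec: ModelSpec) -> dict:
    """Exact trainable-parameter count, itemized by component.

    Returns a dict with keys ``nmf`` (auxiliary U matrices), ``conv1x1``
    (mixing layers), ``cnn`` (non-1x1 convolutions), ``batchnorm``,
    ``total``, and ``cnn_nmf_ratio`` (= (cnn + conv1x1) / nmf; inf for
    NMF-free models).  Batchnorm is itemized separately so either ratio
    convention can be reported.
    """
    model = build_model(spec, seed=0)
    counts = {"nmf": 0, "conv1x1": 0, "cnn": 0, "batchnorm": 0}
    for m in model:
        n = sum(p.size for p in m.parameters())
        if isinstance(m, CNMF2d):
            counts["nmf"] += n
        elif isinstance(m, BatchNorm2d):
            counts["batchnorm"] += n
        elif isinstance(m, Conv2d):
            if m.geom.kernel_h == 1 and m.geom.kernel_w == 1:
                counts["conv1x1"] += n
            else:
                counts["cnn"] += n
    counts["total"] = sum(counts.values())
    signed = counts["cnn"] + counts["conv1x1"]
    counts["cnn_nmf_ratio"] = signed / counts["nmf"] if counts["nmf"] else float("inf")
    return counts


#: the five base configurations of the width x groups sweep: the four block
#: variants (groups applied to NMF and CNN layers alike) plus CNMF+1x1 with
#: grouping restricted to the NMF modules.
SWEEP_CONFIGURATIONS: tuple[tuple[str, dict], ...] = (
    ("cnn", {"variant": "cnn"}),
    ("cnmf", {"variant": "cnmf"}),
    ("cnn_1x1", {"variant": "cnn_1x1"}),
    ("cnmf_1x1", {"variant": "cnmf_1x1"}),
    ("cnmf_1x1_nmfgroups", {"variant": "cnmf_1x1", "group_nmf_only": True}),
)


def sweep_grid(
    width_factors: tuple[int, ...] = (1, 2, 4, 8),
    group_counts: tuple[int, ...] = (1, 2, 4, 8, 16),
    configurations: tuple[tuple[str, dict], ...] = SWEEP_CONFIGURATIONS,
    **spec_kwargs,
) -> list[tuple[ModelSpec, dict]]:
    """Cartesian width x groups x configuration grid with parameter accounting.

    Returns ``(spec, parameter_counts)`` pairs in deterministic order.
    Combinations whose group count does not divide a layer's channels are
    skipped with a warning.
    """
    if not width_factors or not group_counts:
        raise ValueError("width_factors and group_counts must be non-empty")
    out = []
    seen = set()
    for (cname, ckw), w, g in itertools.product(configurations, width_factors, group_counts):
        try:
            spec = make_model_spec(
                width=w, groups=g, name=f"{cname}_w{w}_g{g}", **{**ckw, **spec_kwargs}
            )
        except ValueError as exc:
            warnings.warn(f"skipping {cname} width={w} groups={g}: {exc}", stacklevel=2)
            continue
        key = (cname, w, g)
        if key in seen:
            continue
        seen.add(key)
        out.append((spec, count_parameters(spec)))
    return out
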