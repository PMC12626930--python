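"""Trainable layer modules with explicit forward/backward passes.

Small, dependency-free building blocks for the NMF networks: grouped
convolution, batch normalization, rectifier, the CNMF layer (iterative NMF
dynamics with the single-step approximate backward), and a sequential
container.  Gradients follow the loss-gradient convention and are
accumulated into each ``Parameter.grad``.
"""

from __future__ import annotations

import numpy as np

from . import conv_nmf
from .conv_nmf import ConvGeometry
from .nmf_dynamics import LayerConfig, LayerWeights


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:
        return f"Parameter({self.name!r}, shape={self.data.shape})"


class Module:
    """Base class: parameter registry plus forward/backward contract."""

    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[:] = 0.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train)


class CNMF2d(Module):
    """Convolutional NMF layer.

    Holds one unconstrained auxiliary matrix U per channel group; the
    non-negative column-normalized weight W is derived from U on every
    forward pass.  The backward pass touches only the final dynamics state
    per position (``stored_iterates == 1``), applying the single-step
    approximation.  Inputs must be non-negative (place a rectifier before
    this layer); violations raise immediately.
    """

    def __init__(
        self,
        geom: ConvGeometry,
        cfg: LayerConfig = LayerConfig(),
        rng: np.random.Generator | None = None,
        name: str = "cnmf",
    ) -> None:
        if cfg.epsilon != 1.0:
            import warnings

            warnings.warn(
                "CNMF2d backward assumes unit gain; epsilon != 1 is forward-only",
                stacklevel=2,
            )
        self.geom = geom
        self.cfg = cfg
        self.name = name
        rng = rng or np.random.default_rng(0)
        self.U = [
            Parameter(
                rng.normal(size=(geom.patch_size, geom.out_per_group)),
                name=f"{name}.U{g}",
            )
            for g in range(geom.groups)
        ]
        self._cache: conv_nmf.CNMFCache | None = None
        self.last_input_min: float = np.nan

    @property
    def stored_iterates(self) -> int:
        """Iterates kept per group for the backward pass: always one."""
        return 1 if self._cache is None else self._cache.stored_iterates_per_group

    def _weights(self) -> list[LayerWeights]:
        return [LayerWeights(U=p.data) for p in self.U]

    def parameters(self) -> list[Parameter]:
        return list(self.U)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self.last_input_min = float(np.min(x))
        out, cache = conv_nmf.cnmf_forward(
            x, self._weights(), self.geom, self.cfg, return_cache=True
        )
        self._cache = cache if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a cached training forward")
        grad_in, u_grads = conv_nmf.cnmf_backward(
            self._cache, self._weights(), self.geom, grad, self.cfg.floor
        )
        for p, g in zip(self.U, u_grads):
            p.grad += g
        return grad_in


class Conv2d(Module):
    """Standard (signed-weight) grouped convolution with bias, via im2col."""

    def __init__(
        self,
        geom: ConvGeometry,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        self.geom = geom
        self.name = name
        rng = rng or np.random.default_rng(0)
        fan_in = geom.patch_size
        self.weight = Parameter(
            rng.normal(scale=np.sqrt(2.0 / fan_in), size=(geom.out_channels, fan_in)),
            name=f"{name}.weight",
        )
        self.bias = Parameter(np.zeros(geom.out_channels), name=f"{name}.bias") if bias else None
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        B, C, H, W = x.shape
        g = self.geom
        oh, ow = g.out_shape(H, W)
        P = oh * ow
        out = np.empty((B, g.out_channels, oh, ow))
        patches_per_group = []
        cg, og = g.in_per_group, g.out_per_group
        for k in range(g.groups):
            patches = conv_nmf.extract_patches(x[:, k * cg : (k + 1) * cg], g)
            wk = self.weight.data[k * og : (k + 1) * og]  # (og, S)
            y = patches @ wk.T  # (B, P, og)
            out[:, k * og : (k + 1) * og] = y.transpose(0, 2, 1).reshape(B, og, oh, ow)
            patches_per_group.append(patches)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (patches_per_group, (C, H, W), (oh, ow)) if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        patches_per_group, in_shape, (oh, ow) = self._cache
        g = self.geom
        B = grad.shape[0]
        P = oh * ow
        cg, og = g.in_per_group, g.out_per_group
        C, H, W = in_shape
        grad_in = np.empty((B, C, H, W))
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        for k in range(g.groups):
            gy = grad[:, k * og : (k + 1) * og].reshape(B, og, P).transpose(0, 2, 1)
            patches = patches_per_group[k]  # (B, P, S)
            wk = self.weight.data[k * og : (k + 1) * og]
            self.weight.grad[k * og : (k + 1) * og] += np.einsum(
                "bpo,bps->os", gy, patches
            )
            gpatch = gy @ wk  # (B, P, S)
            grad_in[:, k * cg : (k + 1) * cg] = conv_nmf.fold_patches(
                gpatch, g, (cg, H, W)
            )
        return grad_in


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        self._cache = (xhat, inv, train) if train else None
        if not train:
            self._eval_inv = inv
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, _ = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        g = self.gamma.data[None, :, None, None] * inv[None, :, None, None]
        mean_dy = grad.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dyx = (grad * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (grad - mean_dy - xhat * mean_dyx)


class ReLU(Module):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class Flatten(Module):
    """(B, C, H, W) -> (B, C*H*W); used to read class scores off a 1x1 map."""

    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        self.modules = list(modules)

    def parameters(self) -> list[Parameter]:
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad

    def __iter__(self):
        return iter(self.modules)
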