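"""Supervised training: composite loss, Adam, plateau schedule, augmentation.

The loss combines cross-entropy with a mean-squared-error regularizer over
the predicted class distribution:

    ``L = -sum_i y_i log(yhat_i) + alpha * sum_i (y_i - yhat_i)^2``

with ``alpha = 0.5`` by default and ``yhat`` the softmax of the final 1x1
layer's output.  Training uses Adam from an initial learning rate of 1e-3;
the rate drops by a factor of 10 whenever the validation loss plateaus for
10 consecutive epochs and training stops once it falls below 1e-9 (or at
the epoch cap).  NMF layers are updated exclusively through their auxiliary
matrices U — the derived W is rebuilt each forward pass.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import Module, Parameter

LOG_EPS = 1e-12  # clamp for log(yhat) at the true class


@dataclass(frozen=True)
class LossConfig:
    """MSE weight alpha of the composite loss (>= 0; 0 is pure cross-entropy)."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol and augmentation switches.

    lr decreases by ``lr_factor`` when the validation loss fails to improve
    by at least ``plateau_threshold`` (relative) for ``plateau_patience``
    consecutive epochs; training stops below ``lr_min`` or at
    ``max_epochs``.
    """

    lr0: float = 1e-3
    plateau_patience: int = 10
    lr_factor: float = 10.0
    lr_min: float = 1e-9
    max_epochs: int = 500
    batch_size: int = 64
    seed: int = 0
    plateau_threshold: float = 1e-4
    loss: LossConfig = field(default_factory=LossConfig)
    flip: bool = False
    jitter: bool = False
    crop: bool = False
    crop_size: int = 28

    def __post_init__(self) -> None:
        if not (self.lr0 > self.lr_min > 0):
            raise ValueError("need lr0 > lr_min > 0")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def composite_loss(y: np.ndarray, yhat: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Batch-mean composite loss on predicted class distributions.

    ``y`` is one-hot, ``yhat`` a distribution per sample (rows sum to 1).
    Zero predicted probability at the true class is clamped at 1e-12.
    """
    y = np.atleast_2d(y)
    yhat = np.atleast_2d(yhat)
    ce = -(y * np.log(np.maximum(yhat, LOG_EPS))).sum(axis=1)
    mse = ((y - yhat) ** 2).sum(axis=1)
    return float((ce + cfg.alpha * mse).mean())


def loss_and_score_grad(
    scores: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the raw (pre-softmax) scores.

    With ``p = softmax(z)``, the cross-entropy term contributes ``p - y``
    and the MSE term ``p * (v - p.v)`` with ``v = 2 alpha (p - y)``; both
    are averaged over the batch.
    """
    p = softmax(scores)
    y = np.atleast_2d(y)
    loss = composite_loss(y, p, cfg)
    B = len(p)
    v = 2.0 * cfg.alpha * (p - y)
    grad = (p - y + p * (v - (v * p).sum(axis=1, keepdims=True))) / B
    return loss, grad


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * p.grad
            v[:] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Divide the learning rate when the monitored loss stops improving.

    "No improvement" means the loss fails to drop below
    ``best * (1 - threshold)``; after ``patience`` consecutive such epochs
    the rate is divided by ``factor`` and the counter resets.
    """

    def __init__(
        self, optimizer: Adam, patience: int = 10, factor: float = 10.0, threshold: float = 1e-4
    ) -> None:
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.threshold = threshold
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        """Record an epoch's metric; returns True if the lr was reduced."""
        if metric < self.best * (1 - self.threshold):
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.opt.lr /= self.factor
            self.num_bad = 0
            return True
        return False


def augment(
    images: np.ndarray,
    rng: np.random.Generator,
    flip: bool = False,
    jitter: bool = False,
    crop: bool = False,
    crop_size: int = 28,
    jitter_strength: float = 0.1,
) -> np.ndarray:
    """Per-sample augmentation: horizontal flip, color jitter, random crop.

    Flips are independent coin flips (p = 0.5); jitter scales brightness and
    contrast by factors in ``1 +- jitter_strength`` (and saturation for
    3-channel images); cropping takes a ``crop_size`` square at a uniform
    random offset (use :func:`center_crop` on the evaluation path).
    """
    x = np.asarray(images, dtype=float).copy()
    B, C, H, W = x.shape
    if flip:
        coins = rng.random(B) < 0.5
        x[coins] = x[coins][:, :, :, ::-1]
    if jitter:
        b = 1.0 + rng.uniform(-jitter_strength, jitter_strength, size=(B, 1, 1, 1))
        c = 1.0 + rng.uniform(-jitter_strength, jitter_strength, size=(B, 1, 1, 1))
        mean = x.mean(axis=(1, 2, 3), keepdims=True)
        x = np.maximum((x * b - mean) * c + mean, 0.0)
        if C == 3:
            s = 1.0 + rng.uniform(-jitter_strength, jitter_strength, size=(B, 1, 1, 1))
            gray = x.mean(axis=1, keepdims=True)
            x = np.maximum(gray + (x - gray) * s, 0.0)
    if crop:
        if H < crop_size or W < crop_size:
            raise ValueError(f"cannot crop {H}x{W} images to {crop_size}")
        oy = rng.integers(0, H - crop_size + 1, size=B)
        ox = rng.integers(0, W - crop_size + 1, size=B)
        out = np.empty((B, C, crop_size, crop_size))
        for i in range(B):
            out[i] = x[i, :, oy[i] : oy[i] + crop_size, ox[i] : ox[i] + crop_size]
        x = out
    return x


def center_crop(images: np.ndarray, crop_size: int) -> np.ndarray:
    """Deterministic center crop for the evaluation path."""
    H, W = images.shape[2:]
    oy, ox = (H - crop_size) // 2, (W - crop_size) // 2
    return images[:, :, oy : oy + crop_size, ox : ox + crop_size]


def evaluate(
    model: Module,
    images: np.ndarray,
    labels: np.ndarray,
    loss_cfg: LossConfig = LossConfig(),
    batch_size: int = 256,
) -> tuple[float, float]:
    """(loss, accuracy) of the model in evaluation mode."""
    n_classes = None
    losses, correct, total = [], 0, 0
    for start in range(0, len(images), batch_size):
        xb = images[start : start + batch_size]
        yb = labels[start : start + batch_size]
        scores = model.forward(xb, train=False)
        if n_classes is None:
            n_classes = scores.shape[1]
        p = softmax(scores)
        losses.append(composite_loss(one_hot(yb, n_classes), p, loss_cfg) * len(xb))
        correct += int((scores.argmax(axis=1) == yb).sum())
        total += len(xb)
    return float(np.sum(losses) / total), correct / total


def _snapshot(model: Module) -> list[np.ndarray]:
    return [p.data.copy() for p in model.parameters()]


def _restore(model: Module, snap: list[np.ndarray]) -> None:
    for p, d in zip(model.parameters(), snap):
        p.data[:] = d


def train(
    model: Module,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> list[dict]:
    """Train in place; returns the per-epoch log and restores the best-val weights.

    Each log entry carries ``epoch, train_loss, val_loss, val_acc, lr``.
    Aborts with a diagnostic on NaN loss.
    """
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    n_classes = model.forward(train_images[:1], train=False).shape[1]
    opt = Adam(model.parameters(), lr=cfg.lr0)
    sched = ReduceLROnPlateau(opt, cfg.plateau_patience, cfg.lr_factor, cfg.plateau_threshold)
    log: list[dict] = []
    best_val = np.inf
    best_snap = _snapshot(model)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_images))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = augment(
                train_images[idx], rng, cfg.flip, cfg.jitter, cfg.crop, cfg.crop_size
            )
            yb = one_hot(train_labels[idx], n_classes)
            model.zero_grad()
            scores = model.forward(xb, train=True)
            loss, gscore = loss_and_score_grad(scores, yb, cfg.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"loss={loss}, score range [{scores.min()}, {scores.max()}]"
                )
            model.backward(gscore)
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        val_x = center_crop(val_images, cfg.crop_size) if cfg.crop else val_images
        val_loss, val_acc = evaluate(model, val_x, val_labels, cfg.loss)
        log.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / seen,
                "val_loss": val_loss,
                "val_acc": val_acc,
                "lr": opt.lr,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  train {epoch_loss / seen:.4f}  "
                f"val {val_loss:.4f}  acc {val_acc:.3f}  lr {opt.lr:g}"
            )
        if val_loss < best_val:
            best_val = val_loss
            best_snap = _snapshot(model)
        sched.step(val_loss)
        if opt.lr < cfg.lr_min:
            break
    _restore(model, best_snap)
    return log
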