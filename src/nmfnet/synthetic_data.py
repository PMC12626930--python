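"""Seeded generators for NMF-structured synthetic data.

NMF assumes non-negative data composed additively from parts.  These
generators produce exactly that structure with known ground truth — a
low-rank non-negative product for factorization recovery, parts-based toy
images for end-to-end classification, and generic well-conditioned
instances for gradient checks — so every other module is testable without
external datasets.  All generators are pure functions of their parameters
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nmf_dynamics import LayerWeights, forward, LayerConfig


@dataclass(frozen=True)
class PartsImageSet:
    """Labeled non-negative images built from shared additive parts.

    images: (n, 1, size, size) non-negative; labels: (n,) ints in
    [0, n_classes); templates: (n_classes, 1, size, size) noiseless class
    prototypes (the additive combination defining each class).
    """

    images: np.ndarray
    labels: np.ndarray
    templates: np.ndarray
    seed: int

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]


def make_low_rank(
    M: int, S: int, I: int, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth factorization target ``X = H_true @ W_true.T`` plus noise.

    ``W_true`` (S x I) is column-normalized non-negative, ``H_true`` (M x I)
    non-negative; Gaussian noise of sd ``noise_sd`` is truncated at zero so
    X stays a valid factorization target.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if I > min(M, S):
        raise ValueError("rank I must be <= min(M, S) for identifiable tests")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.0, size=(S, I))
    W /= W.sum(axis=0)
    H = rng.uniform(0.1, 1.0, size=(M, I))
    X = H @ W.T
    if noise_sd > 0:
        X = np.maximum(X + rng.normal(scale=noise_sd, size=X.shape), 0.0)
    return X, W, H


def _blob(size: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * radius**2))


def make_parts_images(
    n_classes: int = 3,
    n_per_class: int = 200,
    size: int = 12,
    n_parts: int = 6,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> PartsImageSet:
    """Toy images where each class is a distinct additive combination of parts.

    ``n_parts`` shared Gaussian blobs are placed at distinct positions; each
    class is defined by a distinct subset of them.  Images are the class
    template with per-part amplitude jitter and pixel noise, both of scale
    ``noise_sd`` and clipped so pixels stay non-negative.  At zero noise the
    images equal their templates, so a nearest-template classifier is
    perfect by construction.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    if n_parts < n_classes:
        raise ValueError("need at least one part per class")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    radius = size / 8.0
    if 2 * radius > size:
        raise ValueError("parts larger than the image")
    # distinct part positions on an interior grid
    margin = radius
    centers = rng.uniform(margin, size - 1 - margin, size=(n_parts, 2))
    parts = np.stack([_blob(size, cy, cx, radius) for cy, cx in centers])
    # distinct subsets: class c always owns part c, plus extras
    k = max(2, n_parts // n_classes)
    subsets: list[np.ndarray] = []
    tries = 0
    while len(subsets) < n_classes:
        c = len(subsets)
        extra = rng.choice(
            [p for p in range(n_parts) if p != c], size=k - 1, replace=False
        )
        cand = np.sort(np.concatenate(([c], extra)))
        if any(np.array_equal(cand, s) for s in subsets):
            tries += 1
            if tries > 1000:
                raise ValueError("could not find distinct class subsets")
            continue
        subsets.append(cand)
    templates = np.stack([parts[s].sum(axis=0) for s in subsets])[:, None]
    n = n_classes * n_per_class
    labels = np.repeat(np.arange(n_classes), n_per_class)
    images = np.empty((n, 1, size, size))
    for idx, c in enumerate(labels):
        amps = 1.0 + rng.normal(scale=noise_sd, size=len(subsets[c]))
        amps = np.maximum(amps, 0.1)
        img = (amps[:, None, None] * parts[subsets[c]]).sum(axis=0)
        if noise_sd > 0:
            img = img + rng.normal(scale=noise_sd, size=img.shape)
        images[idx, 0] = np.maximum(img, 0.0)
    order = rng.permutation(n)
    images, labels = images[order], labels[order]
    assert images.min() >= 0
    return PartsImageSet(images=images, labels=labels, templates=templates, seed=seed)


def nearest_template_accuracy(data: PartsImageSet) -> float:
    """Accuracy of classifying each image by its closest class template."""
    flat = data.images.reshape(len(data.images), -1)
    temps = data.templates.reshape(data.n_classes, -1)
    d = ((flat[:, None, :] - temps[None]) ** 2).sum(axis=2)
    return float((d.argmin(axis=1) == data.labels).mean())


def make_gradcheck_instance(
    S: int, I: int, N: int = 25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generic well-conditioned instance ``(x, U, phi_upper)`` for gradient checks.

    x is strictly positive and normalized; U has mixed signs with entries
    bounded away from zero (no subgradient ambiguity, no zero columns);
    phi_upper is generic Gaussian.  The forward reconstruction denominators
    are asserted to stay far from the floor.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.5, 1.5, size=S)
    x /= x.sum()
    mag = rng.uniform(0.2, 1.5, size=(S, I))
    U = mag * rng.choice([-1.0, 1.0], size=(S, I))
    phi = rng.normal(size=I)
    state = forward(x, LayerWeights(U=U), LayerConfig(n_iters=N))
    assert state.R.min() > 1e-6, "degenerate gradcheck instance"
    return x, U, phi
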