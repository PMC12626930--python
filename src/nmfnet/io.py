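"""Matrix and tensor I/O: delimited text, npz archives, optional PNG images."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a dense matrix from delimited text (.csv or .tsv by suffix)."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    X = np.loadtxt(path, delimiter=delim, ndmin=2)
    return X


def write_matrix(path: str | Path, X: np.ndarray) -> None:
    """Write a dense matrix as delimited text (.csv or .tsv by suffix)."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    np.savetxt(path, np.atleast_2d(X), delimiter=delim, fmt="%.12g")


def write_archive(path: str | Path, **arrays: np.ndarray) -> None:
    """Write named arrays to a portable .npz archive."""
    np.savez_compressed(path, **arrays)


def read_archive(path: str | Path) -> dict[str, np.ndarray]:
    """Read all arrays from a .npz archive into a dict."""
    with np.load(path) as f:
        return {k: f[k] for k in f.files}


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG image as a float (C, H, W) array scaled to [0, 1].

    Requires pillow; images are the only input format that needs it.
    """
    from PIL import Image

    arr = np.asarray(Image.open(path), dtype=float) / 255.0
    if arr.ndim == 2:
        arr = arr[None]
    else:
        arr = arr.transpose(2, 0, 1)
    return arr


def load_image_set(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load (images, labels) from an archive written by the synth command."""
    d = read_archive(path)
    return d["images"], d["labels"].astype(int)
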