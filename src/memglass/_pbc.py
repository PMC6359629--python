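"""Minimum-image helpers for orthorhombic periodic boxes (Å units)."""

from __future__ import annotations

import numpy as np


def minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    ``vec`` has shape (..., 3); ``box`` broadcasts against it.
    """
    vec = np.asarray(vec, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    return vec - box * np.round(vec / box)


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance matrix, shape ``(len(a), len(b))``."""
    d = minimum_image(a[:, None, :] - b[None, :, :], box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def wrap_into_box(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [-box/2, box/2) per axis."""
    return minimum_image(coords, box)
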