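"""Haralick gray-level co-occurrence texture on the decimated working image.

At ~4 µm/px each pixel is on the order of a cell, so co-occurrence
statistics of neighbouring pixels describe local (cell-to-cell)
heterogeneity, complementing the region-scale Voronoï and quadrat
features.  Only pixel pairs entirely inside the ROI contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GLCM",
    "DEFAULT_OFFSETS",
    "quantize_image",
    "compute_glcm",
    "haralick_energy",
    "haralick_correlation",
    "haralick_extended",
]

# distance-1 displacements at 0°, 45°, 90°, 135° as (dx, dy), y downward
DEFAULT_OFFSETS = ((1, 0), (1, 1), (0, 1), (-1, 1))

INVALID = -1  # quantized label for pixels outside the ROI


@dataclass(frozen=True)
class GLCM:
    """Gray-level co-occurrence matrix: joint probabilities of level pairs."""

    levels: int
    matrix: np.ndarray  # (G, G), sums to 1
    offsets: tuple
    symmetric: bool

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (self.levels, self.levels):
            raise ValueError("GLCM matrix must be G×G")
        if m.min() < 0 or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM entries must be nonnegative and sum to 1")
        object.__setattr__(self, "matrix", m)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",")


def quantize_image(image: np.ndarray, levels: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Linearly bin a grayscale image into ``levels`` levels inside a mask.

    The bin edges span [min, max] of the in-mask values; a constant
    image collapses into a single occupied level (valid).  Pixels
    outside the mask receive the sentinel label -1 and never take part
    in co-occurring pairs.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    img = np.asarray(image, float)
    if mask is None:
        mask = np.ones(img.shape, bool)
    else:
        mask = np.asarray(mask, bool)
        if mask.shape != img.shape:
            raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("ROI is empty")
    vals = img[mask]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.full(img.shape, INVALID, dtype=np.int64)
    if hi - lo < 1e-12:
        q[mask] = 0
    else:
        q[mask] = np.clip(((img[mask] - lo) / (hi - lo) * levels).astype(np.int64), 0, levels - 1)
    return q


def compute_glcm(
    quantized: np.ndarray,
    offsets=DEFAULT_OFFSETS,
    symmetric: bool = True,
    levels: int | None = None,
) -> GLCM:
    """Count co-occurring level pairs at each offset and normalize.

    For offset (dx, dy) the pair is (pixel, pixel shifted by dx columns
    and dy rows); pairs with either pixel invalid (outside the ROI) are
    dropped.  Counts are symmetrized if requested, summed over offsets,
    then normalized to joint probabilities.  Raises if no valid pair
    exists.
    """
    q = np.asarray(quantized)
    if levels is None:
        levels = int(q.max()) + 1 if q.max() >= 0 else 0
    if levels < 1:
        raise ValueError("no valid pixels in the quantized image")
    g = int(levels)
    acc = np.zeros((g, g), dtype=np.int64)
    h, w = q.shape
    for dx, dy in offsets:
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        if y0 >= y1 or x0 >= x1:
            continue
        a = q[y0:y1, x0:x1]
        b = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        valid = (a != INVALID) & (b != INVALID)
        if not valid.any():
            continue
        pairs = np.bincount(a[valid] * g + b[valid], minlength=g * g).reshape(g, g)
        acc += pairs
    if acc.sum() == 0:
        raise ValueError("no valid pixel pair at any offset")
    mat = acc.astype(float)
    if symmetric:
        mat = mat + mat.T
    return GLCM(g, mat / mat.sum(), tuple(tuple(o) for o in offsets), symmetric)


def haralick_energy(glcm: GLCM) -> float:
    """Angular second moment Σ p(i,j)² — in (0, 1], 1 for a constant image."""
    return float(np.sum(glcm.matrix**2))


def haralick_correlation(glcm: GLCM) -> float:
    """Correlation of the co-occurring level pair — in [−1, 1].

    Σ (i−µᵢ)(j−µⱼ) p(i,j) / (σᵢ σⱼ) with marginal means/SDs of the
    GLCM.  Degenerate case σᵢσⱼ = 0 (single occupied level) returns 0
    by convention.
    """
    p = glcm.matrix
    g = glcm.levels
    i = np.arange(g, dtype=float)
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = float(i @ pi), float(i @ pj)
    var_i = float(((i - mu_i) ** 2) @ pi)
    var_j = float(((i - mu_j) ** 2) @ pj)
    denom = np.sqrt(var_i * var_j)
    if denom <= 0:
        return 0.0
    cov = float((np.outer(i - mu_i, i - mu_j) * p).sum())
    return cov / denom


def haralick_extended(glcm: GLCM) -> dict:
    """Additional co-occurrence descriptors (exploratory, not validated)."""
    p = glcm.matrix
    g = glcm.levels
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    d = np.abs(i - j)
    with np.errstate(divide="ignore"):
        entropy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))
    return {
        "contrast": float(np.sum(p * d.astype(float) ** 2)),
        "dissimilarity": float(np.sum(p * d)),
        "homogeneity": float(np.sum(p / (1.0 + d.astype(float) ** 2))),
        "entropy": entropy,
        "maximum_probability": float(p.max()),
    }
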