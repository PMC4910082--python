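"""Grey-level co-occurrence matrix (GLCM) features.

For each displacement d in 1..5 px the co-occurrence matrices of the
four directions 0, 45, 90 and 135 degrees are built, symmetrized,
averaged and normalized to sum 1; rotation by a right angle permutes
the four directions, so the averaged matrix — and hence the features —
is rotation invariant.  Directional offsets follow the per-axis
convention (0 deg = (0, d), 45 deg = (-d, d), 90 deg = (-d, 0),
135 deg = (-d, -d)), i.e. diagonal neighbours step d cells along each
axis.  From each averaged matrix four Haralick-style
statistics are taken: contrast, correlation, energy and homogeneity,
giving 5 x 4 = 20 features ordered by displacement.

Intensities are first quantized to ``levels`` equal-width grey bins
spanning the image's own [min, max] range (8 levels by default, the
convention of Matlab's ``graycomatrix``).  A constant image maps to a
single-cell GLCM: contrast 0, energy 1, homogeneity 1, and correlation 1
by the zero-variance convention.
"""

from __future__ import annotations

import numpy as np

DISPLACEMENTS = (1, 2, 3, 4, 5)
#: (row, col) unit steps of the four directions, scaled by displacement
DIRECTION_STEPS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
STAT_NAMES = ("contrast", "correlation", "energy", "homogeneity")
DEFAULT_LEVELS = 8

GLCM_NAMES = [
    f"glcm:d{d}_{stat}" for d in DISPLACEMENTS for stat in STAT_NAMES
]


def quantize(gray: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Equal-width quantization of [min, max] into ``levels`` bins."""
    gray = np.asarray(gray, dtype=np.float64)
    lo, hi = gray.min(), gray.max()
    if hi == lo:
        return np.zeros(gray.shape, dtype=np.uint8)
    idx = np.floor((gray - lo) / (hi - lo) * levels).astype(np.int64)
    return np.minimum(idx, levels - 1).astype(np.uint8)


def _matrix_stats(p: np.ndarray) -> tuple:
    """Contrast, correlation, energy, homogeneity of a normalized GLCM."""
    g = p.shape[0]
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    contrast = float(np.sum(p * (i - j) ** 2))
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    var_i = float(np.sum(p * (i - mu_i) ** 2))
    var_j = float(np.sum(p * (j - mu_j) ** 2))
    if var_i > 0 and var_j > 0:
        correlation = float(
            np.sum(p * (i - mu_i) * (j - mu_j)) / np.sqrt(var_i * var_j)
        )
    else:
        correlation = 1.0  # zero-variance convention
    return contrast, correlation, energy, homogeneity


def averaged_glcm(
    gray: np.ndarray, displacement: int, levels: int = DEFAULT_LEVELS
) -> np.ndarray:
    """Direction-averaged, symmetrized, normalized GLCM at one displacement."""
    q = quantize(gray, levels)
    h, w = q.shape
    if displacement >= min(h, w):
        raise ValueError(
            f"displacement {displacement} does not fit a {h}x{w} image"
        )
    avg = np.zeros((levels, levels))
    for ur, uc in DIRECTION_STEPS:
        dr, dc = ur * displacement, uc * displacement
        src_r = slice(max(0, -dr), h - max(0, dr))
        src_c = slice(max(0, -dc), w - max(0, dc))
        dst_r = slice(max(0, dr), h - max(0, -dr))
        dst_c = slice(max(0, dc), w - max(0, -dc))
        a = q[src_r, src_c].ravel().astype(np.int64)
        b = q[dst_r, dst_c].ravel().astype(np.int64)
        mat = np.zeros((levels, levels))
        np.add.at(mat, (a, b), 1.0)
        avg += mat + mat.T  # symmetrize
    avg /= len(DIRECTION_STEPS)
    total = avg.sum()
    if total > 0:
        avg /= total
    return avg


def glcm_features(
    img: np.ndarray, levels: int = DEFAULT_LEVELS
) -> np.ndarray:
    """The 20 GLCM features (5 displacements x 4 statistics)."""
    gray = np.asarray(img, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("GLCM features require a 2-D greyscale image")
    if min(gray.shape) <= max(DISPLACEMENTS):
        raise ValueError(
            f"image {gray.shape} too small for displacement "
            f"{max(DISPLACEMENTS)}"
        )
    out = np.empty(len(GLCM_NAMES))
    for k, d in enumerate(DISPLACEMENTS):
        p = averaged_glcm(gray, d, levels)
        out[4 * k : 4 * k + 4] = _matrix_stats(p)
    return out
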