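"""Perception-motivated (Tamura-style) texture features.

Five attributes modelled on how humans describe texture: coarseness,
contrast, directionality, line-likeness and roughness.  Definitions:

* coarseness — per pixel, average intensities over windows of size
  2^k (k = 1..5) and find the k whose horizontal or vertical
  average-difference at offset 2^(k-1) is largest; coarseness is the
  mean of the winning window sizes 2^k.
* contrast — sigma / kurtosis^(1/4) with kurtosis = mu4 / sigma^4;
  spreads of the grey histogram are penalised when polarised.
* directionality — concentration of the gradient-orientation histogram
  (Prewitt gradients, orientations modulo pi, 16 bins) over pixels whose
  gradient magnitude exceeds 12% of the maximum; scaled so a uniform
  orientation histogram scores 0 and a single orientation scores 1.
* line-likeness — average orientation-difference cosine of edge-pixel
  pairs four pixels apart along the local edge direction.
* roughness — coarseness + contrast.

All internal settings (window range, magnitude threshold fraction,
orientation bin count, co-occurrence distance) are keyword arguments.
Degenerate (zero-variance) images get contrast = directionality = 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

PERCEPTUAL_NAMES = [
    "perceptual:coarseness",
    "perceptual:contrast",
    "perceptual:directionality",
    "perceptual:line_likeness",
    "perceptual:roughness",
]

_PREWITT_H = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=np.float64)


def _reflect_indices(idx: np.ndarray, n: int) -> np.ndarray:
    m = np.mod(idx, 2 * n)
    return np.where(m >= n, 2 * n - 1 - m, m)


def coarseness(gray: np.ndarray, k_max: int = 5) -> float:
    """Mean best averaging-window size (2^k) over interior pixels.

    The mean excludes a border margin where the largest windows hang
    over the edge and reflection padding would dominate the
    differences.
    """
    h, w = gray.shape
    rows = np.arange(h)
    cols = np.arange(w)
    best_e = np.full((h, w), -1.0)
    best_size = np.full((h, w), 2.0)
    for k in range(1, k_max + 1):
        avg = ndi.uniform_filter(gray, size=2**k, mode="reflect")
        o = 2 ** (k - 1)
        cp = _reflect_indices(cols + o, w)
        cm = _reflect_indices(cols - o, w)
        rp = _reflect_indices(rows + o, h)
        rm = _reflect_indices(rows - o, h)
        e_h = np.abs(avg[:, cp] - avg[:, cm])
        e_v = np.abs(avg[rp, :] - avg[rm, :])
        e = np.maximum(e_h, e_v)
        better = e > best_e
        best_e = np.where(better, e, best_e)
        best_size = np.where(better, float(2**k), best_size)
    m = min(2**k_max, min(h, w) // 4)
    interior = best_size[m : h - m, m : w - m]
    if interior.size == 0:
        interior = best_size
    return float(interior.mean())


def contrast(gray: np.ndarray) -> float:
    """sigma / kurtosis^(1/4); 0 for a flat image."""
    d = gray - gray.mean()
    var = np.mean(d**2)
    if var == 0:
        return 0.0
    kurt = np.mean(d**4) / var**2
    return float(np.sqrt(var) / kurt**0.25)


def _gradients(gray: np.ndarray):
    dh = ndi.convolve(gray, _PREWITT_H, mode="reflect") / 3.0
    dv = ndi.convolve(gray, _PREWITT_H.T, mode="reflect") / 3.0
    mag = (np.abs(dh) + np.abs(dv)) / 2.0
    theta = np.mod(np.arctan2(dv, dh), np.pi)
    return mag, theta


def directionality(
    gray: np.ndarray,
    n_bins: int = 16,
    threshold_frac: float = 0.12,
) -> float:
    """Sharpness of the gradient-orientation histogram, in [0, 1]."""
    mag, theta = _gradients(gray)
    peak_mag = mag.max()
    if peak_mag == 0:
        return 0.0
    mask = mag >= threshold_frac * peak_mag
    if not mask.any():
        return 0.0
    bins = np.minimum((theta[mask] / np.pi * n_bins).astype(int), n_bins - 1)
    hist = np.bincount(bins, minlength=n_bins).astype(np.float64)
    hist /= hist.sum()
    peak = int(np.argmax(hist))
    d = np.abs(np.arange(n_bins) - peak)
    d = np.minimum(d, n_bins - d) / (n_bins / 2.0)  # circular, in [0, 1]
    spread = float(np.sum(hist * d**2))
    uniform_spread = float(np.mean(d**2))
    return max(0.0, 1.0 - spread / uniform_spread)


def line_likeness(
    gray: np.ndarray,
    n_bins: int = 16,
    threshold_frac: float = 0.12,
    distance: int = 4,
) -> float:
    """Mean cos of orientation differences along local edge directions."""
    mag, theta = _gradients(gray)
    peak_mag = mag.max()
    if peak_mag == 0:
        return 0.0
    h, w = gray.shape
    edge = mag >= threshold_frac * peak_mag
    rr, cc = np.nonzero(edge)
    if rr.size == 0:
        return 0.0
    ang = theta[rr, cc]
    # step along the edge (perpendicular to the gradient)
    tr = rr + np.round(distance * np.cos(ang)).astype(int)
    tc = cc + np.round(distance * np.sin(ang)).astype(int)
    ok = (tr >= 0) & (tr < h) & (tc >= 0) & (tc < w)
    ok &= edge[np.clip(tr, 0, h - 1), np.clip(tc, 0, w - 1)]
    if not ok.any():
        return 0.0
    bins = np.minimum((theta / np.pi * n_bins).astype(int), n_bins - 1)
    bi = bins[rr[ok], cc[ok]]
    bj = bins[tr[ok], tc[ok]]
    return float(np.mean(np.cos((bi - bj) * 2.0 * np.pi / n_bins)))


def perceptual_features(
    img: np.ndarray,
    n_bins: int = 16,
    threshold_frac: float = 0.12,
    k_max: int = 5,
) -> np.ndarray:
    """The five perception-like features."""
    gray = np.asarray(img, dtype=np.float64)
    if gray.ndim != 2 or min(gray.shape) < 2**k_max:
        raise ValueError(
            f"perceptual features require a 2-D image of at least "
            f"{2**k_max}x{2**k_max} pixels"
        )
    crs = coarseness(gray, k_max=k_max)
    con = contrast(gray)
    drc = directionality(gray, n_bins=n_bins, threshold_frac=threshold_frac)
    lin = line_likeness(gray, n_bins=n_bins, threshold_frac=threshold_frac)
    return np.array([crs, con, drc, lin, crs + con])
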