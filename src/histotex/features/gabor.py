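"""Gabor filter bank features.

A bank of quadrature Gabor filters at six orientations (0..150 degrees
in 30-degree steps) and six wavelengths (2, 4, 6, 8, 10, 12 px/cycle —
the scale range of nuclei, cells and collagen fibres in histology at
~0.5 um/px) is applied to the greyscale image.  The feature for one
(wavelength, orientation) pair is the mean of the filter-response
magnitude image; averaging over the six orientations per wavelength
yields 6 rotation-invariant features ordered by wavelength.

Filter construction: Gaussian envelope with sigma = 0.56 * wavelength
along the wave direction (one-octave half-response bandwidth) and
spatial aspect ratio 0.5; the even (cosine) component is DC-corrected
with an envelope-weighted offset so constant images give zero response;
kernels are truncated at three standard deviations of the wider
envelope axis, and the image is reflect-padded before convolution.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

WAVELENGTHS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
ORIENTATIONS_DEG = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
SIGMA_FACTOR = 0.56  # sigma / wavelength, one-octave bandwidth
ASPECT_RATIO = 0.5  # envelope sigma ratio (perpendicular axis is wider)
TRUNCATE = 3.0  # half-size in units of the wider envelope sigma

GABOR_NAMES = [f"gabor:wavelength{int(w)}" for w in WAVELENGTHS]


def gabor_kernel_pair(wavelength: float, theta_deg: float):
    """Zero-DC even and odd Gabor kernels for one (wavelength, angle)."""
    sigma = SIGMA_FACTOR * wavelength
    sigma_wide = sigma / ASPECT_RATIO
    hs = int(np.ceil(TRUNCATE * sigma_wide))
    y, x = np.mgrid[-hs : hs + 1, -hs : hs + 1].astype(np.float64)
    theta = np.deg2rad(theta_deg)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-(xr**2 + (ASPECT_RATIO * yr) ** 2) / (2.0 * sigma**2))
    phase = 2.0 * np.pi * xr / wavelength
    cos_part = np.cos(phase)
    dc = (envelope * cos_part).sum() / envelope.sum()
    even = envelope * (cos_part - dc)
    odd = envelope * np.sin(phase)
    return even, odd


def _magnitude_response(gray: np.ndarray, even: np.ndarray, odd: np.ndarray):
    hs = even.shape[0] // 2
    padded = np.pad(gray, hs, mode="reflect")
    re = fftconvolve(padded, even, mode="valid")
    im = fftconvolve(padded, odd, mode="valid")
    return np.sqrt(re**2 + im**2)


def gabor_features(img: np.ndarray) -> np.ndarray:
    """Six orientation-averaged Gabor magnitude means, one per wavelength."""
    gray = np.asarray(img, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("Gabor features require a 2-D greyscale image")
    max_kernel = 2 * int(np.ceil(TRUNCATE * SIGMA_FACTOR * max(WAVELENGTHS)
                                 / ASPECT_RATIO)) + 1
    if min(gray.shape) < max_kernel:
        raise ValueError(
            f"image {gray.shape} smaller than the largest Gabor kernel "
            f"({max_kernel}px)"
        )
    out = np.empty(len(WAVELENGTHS))
    for i, lam in enumerate(WAVELENGTHS):
        acc = 0.0
        for theta in ORIENTATIONS_DEG:
            even, odd = gabor_kernel_pair(lam, theta)
            acc += _magnitude_response(gray, even, odd).mean()
        out[i] = acc / len(ORIENTATIONS_DEG)
    return out
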