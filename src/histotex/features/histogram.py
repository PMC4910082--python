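"""First-order (grey-level histogram) texture features.

Two descriptor sets built from the distribution of pixel intensities:

* ``histogram_lower`` — mean, population variance, skewness (mu3/sigma^3),
  non-excess kurtosis (mu4/sigma^4) and the raw 5th central moment.
* ``histogram_higher`` — the raw central moments mu2..mu11.  Because the
  mean is excluded, this set is invariant to adding a constant to every
  pixel, which makes it insensitive to overall staining intensity.

Moments are computed directly over all pixels treated as one sample
rather than on a binned histogram, removing the bin-count parameter.
Zero-variance images get skewness = kurtosis = 0 by convention so that
degenerate tiles (e.g. empty background) still yield finite vectors.
"""

from __future__ import annotations

import numpy as np

HISTOGRAM_LOWER_NAMES = [
    "histogram_lower:mean",
    "histogram_lower:variance",
    "histogram_lower:skewness",
    "histogram_lower:kurtosis",
    "histogram_lower:moment5",
]

HISTOGRAM_HIGHER_NAMES = [f"histogram_higher:moment{k}" for k in range(2, 12)]


def histogram_lower(img: np.ndarray) -> np.ndarray:
    """Five lower-order statistics of the intensity distribution."""
    x = np.asarray(img, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty image")
    mean = x.mean()
    d = x - mean
    var = np.mean(d**2)
    if var > 0:
        sigma = np.sqrt(var)
        skew = np.mean(d**3) / sigma**3
        kurt = np.mean(d**4) / sigma**4
    else:
        skew = 0.0
        kurt = 0.0
    mu5 = np.mean(d**5)
    return np.array([mean, var, skew, kurt, mu5])


def histogram_higher(img: np.ndarray) -> np.ndarray:
    """Raw central moments mu2..mu11 (ten features, mean-shift invariant)."""
    x = np.asarray(img, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty image")
    d = x - x.mean()
    return np.array([np.mean(d**k) for k in range(2, 12)])
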