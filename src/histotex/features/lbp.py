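"""Rotation-invariant local binary pattern histogram Fourier (LBP-HF) features.

The (8, 1) LBP operator thresholds the eight neighbours on a unit circle
around each interior pixel at the centre value (neighbour >= centre gives
bit 1); diagonal samples fall between pixels and are bilinearly
interpolated.  The 256-bin code histogram is reduced to *uniform*
patterns (at most two circular 0/1 transitions).  Uniform patterns with
1..7 set bits form rotation orbits of eight members each; image rotation
cyclically shifts the histogram mass inside an orbit, so the DFT
magnitudes of each orbit histogram are rotation invariant.  Keeping
frequencies 0..4 (floor(8/2) + 1 = 5 values) per orbit plus the two
constant patterns (all-0, all-1) and the pooled non-uniform bin yields
7 x 5 + 3 = 38 features.
"""

from __future__ import annotations

import numpy as np

P = 8  # neighbours on the ring
R = 1.0  # ring radius in pixels
N_FREQ = P // 2 + 1  # DFT magnitudes kept per orbit

LBP_HF_NAMES = (
    [f"lbp:hf_n{n}_f{u}" for n in range(1, P) for u in range(N_FREQ)]
    + ["lbp:all_zeros", "lbp:all_ones", "lbp:non_uniform"]
)

N_FEATURES = len(LBP_HF_NAMES)  # 38


def _circular_transitions(code: int) -> int:
    bits = [(code >> k) & 1 for k in range(P)]
    return sum(bits[k] != bits[(k + 1) % P] for k in range(P))


def _build_tables():
    """Map each 8-bit code to (orbit id, rotation index).

    Orbit ids: 0 = all-zeros, 1..7 = uniform with that many set bits,
    8 = all-ones, -1 = non-uniform.  The rotation index of a uniform
    pattern is the ring position where its run of ones starts.
    """
    orbit = np.full(256, -1, dtype=int)
    rot = np.zeros(256, dtype=int)
    orbit[0] = 0
    orbit[255] = P
    for code in range(1, 255):
        if _circular_transitions(code) != 2:
            continue
        n = bin(code).count("1")
        bits = [(code >> k) & 1 for k in range(P)]
        # run start: a 1 whose circular predecessor is 0
        start = next(k for k in range(P) if bits[k] and not bits[k - 1])
        orbit[code] = n
        rot[code] = start
    return orbit, rot


_ORBIT, _ROT = _build_tables()


def _sample_ring(gray: np.ndarray) -> np.ndarray:
    """Neighbour samples for every interior pixel; shape (8, H-2, W-2)."""
    h, w = gray.shape
    samples = np.empty((P, h - 2, w - 2))
    for k in range(P):
        angle = 2.0 * np.pi * k / P
        dx = R * np.cos(angle)
        dy = -R * np.sin(angle)
        if abs(dx - round(dx)) < 1e-12 and abs(dy - round(dy)) < 1e-12:
            di, dj = int(round(dy)), int(round(dx))
            samples[k] = gray[1 + di : h - 1 + di, 1 + dj : w - 1 + dj]
        else:
            i0, j0 = int(np.floor(dy)), int(np.floor(dx))
            fy, fx = dy - i0, dx - j0
            block = lambda di, dj: gray[
                1 + di : h - 1 + di, 1 + dj : w - 1 + dj
            ]
            samples[k] = (1 - fy) * (
                (1 - fx) * block(i0, j0) + fx * block(i0, j0 + 1)
            ) + fy * ((1 - fx) * block(i0 + 1, j0) + fx * block(i0 + 1, j0 + 1))
    return samples


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """Raw (8, 1) LBP codes 0..255 for every interior pixel."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("LBP requires a 2-D image of at least 3x3 pixels")
    centre = gray[1:-1, 1:-1]
    samples = _sample_ring(gray)
    codes = np.zeros(centre.shape, dtype=np.int64)
    for k in range(P):
        codes |= (samples[k] >= centre).astype(np.int64) << k
    return codes


def lbp_hf(img: np.ndarray) -> np.ndarray:
    """The 38 LBP-HF features of a greyscale image."""
    codes = lbp_codes(img)
    hist = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    hist /= hist.sum()

    orbit_hist = np.zeros((P - 1, P))  # rows: n = 1..7, cols: rotation
    uniform = _ORBIT > 0
    for code in np.nonzero(uniform & (_ORBIT < P))[0]:
        orbit_hist[_ORBIT[code] - 1, _ROT[code]] += hist[code]

    features = np.empty(N_FEATURES)
    for n in range(P - 1):
        spectrum = np.fft.fft(orbit_hist[n])
        features[n * N_FREQ : (n + 1) * N_FREQ] = np.abs(spectrum[:N_FREQ])
    features[-3] = hist[0]  # all-zeros pattern
    features[-2] = hist[255]  # all-ones pattern
    features[-1] = hist[_ORBIT == -1].sum()  # pooled non-uniform mass
    return features
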