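"""Seeded synthetic tile datasets emulating an 8-class histology benchmark.

Eight texture families stand in for the eight tissue classes of an H&E
colorectal-cancer tile collection (tumour epithelium, simple stroma,
complex stroma, immune cells, debris, mucosal glands, adipose tissue,
background).  The mapping is cosmetic — what matters is that the
families differ in their second-order statistics (blob scale,
orientation structure, sparsity, cell boundaries) while their per-tile
mean intensities are drawn from overlapping ranges, mirroring the
benchmark's design of containing both bright and dark samples of every
class so that no mean-intensity shortcut exists.

All randomness flows from explicit seeds (per-tile generators are
seeded from ``(master_seed, class, index)``); there is no global random
state.  Greyscale textures are tinted with an H&E-like pink/purple
palette plus per-tile jitter so that the RGB-to-grey conversion of the
I/O layer is exercised nontrivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .image_io import LabeledTileSet

__all__ = [
    "CLASS_NAMES",
    "FAMILY_KINDS",
    "MosaicSpec",
    "generate_tile",
    "generate_dataset",
    "generate_mosaic",
]

CLASS_NAMES = [
    "01_tumour_epithelium",
    "02_stroma_simple",
    "03_stroma_complex",
    "04_immune_cells",
    "05_debris",
    "06_mucosa",
    "07_adipose",
    "08_background",
]

FAMILY_KINDS = {
    1: "blob_field",
    2: "oriented_grating",
    3: "mixed",
    4: "speckle",
    5: "coarse_patches",
    6: "ring_motifs",
    7: "cell_mosaic",
    8: "constant",
}

# per-family range the tile's base (mean) intensity is drawn from;
# all ranges pairwise intersect, so mean alone separates no pair
_BASE_RANGE = {f: (0.35, 0.65) for f in range(1, 8)}
_BASE_RANGE[8] = (0.50, 0.90)

_HE_TINT = np.array([1.00, 0.72, 0.88])  # pink/purple H&E-like multipliers


def _smooth_noise(rng, size: int, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian-filtered white noise."""
    n = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma,
                            mode="reflect")
    sd = n.std()
    return n / sd if sd > 0 else n


def _coords(size: int):
    return np.mgrid[0:size, 0:size].astype(np.float64)


def _nearest_distances(size: int, centers: np.ndarray, k: int = 2):
    yy, xx = _coords(size)
    d = np.sqrt(
        (yy[None] - centers[:, 0, None, None]) ** 2
        + (xx[None] - centers[:, 1, None, None]) ** 2
    )
    d.sort(axis=0)
    return d[:k]


def _gray_texture(family: int, size: int, rng, overrides: dict) -> np.ndarray:
    lo, hi = _BASE_RANGE[family]
    base = rng.uniform(lo, hi)
    kind = FAMILY_KINDS[family]

    if kind == "constant":
        return np.full((size, size), base)

    if kind == "blob_field":
        # dense mid-scale blobs with fine-scale substructure (nuclei-like)
        tex = 0.20 * _smooth_noise(rng, size, 2.0)
        tex += 0.10 * _smooth_noise(rng, size, 1.0)
    elif kind == "oriented_grating":
        wavelength = rng.uniform(6.0, 10.0)
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        n = rng.standard_normal((size, size))
        wavelength = overrides.get("wavelength", wavelength)
        theta = overrides.get("orientation", theta)
        yy, xx = _coords(size)
        u = xx * np.cos(theta) + yy * np.sin(theta)
        tex = 0.18 * np.sin(2 * np.pi * u / wavelength + phase)
        # symmetrized so the texture transposes with the orientation
        sym = ndi.gaussian_filter((n + n.T) / 2.0, 2.0, mode="reflect")
        sd = sym.std()
        tex += 0.06 * (sym / sd if sd > 0 else sym)
        return np.clip(base + tex, 0.0, 1.0)
    elif kind == "mixed":
        wavelength = rng.uniform(6.0, 10.0)
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        yy, xx = _coords(size)
        u = xx * np.cos(theta) + yy * np.sin(theta)
        tex = 0.10 * np.sin(2 * np.pi * u / wavelength + phase)
        tex += 0.16 * _smooth_noise(rng, size, 2.0)
    elif kind == "speckle":
        density = rng.uniform(0.04, 0.08)
        impulses = (rng.random((size, size)) < density).astype(np.float64)
        x = ndi.gaussian_filter(impulses, 1.0, mode="reflect")
        sd = x.std()
        tex = -0.30 * ((x - x.mean()) / sd if sd > 0 else x)  # dark dots
    elif kind == "coarse_patches":
        tex = 0.28 * _smooth_noise(rng, size, 8.0)
    elif kind == "ring_motifs":
        n_centers = rng.integers(4, 8)
        centers = rng.uniform(0, size, size=(n_centers, 2))
        ring_period = rng.uniform(8.0, 12.0)
        d1 = _nearest_distances(size, centers, k=1)[0]
        tex = 0.18 * np.cos(2 * np.pi * d1 / ring_period)
    elif kind == "cell_mosaic":
        n_centers = rng.integers(10, 17)
        centers = rng.uniform(0, size, size=(n_centers, 2))
        d1, d2 = _nearest_distances(size, centers, k=2)
        edge = np.exp(-((d2 - d1) / 2.0) ** 2)
        tex = 0.15 - 0.45 * edge  # pale cells, thin dark boundaries
    else:  # pragma: no cover
        raise ValueError(f"unknown family kind {kind!r}")

    tex = tex + 0.02 * rng.standard_normal((size, size))
    return np.clip(base + tex, 0.0, 1.0)


def _tint(gray: np.ndarray, rng) -> np.ndarray:
    mult = np.clip(_HE_TINT + rng.uniform(-0.06, 0.06, size=3), 0.0, 1.0)
    return np.clip(gray[:, :, None] * mult[None, None, :], 0.0, 1.0)


def generate_tile(family: int, size: int = 150, seed: int = 0,
                  **overrides) -> np.ndarray:
    """One RGB tile of the given texture family; deterministic under seed.

    ``overrides`` pin per-tile parameters that are otherwise drawn at
    random (currently ``orientation`` and ``wavelength`` of the
    grating-type families).
    """
    if family not in FAMILY_KINDS:
        raise ValueError(f"unknown texture family {family}")
    if size < 32:
        raise ValueError("tile size must be at least 32 px")
    rng = np.random.default_rng([int(seed), int(family)])
    gray = _gray_texture(family, size, rng, overrides)
    return _tint(gray, rng)


def generate_dataset(n_per_class: int = 50, size: int = 150,
                     seed: int = 0) -> LabeledTileSet:
    """Balanced 8-class tile set; per-tile seeds derive from the master seed."""
    if n_per_class < 1:
        raise ValueError("need at least one tile per class")
    tiles, labels = [], []
    for family in range(1, 9):
        for i in range(n_per_class):
            rng_seed = np.random.SeedSequence(
                [int(seed), int(family), int(i)]
            ).generate_state(1)[0] % (2**31)
            tiles.append(generate_tile(family, size=size, seed=int(rng_seed)))
            labels.append(family)
    return LabeledTileSet(
        tiles=tiles,
        labels=np.asarray(labels),
        class_names=list(CLASS_NAMES),
        tile_size=size,
    )


@dataclass
class MosaicSpec:
    """Square-region layout of texture families for a ground-truthed mosaic."""

    layout: np.ndarray = field(
        default_factory=lambda: np.array([[1, 2], [4, 8]])
    )
    region_size: int = 300

    def __post_init__(self) -> None:
        self.layout = np.asarray(self.layout, dtype=int)
        if self.layout.ndim != 2:
            raise ValueError("layout must be a 2-D grid of family ids")
        bad = set(self.layout.ravel()) - set(FAMILY_KINDS)
        if bad:
            raise ValueError(f"unknown families in layout: {sorted(bad)}")

    @property
    def image_shape(self):
        return (self.layout.shape[0] * self.region_size,
                self.layout.shape[1] * self.region_size)


def generate_mosaic(spec: MosaicSpec, seed: int = 0):
    """A large RGB image of texture regions plus its ground-truth raster.

    Returns ``(image, truth)`` where ``truth[r, c]`` is the family id of
    the region containing pixel ``(r, c)``.
    """
    h, w = spec.image_shape
    image = np.zeros((h, w, 3))
    truth = np.zeros((h, w), dtype=int)
    s = spec.region_size
    for i in range(spec.layout.shape[0]):
        for j in range(spec.layout.shape[1]):
            family = int(spec.layout[i, j])
            rng_seed = np.random.SeedSequence(
                [int(seed), 1000 + i, 2000 + j, family]
            ).generate_state(1)[0] % (2**31)
            tile = generate_tile(family, size=s, seed=int(rng_seed))
            image[i * s : (i + 1) * s, j * s : (j + 1) * s] = tile
            truth[i * s : (i + 1) * s, j * s : (j + 1) * s] = family
    return image, truth
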