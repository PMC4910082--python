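"""Image and tile-dataset I/O.

All descriptors in :mod:`histotex.features` consume a single canonical
representation: a 2-D ``float64`` greyscale raster with intensities in
``[0, 1]``.  This module reads the standard raster formats (PNG, TIFF,
JPEG, BMP), converts RGB to greyscale with ITU-R BT.601 luma weights,
and loads directory-per-class tile datasets of the kind used for
histological texture benchmarks (``root/<class_name>/<tile>.tif``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LUMA_WEIGHTS",
    "IMAGE_EXTENSIONS",
    "LabeledTileSet",
    "load_image",
    "save_image",
    "to_grayscale",
    "load_tile_dataset",
]

#: ITU-R BT.601 luma weights (the convention of Matlab's ``rgb2gray``).
LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass
class LabeledTileSet:
    """A balanced-or-not collection of same-sized RGB tiles with labels.

    Attributes
    ----------
    tiles : list of ndarray
        Each tile is an ``H x W x 3`` float array in ``[0, 1]``.
    labels : ndarray of int
        Class ids in ``1..C``, aligned with ``tiles``.
    class_names : list of str
        Ordered class names; ``class_names[c - 1]`` names class id ``c``.
    tile_size : int
        Side length in pixels shared by every tile.
    """

    tiles: list = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    class_names: list = field(default_factory=list)
    tile_size: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.tiles) != len(self.labels):
            raise ValueError(
                f"{len(self.tiles)} tiles but {len(self.labels)} labels"
            )
        c = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 1 or self.labels.max() > c):
            raise ValueError(f"labels must lie in 1..{c}")

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset_by_class_names(self, names) -> "LabeledTileSet":
        """Restrict to the given classes, relabelling them 1..len(names)."""
        for name in names:
            if name not in self.class_names:
                raise ValueError(f"unknown class name: {name!r}")
        ids = [self.class_names.index(n) + 1 for n in names]
        keep = np.isin(self.labels, ids)
        remap = {old: new + 1 for new, old in enumerate(ids)}
        return LabeledTileSet(
            tiles=[t for t, k in zip(self.tiles, keep) if k],
            labels=np.array([remap[l] for l in self.labels[keep]], dtype=int),
            class_names=list(names),
            tile_size=self.tile_size,
        )


def load_image(path) -> np.ndarray:
    """Read an image file into an ``H x W x 3`` float array in ``[0, 1]``.

    Greyscale files are replicated across the three channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB") if im.mode not in ("RGB", "L", "I;16") else im
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.shape[2] > 3:
        arr = arr[:, :, :3]
    return np.clip(arr, 0.0, 1.0)


def save_image(path, pixels: np.ndarray) -> None:
    """Write a float image in ``[0, 1]`` (grey or RGB) as 8-bit."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    data = np.round(arr * 255.0).astype(np.uint8)
    Image.fromarray(data).save(path)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to greyscale with BT.601 luma weights.

    ``gray = 0.2989 R + 0.5870 G + 0.1140 B``, clipped to ``[0, 1]``.
    A 2-D input is assumed already greyscale and returned clipped.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        return np.clip(arr, 0.0, 1.0)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {arr.shape}")
    return np.clip(arr @ LUMA_WEIGHTS, 0.0, 1.0)


def load_tile_dataset(root) -> LabeledTileSet:
    """Load a ``root/<class_name>/<tile>`` directory layout.

    Class ids are assigned by lexicographic order of the subdirectory
    names; tiles within a class are ordered by sorted filename, so the
    result is deterministic across calls.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories found under {root}")
    tiles, labels = [], []
    class_names = [d.name for d in class_dirs]
    tile_size = None
    for cid, cdir in enumerate(class_dirs, start=1):
        files = sorted(
            f for f in cdir.iterdir()
            if f.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise ValueError(f"class directory {cdir.name!r} contains no images")
        for f in files:
            img = load_image(f)
            h, w = img.shape[:2]
            if h != w:
                raise ValueError(f"tile {f} is not square ({h}x{w})")
            if tile_size is None:
                tile_size = h
            elif h != tile_size:
                raise ValueError(
                    f"mixed tile sizes: {f} is {h}px, expected {tile_size}px"
                )
            tiles.append(img)
            labels.append(cid)
    return LabeledTileSet(
        tiles=tiles,
        labels=np.asarray(labels),
        class_names=class_names,
        tile_size=int(tile_size),
    )


def save_tile_dataset(root, tileset: LabeledTileSet, fmt: str = "png") -> None:
    """Write a tile set back out in the directory-per-class layout."""
    root = Path(root)
    counters = {}
    for tile, label in zip(tileset.tiles, tileset.labels):
        name = tileset.class_names[label - 1]
        cdir = root / name
        os.makedirs(cdir, exist_ok=True)
        i = counters.get(label, 0)
        counters[label] = i + 1
        save_image(cdir / f"tile_{i:05d}.{fmt}", tile)
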