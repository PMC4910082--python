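"""Tile-based segmentation of large images with a trained classifier.

A large image is covered by an evenly spaced grid of overlapping square
tiles (by default 100 x 100 tiles of 150 px for a 5000 x 5000 image —
10,000 tiles).  Each tile is converted to greyscale, its features are
extracted and the classifier's committee scores are recorded at the
tile's grid position, yielding one label grid and one score grid per
class.  The label grid can be smoothed with a modal (majority) filter —
the categorical analogue of a median filter — and rendered as a
false-colour classification map or as per-class probability maps,
enlarged with bicubic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.transform import resize

from .features import combined_features, feature_names
from .image_io import to_grayscale

__all__ = [
    "TileGrid",
    "SegmentationResult",
    "DEFAULT_PALETTE",
    "make_tile_grid",
    "segment_image",
    "median_smooth_labels",
    "render_classification_map",
    "render_vote_rgb",
]

#: 8 maximally distinct colours; index c-1 renders class id c.
DEFAULT_PALETTE = {
    1: (0.89, 0.10, 0.11),
    2: (0.22, 0.49, 0.72),
    3: (0.30, 0.69, 0.29),
    4: (0.60, 0.31, 0.64),
    5: (1.00, 0.50, 0.00),
    6: (1.00, 1.00, 0.20),
    7: (0.65, 0.34, 0.16),
    8: (0.97, 0.51, 0.75),
}


@dataclass
class TileGrid:
    """Evenly spaced overlapping tile positions inside an image."""

    tile_size: int
    grid_rows: int
    grid_cols: int
    top_left_coords: list  # (row, col) pixel offsets, row-major

    def __len__(self) -> int:
        return len(self.top_left_coords)


def _offsets(extent: int, tile: int, count: int) -> np.ndarray:
    if count == 1:
        return np.zeros(1, dtype=int)
    return np.round(
        np.arange(count) * (extent - tile) / (count - 1)
    ).astype(int)


def make_tile_grid(image_h: int, image_w: int, tile_size: int = 150,
                   grid_rows: int = 100, grid_cols: int = 100) -> TileGrid:
    """Evenly spaced tile offsets; the last tile ends exactly at the edge."""
    if tile_size > min(image_h, image_w):
        raise ValueError(
            f"tile size {tile_size} exceeds image extent "
            f"{image_h}x{image_w}"
        )
    rows = _offsets(image_h, tile_size, grid_rows)
    cols = _offsets(image_w, tile_size, grid_cols)
    coords = [(int(r), int(c)) for r in rows for c in cols]
    return TileGrid(tile_size=tile_size, grid_rows=grid_rows,
                    grid_cols=grid_cols, top_left_coords=coords)


@dataclass
class SegmentationResult:
    """Per-tile labels and per-class committee scores for a large image."""

    label_grid: np.ndarray  # grid_rows x grid_cols class ids
    score_grids: np.ndarray  # n_classes x grid_rows x grid_cols
    class_ids: np.ndarray
    grid: TileGrid
    smoothed_label_grid: np.ndarray = None


def segment_image(img: np.ndarray, clf, set_id: str,
                  grid: TileGrid = None) -> SegmentationResult:
    """Classify every tile of a large image.

    The classifier must have been trained on the same feature set: its
    feature-name list is checked against ``set_id`` before any tile is
    processed.
    """
    expected = feature_names(set_id)
    if list(clf.feature_names) != expected:
        raise ValueError(
            f"classifier was not trained on feature set {set_id!r}"
        )
    gray = to_grayscale(img)
    h, w = gray.shape
    if grid is None:
        grid = make_tile_grid(h, w)
    t = grid.tile_size
    features = np.empty((len(grid), len(expected)))
    for i, (r, c) in enumerate(grid.top_left_coords):
        features[i] = combined_features(gray[r : r + t, c : c + t], set_id)
    scores = clf.predict_scores(pd.DataFrame(features, columns=expected))
    labels = clf.class_ids[np.argmax(scores, axis=1)]
    shape = (grid.grid_rows, grid.grid_cols)
    label_grid = labels.reshape(shape)
    score_grids = np.stack(
        [scores[:, i].reshape(shape) for i in range(scores.shape[1])]
    )
    return SegmentationResult(
        label_grid=label_grid,
        score_grids=score_grids,
        class_ids=clf.class_ids,
        grid=grid,
        smoothed_label_grid=median_smooth_labels(label_grid),
    )


def median_smooth_labels(label_grid: np.ndarray, window: int = 3) -> np.ndarray:
    """Modal (majority) filter — the categorical median; ties keep the
    original label; borders use reflected padding."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window == 1:
        return label_grid.copy()
    grid = np.asarray(label_grid)
    classes = np.unique(grid)
    counts = np.stack([
        ndi.uniform_filter((grid == c).astype(np.float64), size=window,
                           mode="reflect")
        for c in classes
    ])
    best = np.argmax(counts, axis=0)
    best_count = np.max(counts, axis=0)
    out = classes[best]
    # tie: the original label reaches the same count -> keep it
    orig_idx = np.searchsorted(classes, grid)
    orig_count = np.take_along_axis(
        counts, orig_idx[None, :, :], axis=0
    )[0]
    ties = np.isclose(orig_count, best_count)
    out[ties] = grid[ties]
    return out


def _upscale(img: np.ndarray, target_size) -> np.ndarray:
    th, tw = target_size
    return np.clip(
        resize(img, (th, tw), order=3, mode="edge", anti_aliasing=False),
        0.0, 1.0,
    )


def render_classification_map(label_grid: np.ndarray, palette: dict,
                              target_size) -> np.ndarray:
    """Map labels to palette colours, then bicubically enlarge."""
    grid = np.asarray(label_grid)
    missing = [c for c in np.unique(grid) if c not in palette]
    if missing:
        raise ValueError(f"palette misses colour(s) for class(es) {missing}")
    rgb = np.zeros(grid.shape + (3,))
    for c in np.unique(grid):
        rgb[grid == c] = palette[c]
    return _upscale(rgb, target_size)


def render_vote_rgb(score_grids: np.ndarray, class_triplet, target_size,
                    class_ids=None) -> np.ndarray:
    """False-colour committee votes: R, G, B = three classes' scores."""
    if len(set(class_triplet)) != 3:
        raise ValueError("class_triplet must contain three distinct classes")
    if class_ids is None:
        class_ids = np.arange(1, score_grids.shape[0] + 1)
    index = {int(c): i for i, c in enumerate(class_ids)}
    channels = []
    for c in class_triplet:
        if int(c) not in index:
            raise ValueError(f"class {c} has no score grid")
        channels.append(np.clip(score_grids[index[int(c)]], 0.0, 1.0))
    rgb = np.stack(channels, axis=-1)
    return _upscale(rgb, target_size)
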