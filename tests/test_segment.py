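import numpy as np
import pytest

from histotex import (
    ClassifierSpec,
    MosaicSpec,
    extract_matrix,
    generate_mosaic,
    generate_tile,
    train_classifier,
)
from histotex.segment import (
    DEFAULT_PALETTE,
    make_tile_grid,
    median_smooth_labels,
    render_classification_map,
    render_vote_rgb,
    segment_image,
)


@pytest.fixture(scope="module")
def trained_best5(small_dataset, small_best5):
    df = small_best5
    return train_classifier(df, df["label"].to_numpy(),
                            ClassifierSpec("rbf_svm", seed=0))


class TestTileGrid:
    def test_reference_application_grid_has_10000_tiles(self):
        grid = make_tile_grid(5000, 5000, tile_size=150,
                              grid_rows=100, grid_cols=100)
        assert len(grid) == 10_000
        assert grid.top_left_coords[0] == (0, 0)

    def test_degenerate_single_tile(self):
        grid = make_tile_grid(150, 150, tile_size=150,
                              grid_rows=1, grid_cols=1)
        assert grid.top_left_coords == [(0, 0)]

    def test_last_tile_ends_at_image_edge(self):
        grid = make_tile_grid(5000, 4000, tile_size=150,
                              grid_rows=100, grid_cols=80)
        last_r, last_c = grid.top_left_coords[-1]
        assert last_r + 150 == 5000
        assert last_c + 150 == 4000

    def test_tiles_cover_the_image(self):
        grid = make_tile_grid(640, 640, tile_size=150,
                              grid_rows=5, grid_cols=5)
        covered = np.zeros((640, 640), dtype=bool)
        for r, c in grid.top_left_coords:
            covered[r : r + 150, c : c + 150] = True
        assert covered.all()

    def test_oversized_tile_rejected(self):
        with pytest.raises(ValueError):
            make_tile_grid(100, 100, tile_size=150)


class TestSegmentImage:
    def test_repeated_tile_image_gives_uniform_labels(self, trained_best5):
        tile = generate_tile(2, size=150, seed=9)
        img = np.tile(tile, (2, 2, 1))
        grid = make_tile_grid(300, 300, tile_size=150,
                              grid_rows=3, grid_cols=3)
        res = segment_image(img, trained_best5, "best5", grid)
        assert len(np.unique(res.label_grid)) == 1
        assert np.allclose(res.score_grids.sum(axis=0), 1.0, atol=1e-9)
        assert np.all((res.score_grids >= 0) & (res.score_grids <= 1))

    def test_mosaic_interior_tiles_recovered(self, trained_best5):
        spec = MosaicSpec(layout=np.array([[1, 2], [4, 8]]),
                          region_size=300)
        img, truth = generate_mosaic(spec, seed=11)
        grid = make_tile_grid(600, 600, tile_size=150,
                              grid_rows=7, grid_cols=7)
        res = segment_image(img, trained_best5, "best5", grid)
        correct = total = 0
        for idx, (r, c) in enumerate(grid.top_left_coords):
            region = truth[r : r + 150, c : c + 150]
            if len(np.unique(region)) == 1:  # interior tile
                total += 1
                correct += int(
                    res.label_grid.ravel()[idx] == region[0, 0]
                )
        assert total >= 10
        assert correct / total >= 0.90

    def test_feature_set_mismatch_rejected_before_processing(
        self, trained_best5
    ):
        img = np.zeros((300, 300, 3))
        with pytest.raises(ValueError, match="feature set"):
            segment_image(img, trained_best5, "glcm")


class TestMedianSmoothLabels:
    def test_uniform_grid_unchanged(self):
        grid = np.full((5, 5), 3)
        assert np.array_equal(median_smooth_labels(grid), grid)

    def test_single_deviant_cell_replaced(self):
        grid = np.ones((3, 3), dtype=int)
        grid[1, 1] = 2
        assert median_smooth_labels(grid)[1, 1] == 1

    def test_window_one_is_identity(self, rng):
        grid = rng.integers(1, 4, (6, 6))
        assert np.array_equal(median_smooth_labels(grid, window=1), grid)

    def test_never_introduces_foreign_labels(self, rng):
        grid = rng.integers(1, 5, (12, 12))
        smoothed = median_smooth_labels(grid)
        for r in range(12):
            for c in range(12):
                window = grid[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
                assert smoothed[r, c] in window

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_smooth_labels(np.ones((3, 3), dtype=int), window=2)


class TestRendering:
    def test_single_class_grid_renders_solid_colour(self):
        grid = np.full((2, 2), 4)
        img = render_classification_map(grid, DEFAULT_PALETTE, (60, 60))
        assert img.shape == (60, 60, 3)
        assert np.allclose(img, np.array(DEFAULT_PALETTE[4]), atol=1e-6)

    def test_round_trip_recovers_blocky_labels(self, rng):
        grid = rng.integers(1, 5, (8, 8))
        target = (8 * 25, 8 * 25)
        img = render_classification_map(grid, DEFAULT_PALETTE, target)
        # nearest-neighbour downscale at block centres
        centres = img[12::25, 12::25]
        palette = np.array([DEFAULT_PALETTE[c] for c in range(1, 5)])
        recovered = 1 + np.argmin(
            ((centres[:, :, None, :] - palette[None, None]) ** 2).sum(-1),
            axis=2,
        )
        assert (recovered == grid).mean() >= 0.95

    def test_missing_palette_entry_rejected(self):
        with pytest.raises(ValueError, match="palette"):
            render_classification_map(np.full((2, 2), 9), DEFAULT_PALETTE,
                                      (10, 10))

    def test_vote_rgb_one_hot_first_class_is_pure_red(self):
        scores = np.zeros((3, 4, 4))
        scores[0] = 1.0
        img = render_vote_rgb(scores, (1, 2, 3), (40, 40))
        assert img.shape == (40, 40, 3)
        assert np.allclose(img[..., 0], 1.0, atol=1e-6)
        assert np.allclose(img[..., 1:], 0.0, atol=1e-6)

    def test_vote_rgb_equal_scores_are_grey(self):
        scores = np.full((3, 4, 4), 1 / 3)
        img = render_vote_rgb(scores, (1, 2, 3), (20, 20))
        assert np.allclose(img, 1 / 3, atol=1e-6)

    def test_vote_rgb_values_clipped_to_unit(self, rng):
        scores = rng.random((3, 5, 5)) * 2.0
        img = render_vote_rgb(scores, (1, 2, 3), (30, 30))
        assert img.max() <= 1.0 and img.min() >= 0.0

    def test_vote_rgb_duplicate_classes_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            render_vote_rgb(np.zeros((3, 2, 2)), (1, 1, 2), (10, 10))
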