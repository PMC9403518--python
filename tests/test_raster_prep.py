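"""Band construction, ground filtering, stacking, tiling, augmentation."""

import numpy as np
import pytest

from crownscope.errors import ConfigurationError, DimensionError, ParameterError
from crownscope.raster_prep import (
    BAND_COMBINATIONS,
    BandCombination,
    RasterStack,
    augment_rotations,
    compute_chm,
    compute_exg,
    derive_dem,
    normalize_bands,
    stack_bands,
    tile_pair,
)


def dem_oracle(dsm, min_window, mean_window):
    """Literal double-loop sliding-window min then mean, edge-replicated."""
    def filt(grid, w, op):
        h, ww = grid.shape
        lo = w // 2  # even windows center-heavy on the leading side
        hi = w - 1 - lo
        out = np.empty_like(grid, dtype=float)
        for r in range(h):
            for c in range(ww):
                # edge replication: out-of-range rows/cols repeat the edge
                rows = np.clip(np.arange(r - lo, r + hi + 1), 0, h - 1)
                cols = np.clip(np.arange(c - lo, c + hi + 1), 0, ww - 1)
                out[r, c] = op(grid[np.ix_(rows, cols)])
        return out

    return filt(filt(np.asarray(dsm, float), min_window, np.min),
                mean_window, np.mean)


class TestExg:
    def test_single_pixel(self):
        assert compute_exg(np.array([[10.0]]), np.array([[20.0]]),
                           np.array([[5.0]]))[0, 0] == 25.0

    def test_equal_bands_give_zero(self):
        c = np.full((4, 4), 37.0)
        assert np.all(compute_exg(c, c, c) == 0.0)

    def test_constant_grid(self):
        g = np.full((3, 3), 100.0)
        rb = np.full((3, 3), 50.0)
        assert np.array_equal(compute_exg(rb, g, rb), np.full((3, 3), 100.0))

    def test_uint8_bands_do_not_wrap(self):
        r = np.array([[200]], dtype=np.uint8)
        g = np.array([[10]], dtype=np.uint8)
        b = np.array([[200]], dtype=np.uint8)
        assert compute_exg(r, g, b)[0, 0] == -380.0

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            compute_exg(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))


class TestDeriveDem:
    def test_constant_is_fixed_point(self):
        dsm = np.full((30, 30), 5.0)
        assert np.allclose(derive_dem(dsm), 5.0)

    def test_small_plateau_removed(self):
        dsm = np.full((100, 100), 10.0)
        dsm[40:55, 40:55] = 12.0  # 15x15 < 20x20 min window
        assert np.allclose(derive_dem(dsm), 10.0)

    @pytest.mark.parametrize("seed,windows", [(0, (7, 3)), (1, (7, 3)),
                                              (2, (4, 2)), (3, (20, 5))])
    def test_matches_bruteforce_oracle(self, seed, windows):
        rng = np.random.default_rng(seed)
        dsm = rng.uniform(90, 110, size=(33, 41))
        got = derive_dem(dsm, min_window=windows[0], mean_window=windows[1])
        assert np.allclose(got, dem_oracle(dsm, *windows), atol=1e-9)

    def test_ramp_dem_below_dsm(self):
        dsm = np.add.outer(np.linspace(0, 5, 40), np.linspace(0, 3, 40))
        dem = derive_dem(dsm, min_window=5, mean_window=3)
        assert np.allclose(dem, dem_oracle(dsm, 5, 3), atol=1e-9)
        assert np.all(dem <= dsm + 1e-9)

    def test_window_larger_than_raster(self):
        with pytest.raises(ParameterError):
            derive_dem(np.zeros((10, 10)), min_window=11)

    def test_bad_window_type(self):
        with pytest.raises(ParameterError):
            derive_dem(np.zeros((10, 10)), min_window=0)


class TestChm:
    def test_identity_gives_zero(self):
        d = np.random.default_rng(0).uniform(size=(5, 5))
        assert np.allclose(compute_chm(d, d), 0.0)

    def test_constant_offset(self):
        dem = np.full((4, 4), 100.0)
        assert np.allclose(compute_chm(dem + 2.5, dem), 2.5)

    def test_negative_preserved(self):
        chm = compute_chm(np.array([[1.0]]), np.array([[3.0]]))
        assert chm[0, 0] == -2.0

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            compute_chm(np.zeros((2, 2)), np.zeros((3, 3)))


class TestStackBands:
    @pytest.fixture()
    def stack(self):
        bands = {"blue": 1.0, "green": 2.0, "red": 3.0, "dsm": 4.0,
                 "chm": 5.0, "exg": 6.0}
        pixels = np.dstack([np.full((8, 8), v) for v in bands.values()])
        return RasterStack(pixels, list(bands), resolution=0.5)

    @pytest.mark.parametrize(
        "name,layers", [("RGB", 3), ("RGB-DSM", 4), ("RGB-CHM", 4),
                        ("EXG", 1), ("EXG-DSM", 2), ("EXG-CHM", 2)]
    )
    def test_layer_counts(self, stack, name, layers):
        combo = BandCombination.from_name(name)
        assert combo.layers == layers
        assert stack_bands(stack, combo).shape == (8, 8, layers)

    def test_layer_order_blue_green_red_elevation(self, stack):
        grid = stack_bands(stack, "RGB-CHM")
        assert [grid[0, 0, i] for i in range(4)] == [1.0, 2.0, 3.0, 5.0]

    def test_rgb_does_not_require_chm(self):
        pixels = np.dstack([np.zeros((4, 4))] * 3)
        s = RasterStack(pixels, ["blue", "green", "red"], resolution=1.0)
        assert stack_bands(s, "RGB").shape == (4, 4, 3)

    def test_missing_band_named_in_error(self):
        pixels = np.dstack([np.zeros((4, 4))] * 3)
        s = RasterStack(pixels, ["blue", "green", "red"], resolution=1.0)
        with pytest.raises(ConfigurationError, match="chm"):
            stack_bands(s, "RGB-CHM")

    def test_unknown_combo_rejected(self):
        with pytest.raises(ConfigurationError):
            BandCombination.from_name("RGBA")

    def test_table_of_recipes_is_complete(self):
        assert set(BAND_COMBINATIONS) == {
            "RGB", "RGB-DSM", "RGB-CHM", "EXG", "EXG-DSM", "EXG-CHM"
        }


class TestNormalize:
    def test_reflectance_minmax_and_elevation_by_height(self):
        grid = np.dstack([
            np.linspace(0, 255, 16).reshape(4, 4),
            np.full((4, 4), 2.5),
        ])
        out = normalize_bands(grid, ["green", "chm"], max_height=5.0)
        assert out[:, :, 0].min() == 0.0 and out[:, :, 0].max() == 1.0
        assert np.allclose(out[:, :, 1], 0.5)

    def test_constant_band_maps_to_zero(self):
        out = normalize_bands(np.full((3, 3, 1), 7.0), ["red"])
        assert np.all(out == 0.0)


class TestTiling:
    def test_1024_gives_16_tiles(self):
        grid = np.zeros((1024, 1024, 2))
        label = np.zeros((1024, 1024), np.uint8)
        ts = tile_pair(grid, label, 256)
        assert len(ts) == 16
        assert len(set(ts.origins)) == 16

    def test_partials_dropped(self):
        ts = tile_pair(np.zeros((300, 300, 1)), np.zeros((300, 300)), 256)
        assert len(ts) == 1
        assert ts.origins == [(0, 0)]

    def test_label_values_preserved(self):
        label = np.zeros((512, 512), np.uint8)
        label[10:60, 300:380] = 255
        ts = tile_pair(np.zeros((512, 512, 1)), label, 256)
        for _, lab in ts:
            assert set(np.unique(lab)) <= {0, 255}
        total = sum(np.count_nonzero(lab) for _, lab in ts)
        assert total == np.count_nonzero(label)

    def test_too_small_raster_warns_empty(self):
        with pytest.warns(UserWarning, match="smaller"):
            ts = tile_pair(np.zeros((100, 100, 1)), np.zeros((100, 100)), 256)
        assert len(ts) == 0

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            tile_pair(np.zeros((256, 256, 1)), np.zeros((256, 300)))


class TestAugmentation:
    @pytest.fixture()
    def tiles(self):
        rng = np.random.default_rng(3)
        grid = rng.uniform(size=(80, 160, 2))
        label = np.where(rng.random((80, 160)) > 0.8, 255, 0).astype(np.uint8)
        return tile_pair(grid, label, 40)  # 2x4 = 8 tiles

    def test_quadruples_count(self, tiles):
        assert len(augment_rotations(tiles)) == 4 * len(tiles)

    def test_double_180_is_identity(self, tiles):
        inp, lab = tiles.tiles[0]
        r2 = np.rot90(np.rot90(inp, 2), 2)
        assert np.array_equal(r2, inp)

    def test_label_multiset_preserved(self, tiles):
        aug = augment_rotations(tiles)
        for k in range(len(tiles)):
            base = np.count_nonzero(tiles.tiles[k][1])
            for j in range(4):
                _, lab = aug.tiles[4 * k + j]
                assert np.count_nonzero(lab) == base

    def test_input_and_label_rotate_together(self, tiles):
        aug = augment_rotations(tiles)
        inp, lab = tiles.tiles[2]
        inp90, lab90 = aug.tiles[4 * 2 + 1]
        assert np.array_equal(inp90, np.rot90(inp))
        assert np.array_equal(lab90, np.rot90(lab))

    def test_non_square_rejected(self):
        from crownscope.raster_prep import TileSet

        ts = TileSet(tiles=[(np.zeros((4, 6, 1)), np.zeros((4, 6)))],
                     tile_size=4, origins=[(0, 0)])
        with pytest.raises(ParameterError):
            augment_rotations(ts)
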