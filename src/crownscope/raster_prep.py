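"""Model-input raster construction.

This module turns a co-registered RGB orthomosaic + digital surface model
(DSM) pair into the layers a crown-segmentation model trains on:

* the excess green index ``EXG = 2G - R - B``, a visible-band vegetation
  index that highlights green plants against earth-toned background;
* a digital elevation model (DEM) derived from the DSM by a moving-minimum
  filter (which suppresses above-ground objects such as crowns) followed by
  a moving-mean smoothing pass;
* the canopy height model ``CHM = DSM - DEM``, per-pixel vegetation height;
* the six supported band combinations, non-overlapping 256 px tiling and
  rotation augmentation of (input, label) chip pairs.

All grids are row-major numpy arrays; multi-band stacks are
``(rows, cols, bands)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DimensionError, ParameterError

logger = logging.getLogger(__name__)

#: Band recipes: combination name -> ordered source-band tuple.  The order
#: (blue, green, red, then the elevation layer) follows the band description
#: of each combination.
BAND_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "RGB": ("blue", "green", "red"),
    "RGB-DSM": ("blue", "green", "red", "dsm"),
    "RGB-CHM": ("blue", "green", "red", "chm"),
    "EXG": ("exg",),
    "EXG-DSM": ("exg", "dsm"),
    "EXG-CHM": ("exg", "chm"),
}

#: Bands measured in meters (normalized by a height ceiling, not min-max).
ELEVATION_BANDS = frozenset({"dsm", "dem", "chm"})


@dataclass(frozen=True)
class BandCombination:
    """One of the six supported input recipes.

    Attributes
    ----------
    name : str
        Combination identifier, e.g. ``"RGB-CHM"``.
    bands : tuple of str
        Ordered source-band names the recipe stacks.
    """

    name: str
    bands: tuple[str, ...]

    @property
    def layers(self) -> int:
        """Number of input layers the combination produces."""
        return len(self.bands)

    @classmethod
    def from_name(cls, name: str) -> "BandCombination":
        key = name.upper().replace("_", "-")
        if key not in BAND_COMBINATIONS:
            raise ConfigurationError(
                f"unknown band combination {name!r}; "
                f"choose from {sorted(BAND_COMBINATIONS)}"
            )
        return cls(key, BAND_COMBINATIONS[key])


@dataclass
class RasterStack:
    """A multi-band pixel grid with resolution and band semantics.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols, bands)
        Band values; dtype is preserved as given.
    band_names : list of str
        One name per band, e.g. ``["red", "green", "blue", "dsm"]``.
    resolution : float
        Ground sampling distance in meters per pixel (> 0).
    nodata : float, optional
        Sentinel for missing pixels.
    """

    pixels: np.ndarray
    band_names: list[str]
    resolution: float
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise DimensionError(
                f"pixels must be (rows, cols, bands); got shape {self.pixels.shape}"
            )
        if len(self.band_names) != self.pixels.shape[2]:
            raise DimensionError(
                f"{len(self.band_names)} band names for "
                f"{self.pixels.shape[2]} bands"
            )
        if not self.resolution > 0:
            raise ParameterError(f"resolution must be > 0, got {self.resolution}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, name: str) -> np.ndarray:
        """Return one band as a 2-D grid (view when possible)."""
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"band {name!r} not in stack (has {self.band_names})"
            ) from None
        return self.pixels[:, :, idx]

    def with_band(self, name: str, grid: np.ndarray) -> "RasterStack":
        """Return a new stack with ``grid`` appended (or replaced) as ``name``."""
        grid = np.asarray(grid)
        if grid.shape != self.shape:
            raise DimensionError(
                f"band {name!r} shape {grid.shape} != raster shape {self.shape}"
            )
        if name in self.band_names:
            pixels = self.pixels.astype(np.result_type(self.pixels, grid), copy=True)
            pixels[:, :, self.band_names.index(name)] = grid
            return replace(self, pixels=pixels, band_names=list(self.band_names))
        pixels = np.dstack(
            [self.pixels.astype(np.result_type(self.pixels, grid), copy=False), grid]
        )
        return replace(self, pixels=pixels, band_names=[*self.band_names, name])


def compute_exg(
    red: np.ndarray, green: np.ndarray, blue: np.ndarray
) -> np.ndarray:
    """Excess green index ``2G - R - B``.

    Computed on the raw band values without rescaling; negative values are
    kept (no clamp).  Inputs are promoted to float to avoid unsigned
    wrap-around on 8-bit bands.
    """
    r = np.asarray(red, dtype=np.float64)
    g = np.asarray(green, dtype=np.float64)
    b = np.asarray(blue, dtype=np.float64)
    if not (r.shape == g.shape == b.shape):
        raise DimensionError(
            f"band shapes differ: R{r.shape} G{g.shape} B{b.shape}"
        )
    return 2.0 * g - r - b


def derive_dem(
    dsm: np.ndarray, min_window: int = 20, mean_window: int = 5
) -> np.ndarray:
    """Estimate bare-ground elevation from a DSM.

    A moving-minimum filter of ``min_window`` pixels removes above-ground
    objects whose footprint fits inside the window; a moving-mean filter of
    ``mean_window`` pixels then smooths the blocky minimum surface.  Both
    filters use edge-replication padding at the raster margins.
    """
    dsm = np.asarray(dsm, dtype=np.float64)
    if dsm.ndim != 2:
        raise DimensionError(f"dsm must be 2-D, got shape {dsm.shape}")
    for name, w in (("min_window", min_window), ("mean_window", mean_window)):
        if not (isinstance(w, (int, np.integer)) and w >= 1):
            raise ParameterError(f"{name} must be a positive integer, got {w!r}")
        if w > min(dsm.shape):
            raise ParameterError(
                f"{name}={w} exceeds raster dimensions {dsm.shape}"
            )
    ground = ndimage.minimum_filter(dsm, size=int(min_window), mode="nearest")
    return ndimage.uniform_filter(ground, size=int(mean_window), mode="nearest")


def compute_chm(dsm: np.ndarray, dem: np.ndarray) -> np.ndarray:
    """Canopy height model ``DSM - DEM``; negative values are preserved."""
    dsm = np.asarray(dsm, dtype=np.float64)
    dem = np.asarray(dem, dtype=np.float64)
    if dsm.shape != dem.shape:
        raise DimensionError(f"DSM shape {dsm.shape} != DEM shape {dem.shape}")
    chm = dsm - dem
    n_neg = int(np.count_nonzero(chm < 0))
    if n_neg:
        logger.info("CHM contains %d negative pixels (kept)", n_neg)
    return chm


def stack_bands(stack: RasterStack, combo: BandCombination | str) -> np.ndarray:
    """Assemble the ``(rows, cols, layers)`` input grid for one combination.

    Layers are ordered exactly as the recipe lists them (blue, green, red,
    then the elevation layer).  Missing source bands raise a configuration
    error naming the absent band.
    """
    if isinstance(combo, str):
        combo = BandCombination.from_name(combo)
    missing = [b for b in combo.bands if b not in stack.band_names]
    if missing:
        raise ConfigurationError(
            f"combination {combo.name} requires band(s) {missing} "
            f"absent from stack {stack.band_names}"
        )
    return np.stack([stack.band(b) for b in combo.bands], axis=-1).astype(
        np.float64
    )


def normalize_bands(
    grid: np.ndarray,
    band_names: list[str] | tuple[str, ...],
    max_height: float = 5.0,
) -> np.ndarray:
    """Scale mixed-unit layers to commensurate [0, 1]-ish ranges.

    Reflectance-like bands (RGB digital numbers, EXG) are min-max scaled over
    the grid; elevation bands (meters) are divided by ``max_height`` so that
    absolute height is preserved across scenes.  Constant bands map to 0.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim == 2:
        grid = grid[:, :, None]
    if grid.shape[2] != len(band_names):
        raise DimensionError(
            f"{len(band_names)} band names for {grid.shape[2]} layers"
        )
    if not max_height > 0:
        raise ParameterError(f"max_height must be > 0, got {max_height}")
    out = np.empty_like(grid, dtype=np.float32)
    for i, name in enumerate(band_names):
        band = grid[:, :, i]
        if name in ELEVATION_BANDS:
            out[:, :, i] = band / max_height
        else:
            lo, hi = float(band.min()), float(band.max())
            out[:, :, i] = 0.0 if hi == lo else (band - lo) / (hi - lo)
    return out


@dataclass
class TileSet:
    """Paired (input chip, label chip) tiles cut from one raster.

    ``origins`` maps each tile back to its (row, col) offset in the source
    raster; after augmentation the offset of each rotated copy is that of
    its source tile.
    """

    tiles: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    tile_size: int = 256
    origins: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack tiles into ``X (n, t, t, layers)`` and ``y (n, t, t)``."""
        if not self.tiles:
            raise ValueError("empty TileSet")
        X = np.stack([inp for inp, _ in self.tiles])
        y = np.stack([lab for _, lab in self.tiles])
        return X, y


def tile_pair(
    input_grid: np.ndarray, label_mask: np.ndarray, tile_size: int = 256
) -> TileSet:
    """Cut a raster and its label mask into non-overlapping square tiles.

    Tiling starts at the top-left corner; trailing partial windows are
    dropped.  A raster smaller than one tile yields an empty set with a
    warning.
    """
    input_grid = np.asarray(input_grid)
    label_mask = np.asarray(label_mask)
    if input_grid.ndim == 2:
        input_grid = input_grid[:, :, None]
    if input_grid.shape[:2] != label_mask.shape:
        raise DimensionError(
            f"input {input_grid.shape[:2]} and label {label_mask.shape} differ"
        )
    if tile_size < 1:
        raise ParameterError(f"tile_size must be >= 1, got {tile_size}")
    h, w = label_mask.shape
    ts = TileSet(tile_size=tile_size)
    if h < tile_size or w < tile_size:
        warnings.warn(
            f"raster {h}x{w} smaller than one {tile_size}px tile; "
            "empty tile set",
            stacklevel=2,
        )
        return ts
    for r in range(0, h - tile_size + 1, tile_size):
        for c in range(0, w - tile_size + 1, tile_size):
            ts.tiles.append(
                (
                    input_grid[r : r + tile_size, c : c + tile_size].copy(),
                    label_mask[r : r + tile_size, c : c + tile_size].copy(),
                )
            )
            ts.origins.append((r, c))
    return ts


def augment_rotations(tiles: TileSet) -> TileSet:
    """Quadruple a tile set with 90/180/270-degree rotated copies.

    Input and label chips are rotated identically; tiles must be square.
    """
    out = TileSet(tile_size=tiles.tile_size)
    for (inp, lab), origin in zip(tiles.tiles, tiles.origins):
        if inp.shape[0] != inp.shape[1]:
            raise ParameterError(
                f"rotation augmentation needs square tiles, got {inp.shape[:2]}"
            )
        for k in range(4):
            out.tiles.append(
                (
                    np.ascontiguousarray(np.rot90(inp, k, axes=(0, 1))),
                    np.ascontiguousarray(np.rot90(lab, k, axes=(0, 1))),
                )
            )
            out.origins.append(origin)
    return out
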