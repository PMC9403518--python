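"""Seeded synthetic orchard scenes for desk-scale experiments.

The generator emulates the kind of data the pipeline targets: a visible
orthomosaic of a low shrub-tree plantation (green elliptical crowns with a
radial color falloff on an earth-toned, noisy background), a co-registered
DSM (smooth low-amplitude terrain plus an elliptic-paraboloid height dome
per crown), a {0, 255} truth mask, and a per-crown truth table (crown
width, projection area, peak height).  Defaults mirror the surveyed stand:
ground sampling distance 0.01532703 m/pixel, crown widths in
[1.16, 3.47] m, tree heights below 3 m.

Everything is driven by one ``numpy`` generator seed; identical seeds give
bit-identical rasters and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import raster_prep
from .crown_metrics import CrownInstance
from .errors import ParameterError, PlacementError
from .raster_prep import BandCombination, RasterStack, TileSet

__all__ = ["SceneCrown", "SceneTruth", "gen_scene", "scene_to_tiles",
           "prepare_input_grid", "derive_missing_bands",
           "recommended_min_window"]

#: Earth-toned background mean (R, G, B digital numbers).
BACKGROUND_RGB = (120.0, 100.0, 80.0)
#: Crown color at the apex and at the rim of the ellipse.
CROWN_CENTER_RGB = (55.0, 135.0, 60.0)
CROWN_EDGE_RGB = (78.0, 116.0, 72.0)


@dataclass(frozen=True)
class SceneCrown:
    """Planted geometry of one crown (pixel frame, full axes in px)."""

    row: float
    col: float
    major_px: float
    minor_px: float
    orientation: float  # radians, major-axis direction
    height_m: float


@dataclass
class SceneTruth:
    """Ground truth of a generated scene."""

    crowns: list[SceneCrown]
    resolution: float
    mask: np.ndarray              # uint8 {0, 255}
    label_image: np.ndarray       # int32, 0 background, 1..n per crown
    terrain: np.ndarray           # float64 bare-ground elevation (m)
    metrics_table: pd.DataFrame = field(repr=False)
    #: metrics_table is indexed by crown label with columns cw_max_m,
    #: cw_min_m, cw_mean_m, cpa_m2, height_m, pixel_count, centroid_row,
    #: centroid_col, touches_border.

    def to_instances(self, min_crown_pixels: int = 1) -> list[CrownInstance]:
        """Reference :class:`CrownInstance` objects, one per planted crown.

        Built from the truth label image (so overlapping crowns stay
        distinct) with the truth table's measurements attached.
        """
        from skimage import measure

        out = []
        h, w = self.label_image.shape
        for region in measure.regionprops(self.label_image):
            if region.num_pixels < min_crown_pixels:
                continue
            row = self.metrics_table.loc[region.label]
            rmin, cmin, rmax, cmax = region.bbox
            out.append(
                CrownInstance(
                    label=int(region.label),
                    pixel_count=int(region.num_pixels),
                    cpa=float(row["cpa_m2"]),
                    centroid=tuple(map(float, region.centroid)),
                    touches_border=rmin == 0 or cmin == 0 or rmax == h or cmax == w,
                    slice_=region.slice,
                    pixels=region.image.copy(),
                    cw_max=float(row["cw_max_m"]),
                    cw_min=float(row["cw_min_m"]),
                    cw_mean=float(row["cw_mean_m"]),
                    height=float(row["height_m"]),
                )
            )
        return out


def _place_crowns(
    rng: np.random.Generator,
    n_crowns: int,
    size: int,
    majors: np.ndarray,
    overlap_allowed: bool,
    min_gap_px: float = 6.0,
    max_tries_per_crown: int = 500,
    max_restarts: int = 20,
) -> np.ndarray:
    """Centers (n, 2) by rejection sampling; largest crowns placed first.

    When a layout dead-ends (fragmented free space), the whole layout is
    redrawn, up to ``max_restarts`` times, before giving up.
    """
    order = np.argsort(-majors)
    for idx in order:
        if majors[idx] + 6.0 >= size:
            raise PlacementError(
                f"scene of {size}px cannot hold a crown of {majors[idx]:.0f}px"
            )
    for _ in range(max_restarts):
        centers = np.zeros((n_crowns, 2))
        placed: list[int] = []
        for idx in order:
            margin = majors[idx] / 2.0 + 3.0
            for _ in range(max_tries_per_crown):
                cand = rng.uniform(margin, size - margin, size=2)
                if overlap_allowed or all(
                    np.hypot(*(cand - centers[j]))
                    > (majors[idx] + majors[j]) / 2.0 + min_gap_px
                    for j in placed
                ):
                    centers[idx] = cand
                    placed.append(idx)
                    break
            else:
                break
        if len(placed) == n_crowns:
            return centers
    raise PlacementError(
        f"could not place {n_crowns} crowns in a {size}px scene after "
        f"{max_restarts} layout attempts"
    )


def gen_scene(
    n_crowns: int = 20,
    size: int = 1024,
    resolution: float = 0.01532703,
    cw_range: tuple[float, float] = (1.16, 3.47),
    height_max: float = 3.0,
    overlap_allowed: bool = False,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> tuple[RasterStack, SceneTruth]:
    """Generate one orchard scene and its ground truth.

    Returns a :class:`RasterStack` with bands ``red, green, blue, dsm`` and
    the matching :class:`SceneTruth`.  Crown mean widths are drawn
    uniformly from ``cw_range`` (meters), aspect ratios from [0.75, 0.95],
    orientations uniformly, peak heights from [0.4, 0.95] x ``height_max``.
    """
    if n_crowns < 0 or size < 8:
        raise ParameterError(f"invalid n_crowns={n_crowns} / size={size}")
    rng = np.random.default_rng(seed)

    cw_mean = rng.uniform(*cw_range, size=n_crowns)
    ratio = rng.uniform(0.75, 0.95, size=n_crowns)
    majors = 2.0 * cw_mean / resolution / (1.0 + ratio)
    minors = ratio * majors
    thetas = rng.uniform(0.0, np.pi, size=n_crowns)
    heights = rng.uniform(0.4 * height_max, 0.95 * height_max, size=n_crowns)
    centers = (
        _place_crowns(rng, n_crowns, size, majors, overlap_allowed)
        if n_crowns
        else np.zeros((0, 2))
    )

    # smooth, low-relief terrain: tilted plane + long-wavelength undulation
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    terrain = (
        100.0
        + 0.15 * rr / size
        + 0.10 * cc / size
        + 0.05 * np.sin(2 * np.pi * rr / size) * np.cos(2 * np.pi * cc / size)
    )

    rgb = np.empty((size, size, 3))
    for i, mu in enumerate(BACKGROUND_RGB):
        rgb[:, :, i] = mu
    rgb += rng.normal(0.0, noise_sd, size=rgb.shape)
    canopy = np.zeros((size, size))
    mask = np.zeros((size, size), dtype=np.uint8)
    label_image = np.zeros((size, size), dtype=np.int32)

    records = []
    for k in range(n_crowns):
        r0, c0 = centers[k]
        a, b = majors[k] / 2.0, minors[k] / 2.0
        th = thetas[k]
        half = int(np.ceil(a)) + 2
        rlo, rhi = max(0, int(r0) - half), min(size, int(r0) + half + 1)
        clo, chi = max(0, int(c0) - half), min(size, int(c0) + half + 1)
        dy = rr[rlo:rhi, clo:chi] - r0
        dx = cc[rlo:rhi, clo:chi] - c0
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        re2 = (u / a) ** 2 + (v / b) ** 2
        inside = re2 <= 1.0
        # elliptic-paraboloid dome: peak at the center, zero at the rim
        dome = np.where(inside, heights[k] * (1.0 - re2), 0.0)
        canopy[rlo:rhi, clo:chi] = np.maximum(canopy[rlo:rhi, clo:chi], dome)
        mask[rlo:rhi, clo:chi][inside] = 255
        label_image[rlo:rhi, clo:chi][inside] = k + 1
        # radial color falloff from apex green to rim green + jitter
        w_edge = np.sqrt(np.clip(re2, 0.0, 1.0))[inside]
        for i, (cmid, cedge) in enumerate(zip(CROWN_CENTER_RGB, CROWN_EDGE_RGB)):
            vals = cmid + (cedge - cmid) * w_edge
            vals += rng.normal(0.0, 4.0, size=vals.shape)
            rgb[rlo:rhi, clo:chi, i][inside] = vals
        pix = int(np.count_nonzero(inside))
        records.append(
            {
                "label": k + 1,
                "cw_max_m": 2 * a * resolution,
                "cw_min_m": 2 * b * resolution,
                "cw_mean_m": (a + b) * resolution,
                "cpa_m2": pix * resolution**2,
                "height_m": heights[k],
                "pixel_count": pix,
                "centroid_row": r0,
                "centroid_col": c0,
                "touches_border": bool(
                    rlo == 0 or clo == 0 or rhi == size or chi == size
                ),
            }
        )

    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    dsm = terrain + canopy
    pixels = np.dstack([rgb.astype(np.float64), dsm])
    stack = RasterStack(
        pixels=pixels,
        band_names=["red", "green", "blue", "dsm"],
        resolution=resolution,
    )
    table = (
        pd.DataFrame(records).set_index("label")
        if records
        else pd.DataFrame(
            columns=["cw_max_m", "cw_min_m", "cw_mean_m", "cpa_m2", "height_m",
                     "pixel_count", "centroid_row", "centroid_col",
                     "touches_border"]
        )
    )
    truth = SceneTruth(
        crowns=[
            SceneCrown(centers[k][0], centers[k][1], majors[k], minors[k],
                       thetas[k], heights[k])
            for k in range(n_crowns)
        ],
        resolution=resolution,
        mask=mask,
        label_image=label_image,
        terrain=terrain,
        metrics_table=table,
    )
    return stack, truth


def recommended_min_window(truth: SceneTruth, margin_px: int = 8) -> int:
    """Ground-filter window wide enough to see past the largest crown.

    The moving-minimum ground filter only recovers bare ground under a
    crown when its window extends beyond the crown footprint; this returns
    the smallest window that does for every crown in ``truth``.
    """
    if not truth.crowns:
        return 20
    return int(np.ceil(max(c.major_px for c in truth.crowns))) + margin_px


def derive_missing_bands(
    stack: RasterStack,
    combo: BandCombination | str,
    min_window: int = 20,
    mean_window: int = 5,
) -> RasterStack:
    """Add to ``stack`` whatever bands ``combo`` needs that it lacks.

    EXG comes from the RGB bands; DEM and CHM from the DSM via the
    minimum-then-mean ground filter.
    """
    if isinstance(combo, str):
        combo = BandCombination.from_name(combo)
    if "exg" in combo.bands and "exg" not in stack.band_names:
        stack = stack.with_band(
            "exg",
            raster_prep.compute_exg(
                stack.band("red"), stack.band("green"), stack.band("blue")
            ),
        )
    if "chm" in combo.bands and "chm" not in stack.band_names:
        dem = raster_prep.derive_dem(
            stack.band("dsm"), min_window=min_window, mean_window=mean_window
        )
        stack = stack.with_band("dem", dem)
        stack = stack.with_band(
            "chm", raster_prep.compute_chm(stack.band("dsm"), dem)
        )
    return stack


def prepare_input_grid(
    scene: RasterStack,
    truth: SceneTruth,
    combo: BandCombination | str,
    normalize: bool = True,
    max_height: float = 5.0,
    min_window: int | None = None,
    mean_window: int = 5,
) -> tuple[np.ndarray, RasterStack]:
    """Derive, stack and normalize the model-input layers for one scene.

    The ground-filter window defaults to one sized to the scene's largest
    crown (see :func:`recommended_min_window`).  Returns the stacked
    ``(rows, cols, layers)`` grid and the augmented band stack.
    """
    if isinstance(combo, str):
        combo = BandCombination.from_name(combo)
    window = min_window if min_window is not None else recommended_min_window(truth)
    stack = derive_missing_bands(scene, combo, min_window=window,
                                 mean_window=mean_window)
    grid = raster_prep.stack_bands(stack, combo)
    if normalize:
        grid = raster_prep.normalize_bands(grid, combo.bands, max_height=max_height)
    return grid, stack


def scene_to_tiles(
    scene: RasterStack,
    truth: SceneTruth,
    combo: BandCombination | str,
    tile_size: int = 256,
    augment: bool = False,
    normalize: bool = True,
    max_height: float = 5.0,
    min_window: int | None = None,
    mean_window: int = 5,
) -> TileSet:
    """Build (input, label) training tiles from a scene for one combination.

    Derives any bands the combination needs but the scene lacks, optionally
    min-max / height normalizes the layers, tiles without overlap, and
    optionally quadruples the set by rotation.
    """
    grid, _ = prepare_input_grid(
        scene, truth, combo, normalize=normalize, max_height=max_height,
        min_window=min_window, mean_window=mean_window,
    )
    tiles = raster_prep.tile_pair(grid, truth.mask, tile_size=tile_size)
    if augment:
        tiles = raster_prep.augment_rotations(tiles)
    return tiles
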