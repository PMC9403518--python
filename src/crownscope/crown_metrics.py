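"""Per-crown measurements from binary crown masks.

A segmented mask (crown = 255, background = 0) is decomposed into connected
components (8-connectivity); each component becomes a crown instance with

* crown projection area ``CPA = pixel_count x resolution^2`` (m^2);
* crown width from an ellipse fitted to the component's Canny edge points:
  the ellipse's long and short axes give the maximum and minimum crown
  width and their mean the average crown width CW (m);
* tree height as the maximum of the canopy height model over the
  component's pixels (m).

Crowns clipped by the raster border are flagged so downstream reporting can
exclude their incomplete shapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import feature, measure

from .errors import DataError, FitError, ParameterError

logger = logging.getLogger(__name__)

#: Ground sampling distance (m/pixel) of the reference survey imagery.
DEFAULT_RESOLUTION = 0.01532703


@dataclass
class CrownInstance:
    """One connected crown region and its measurements.

    Axis lengths inside ``ellipse`` are full axes in pixels; ``cw_*`` are in
    meters.  ``height`` stays ``None`` until a CHM is supplied, and the
    ``cw_*`` fields stay ``None`` when the ellipse fit failed
    (``unfittable`` set).
    """

    label: int
    pixel_count: int
    cpa: float
    centroid: tuple[float, float]
    touches_border: bool
    slice_: tuple[slice, slice] = field(repr=False)
    pixels: np.ndarray = field(repr=False)  # boolean patch inside slice_
    ellipse: tuple[float, float, float, float, float] | None = None
    cw_max: float | None = None
    cw_min: float | None = None
    cw_mean: float | None = None
    height: float | None = None
    unfittable: bool = False

    @property
    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the component in full-raster frame."""
        rr, cc = np.nonzero(self.pixels)
        return rr + self.slice_[0].start, cc + self.slice_[1].start


def _check_binary_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise DataError(f"mask must be 2-D, got shape {mask.shape}")
    vals = np.unique(mask)
    if not (np.isin(vals, (0, 255)).all() or np.isin(vals, (0, 1)).all()):
        raise DataError(
            f"mask must be binary 0/255, found values {vals[:10]}"
        )
    return mask > 0


def extract_crown_instances(
    mask: np.ndarray,
    resolution: float = DEFAULT_RESOLUTION,
    min_crown_pixels: int = 50,
    fit_ellipses: bool = True,
    chm: np.ndarray | None = None,
) -> list[CrownInstance]:
    """Decompose a binary mask into measured crown instances.

    Components of the 255 class under 8-connectivity become instances;
    components smaller than ``min_crown_pixels`` are dropped as speckle.
    When ``fit_ellipses`` is true each instance also gets crown widths from
    :func:`fit_crown_ellipse` (failures flag the instance unfittable
    instead of raising); when ``chm`` is given, heights from
    :func:`estimate_tree_height`.
    """
    binary = _check_binary_mask(mask)
    if not resolution > 0:
        raise ParameterError(f"resolution must be > 0, got {resolution}")
    labels = measure.label(binary, connectivity=2)
    h, w = binary.shape
    instances: list[CrownInstance] = []
    for region in measure.regionprops(labels):
        if region.num_pixels < min_crown_pixels:
            continue
        rmin, cmin, rmax, cmax = region.bbox
        touches = rmin == 0 or cmin == 0 or rmax == h or cmax == w
        inst = CrownInstance(
            label=int(region.label),
            pixel_count=int(region.num_pixels),
            cpa=float(region.num_pixels) * resolution**2,
            centroid=tuple(map(float, region.centroid)),
            touches_border=bool(touches),
            slice_=region.slice,
            pixels=region.image.copy(),
        )
        if fit_ellipses:
            try:
                cw_max, cw_min, cw_mean, ell = fit_crown_ellipse(
                    inst.pixels, resolution
                )
                inst.cw_max, inst.cw_min, inst.cw_mean = cw_max, cw_min, cw_mean
                inst.ellipse = ell
            except FitError as exc:
                inst.unfittable = True
                logger.warning("crown %d unfittable: %s", inst.label, exc)
        if chm is not None:
            inst.height = estimate_tree_height(chm, inst)
        instances.append(inst)
    return instances


def fit_crown_ellipse(
    component: np.ndarray, resolution: float = DEFAULT_RESOLUTION
) -> tuple[float, float, float, tuple[float, float, float, float, float]]:
    """Crown widths from an ellipse fitted to a component's edge.

    Edge pixels are located with Canny's detector on the binary component
    patch and an ellipse is fitted to them by direct least squares
    (:class:`skimage.measure.EllipseModel`).  Returns
    ``(cw_max, cw_min, cw_mean, (row, col, major_px, minor_px, theta))``
    where ``cw_max``/``cw_min`` are the full major/minor axis lengths times
    ``resolution`` and ``cw_mean`` their mean.

    Raises :class:`FitError` on degenerate components (too few or collinear
    edge pixels, or a non-elliptical fit).
    """
    component = np.asarray(component).astype(bool)
    if component.ndim != 2:
        raise DataError(f"component must be 2-D, got {component.shape}")
    coords = np.argwhere(component).astype(np.float64)
    if len(coords) < 5:
        raise FitError(f"component of {len(coords)} pixels is too small")
    # a blob collapsed onto (nearly) a line has no elliptical edge geometry
    sv = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
    if sv[-1] / np.sqrt(len(coords)) < 0.5:
        raise FitError("component pixels are (near-)collinear")
    # pad so boundary gradients exist even when the blob touches the patch edge
    patch = np.pad(component, 2).astype(np.float64)
    edges = feature.canny(patch, sigma=1.0)
    pts = np.argwhere(edges).astype(np.float64) - 2.0
    if len(pts) < 5:
        raise FitError(f"only {len(pts)} edge pixels; need >= 5 for a conic")
    # EllipseModel wants (x, y) = (col, row); semi-axes come back in a, b
    if hasattr(measure.EllipseModel, "from_estimate"):
        model = measure.EllipseModel.from_estimate(pts[:, ::-1])
        if not model:
            raise FitError("ellipse estimation failed (degenerate edge geometry)")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = measure.EllipseModel()
        if not model.estimate(pts[:, ::-1]):
            raise FitError("ellipse estimation failed (degenerate edge geometry)")
        xc, yc, a, b, theta = model.params
    if not (np.isfinite([xc, yc, a, b]).all() and a > 0 and b > 0):
        raise FitError(f"non-elliptical fit (semi-axes {a}, {b})")
    # the fitted ellipse must describe the blob: its area should roughly
    # match the pixel count, else the edge geometry was degenerate
    fit_area = np.pi * a * b
    n_pix = int(component.sum())
    if not (n_pix / 3.0 <= fit_area <= 3.0 * n_pix + 10.0):
        raise FitError(
            f"fitted ellipse area {fit_area:.1f} px^2 inconsistent with "
            f"component size {n_pix} px"
        )
    major, minor = (2 * a, 2 * b) if a >= b else (2 * b, 2 * a)
    cw_max = major * resolution
    cw_min = minor * resolution
    cw_mean = 0.5 * (cw_max + cw_min)
    return cw_max, cw_min, cw_mean, (float(yc), float(xc), float(major),
                                     float(minor), float(theta))


def estimate_tree_height(chm: np.ndarray, instance: CrownInstance) -> float:
    """Tree height = maximum CHM value over the crown's pixels."""
    chm = np.asarray(chm, dtype=np.float64)
    if instance.pixel_count == 0 or not instance.pixels.any():
        raise DataError(f"crown {instance.label} has no pixels")
    patch = chm[instance.slice_]
    if patch.shape != instance.pixels.shape:
        raise DataError(
            f"CHM not co-registered with mask (crown {instance.label}: "
            f"{patch.shape} vs {instance.pixels.shape})"
        )
    return float(patch[instance.pixels].max())


def filter_border_crowns(instances: list[CrownInstance]) -> list[CrownInstance]:
    """Keep only crowns whose shape is complete (not clipped by the border)."""
    return [inst for inst in instances if not inst.touches_border]


def instances_to_frame(instances: list[CrownInstance]) -> pd.DataFrame:
    """Tabulate instances (one row per crown) for CSV export."""
    rows = []
    for inst in instances:
        rows.append(
            {
                "label": inst.label,
                "pixel_count": inst.pixel_count,
                "cpa_m2": inst.cpa,
                "cw_max_m": inst.cw_max,
                "cw_min_m": inst.cw_min,
                "cw_mean_m": inst.cw_mean,
                "height_m": inst.height,
                "touches_border": inst.touches_border,
                "unfittable": inst.unfittable,
                "centroid_row": inst.centroid[0],
                "centroid_col": inst.centroid[1],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "pixel_count", "cpa_m2", "cw_max_m", "cw_min_m",
            "cw_mean_m", "height_m", "touches_border", "unfittable",
            "centroid_row", "centroid_col",
        ],
    )
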