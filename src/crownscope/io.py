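"""Raster and table I/O.

Rasters travel as TIFF (float32 for elevation/index layers, uint8 for RGB
and masks) or PNG (masks).  Ground resolution is not embedded in the pixel
formats; it rides in a small JSON sidecar ``<raster>.meta.json`` written
next to each file, or is supplied explicitly (e.g. the CLI's
``--resolution`` flag).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import DataError


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_raster(path, array: np.ndarray, resolution: float | None = None) -> None:
    """Write a 2-D or (rows, cols, bands) raster; dtype is preserved."""
    path = Path(path)
    array = np.asarray(array)
    if path.suffix.lower() in (".tif", ".tiff"):
        photometric = (
            "rgb" if array.ndim == 3 and array.shape[2] == 3
            and array.dtype == np.uint8 else "minisblack"
        )
        tifffile.imwrite(path, array, photometric=photometric)
    elif path.suffix.lower() == ".png":
        if array.dtype != np.uint8:
            raise DataError(f"PNG output requires uint8, got {array.dtype}")
        iio.imwrite(path, array)
    else:
        raise DataError(f"unsupported raster format {path.suffix!r}")
    if resolution is not None:
        _sidecar(path).write_text(json.dumps({"resolution_m_per_px": resolution}))


def read_raster(path, resolution: float | None = None) -> tuple[np.ndarray, float | None]:
    """Read a raster; returns ``(array, resolution)``.

    Resolution precedence: explicit argument, then the JSON sidecar, else
    ``None`` (the caller must supply one before metric computations).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        array = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        array = iio.imread(path)
    else:
        raise DataError(f"unsupported raster format {path.suffix!r}")
    if resolution is None and _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
        resolution = meta.get("resolution_m_per_px")
    return np.asarray(array), resolution


def write_mask(path, mask: np.ndarray, resolution: float | None = None) -> None:
    """Write a {0, 255} mask as uint8."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 255)).all():
        raise DataError(f"mask must be {{0,255}}, found {vals[:10]}")
    write_raster(path, mask.astype(np.uint8), resolution)


def read_mask(path) -> np.ndarray:
    """Read a mask raster; any positive value becomes 255."""
    array, _ = read_raster(path)
    if array.ndim == 3:
        array = array[:, :, 0]
    return np.where(array > 0, 255, 0).astype(np.uint8)
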