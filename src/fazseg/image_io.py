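"""Image and mask I/O, intensity normalization, and result reports.

The package works on en-face OCT-A projections: single-channel rasters in
which perfused vasculature appears bright and the foveal avascular zone
(FAZ) appears as a central dark region.  Every image carries the physical
width of its field of view in millimeters (clinical acquisitions use
3 x 3 or 6 x 6 mm), which converts pixel counts into areas in mm^2.

Conventions fixed here and relied on by every other module:

* arrays are row-major, 0-based ``(row, col)``, origin at the top-left;
* intensities are float64 min-max normalized to ``[0, 1]``;
* binary masks share the pixel grid of the image they refer to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "GrayImage",
    "BinaryMask",
    "load_image",
    "normalize",
    "save_mask",
    "load_mask",
    "write_report",
    "aggregate_reports",
]


@dataclass(frozen=True)
class GrayImage:
    """A normalized grayscale raster with a physical field width.

    Parameters
    ----------
    pixels
        2-D float array with values in ``[0, 1]``.
    field_mm
        Physical width of the (square) field of view in millimeters.
    """

    pixels: np.ndarray
    field_mm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ValueError("intensities must lie in [0, 1]")
        if not self.field_mm > 0:
            raise ValueError("field_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean raster on the same grid as its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.bool_:
            if not np.isin(px, (0, 1)).all():
                raise ValueError("mask values must be strictly binary")
            px = px.astype(bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __eq__(self, other: object) -> bool:  # bit-exact comparison
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


def normalize(pixels: np.ndarray) -> np.ndarray:
    """Min-max normalize an intensity array to ``[0, 1]``.

    Idempotent: an array already spanning ``[0, 1]`` is returned unchanged
    up to floating round-off.

    Raises
    ------
    DegenerateInputError
        If the array has zero dynamic range (constant image).
    """
    px = np.asarray(pixels, dtype=np.float64)
    lo, hi = float(px.min()), float(px.max())
    if hi - lo <= 0:
        raise DegenerateInputError("image has zero dynamic range")
    return (px - lo) / (hi - lo)


def load_image(path: str | Path, field_mm: float) -> GrayImage:
    """Load a PNG/TIFF raster as a normalized :class:`GrayImage`.

    RGB(A) inputs are converted to gray by averaging the color channels
    (alpha, if present, is dropped); many dataset exports are RGB
    screenshots of a gray image, so rejecting them would be unhelpful.
    """
    try:
        arr = iio.imread(Path(path))
    except OSError:
        raise
    except Exception as exc:  # plugin backends raise assorted types
        raise OSError(f"{path}: cannot decode as an image ({exc})") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise OSError(f"{path}: not a 2-D raster (shape {arr.shape})")
    return GrayImage(normalize(arr), field_mm=field_mm)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a lossless 8-bit PNG (False -> 0, True -> 255)."""
    iio.imwrite(Path(path), mask.pixels.astype(np.uint8) * 255)


def load_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask written by :func:`save_mask` (any nonzero = True)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return BinaryMask(arr > 0)


def write_report(result: Any, path: str | Path, *, image_id: str | None = None,
                 extra: dict | None = None) -> None:
    """Serialize a segmentation result to a JSON report.

    ``result`` is a :class:`fazseg.growseg.SegmentationResult`; the report
    records the derived biomarkers (area in mm^2, circularity), the region
    centroid, convergence information and the full parameter set used, so
    any report can be reproduced exactly.
    """
    record = report_record(result, image_id=image_id)
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))


def report_record(result: Any, *, image_id: str | None = None) -> dict:
    """Build the flat JSON-serializable record behind :func:`write_report`."""
    from . import __version__

    return {
        "image_id": image_id,
        "area_mm2": float(result.area_mm2),
        "circularity": float(result.circularity),
        "centroid": [float(c) for c in result.centroid],
        "converged": bool(result.converged),
        "iterations": int(result.iterations),
        "config": result.params,
        "version": __version__,
    }


def aggregate_reports(paths: Iterable[str | Path], out_csv: str | Path) -> pd.DataFrame:
    """Collect per-image JSON reports into one CSV table (one row each)."""
    rows = []
    for p in paths:
        rec = json.loads(Path(p).read_text())
        rows.append(
            {
                "image_id": rec.get("image_id"),
                "area_mm2": rec["area_mm2"],
                "circularity": rec["circularity"],
                "centroid_row": rec["centroid"][0],
                "centroid_col": rec["centroid"][1],
                "converged": rec["converged"],
                "iterations": rec["iterations"],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df
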