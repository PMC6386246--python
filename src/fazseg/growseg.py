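"""Precise FAZ segmentation by erosion-seeded region growing.

The preliminary region produced from the morphological pipeline tends to
overshoot the true avascular contour (closure and opening both distort
boundaries), so it is first eroded to a seed guaranteed to lie inside
the real FAZ, and then refined by a region-growing variant that both
adds and deletes pixels.

Each sweep computes ARV, the average intensity of the current region on
the top-hat-enhanced image, and accepts exactly the pixels whose value
lies in the tolerance interval

    [ARV - tol*ARV, ARV + tol*ARV]        (default tol = 0.3)

8-neighbors of the region inside the interval are added; region pixels
outside it are deleted, except the original seed pixels, which anchor
the region against evaporation.  The region is kept as the single
connected component holding the seed, and the process stops at the
first sweep that changes nothing.

Because the enhanced image is near zero inside the avascular zone, a
purely multiplicative interval can degenerate as ARV -> 0; an optional
absolute half-width floor (``abs_floor``) widens the interval to
``max(tol*ARV, abs_floor)`` so dark pixels with small additive noise
remain acceptable.

From the final mask the module derives the clinical biomarkers: the
area in mm^2 (pixel count times the physical area of one pixel) and the
circularity 4*pi*A/P^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .candidates import (
    close_edges,
    invert_and_open,
    label_candidates,
    region_perimeter,
    remove_false_positives,
    select_faz,
)
from .enhance import white_tophat
from .errors import ParameterError
from .image_io import BinaryMask, GrayImage
from .vessel_edges import CannyParams, adaptive_canny

__all__ = [
    "GrowParams",
    "SegmentationResult",
    "erode_seed",
    "region_grow",
    "compute_area_mm2",
    "compute_circularity",
    "circularity",
    "segment_faz",
]

_STRUCT8 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class GrowParams:
    """Parameters of the add/delete region-growing refinement.

    Attributes
    ----------
    tolerance_frac
        Fractional intensity tolerance around ARV (0.3 = +/-30%).
    seed_erosion_radius
        Disc radius for the preliminary erosion of the seed.
    max_iterations
        Hard bound on growing sweeps.
    abs_floor
        Absolute floor on the acceptance half-width (see module docs).
    update_arv, allow_deletion
        Switch off the per-sweep ARV update / the pixel-deletion rule;
        with both off the process reduces to a plain interval-membership
        flood fill from the seed (useful as an independent cross-check).
    """

    tolerance_frac: float = 0.3
    seed_erosion_radius: int = 3
    max_iterations: int = 100
    abs_floor: float = 0.02
    update_arv: bool = True
    allow_deletion: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.tolerance_frac < 1:
            raise ParameterError("tolerance_frac must be in (0,1)")
        if self.seed_erosion_radius < 1:
            raise ParameterError("seed_erosion_radius must be >= 1")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.abs_floor < 0:
            raise ParameterError("abs_floor must be >= 0")


@dataclass(frozen=True)
class SegmentationResult:
    """Final FAZ mask with its derived biomarkers."""

    mask: BinaryMask
    area_mm2: float
    circularity: float
    centroid: tuple[float, float]
    converged: bool
    iterations: int
    evaporated: bool = False  # region shrank to the anchor seed only
    preliminary_mask: BinaryMask | None = field(default=None, compare=False)
    params: dict[str, Any] | None = field(default=None, compare=False)


def erode_seed(preliminary: BinaryMask, radius: int) -> BinaryMask:
    """Erode the preliminary region into a seed safely inside the FAZ.

    If the erosion would empty the mask the radius is halved (down to 1)
    until the result is non-empty; if even radius 1 empties it, a single
    pixel at the (rounded, clipped) centroid is used.
    """
    if not preliminary.pixels.any():
        raise ParameterError("preliminary mask is empty")
    r = int(radius)
    while r >= 1:
        eroded = morphology.erosion(preliminary.pixels, morphology.disk(r))
        if eroded.any():
            return BinaryMask(eroded)
        r //= 2
    rr, cc = np.nonzero(preliminary.pixels)
    out = np.zeros_like(preliminary.pixels)
    r0 = int(np.clip(round(rr.mean()), 0, out.shape[0] - 1))
    c0 = int(np.clip(round(cc.mean()), 0, out.shape[1] - 1))
    out[r0, c0] = True
    return BinaryMask(out)


def _seed_component(region: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Restrict a region to the connected component containing the seed.

    Preference goes to the component holding the rounded seed centroid;
    if deletion has carved that pixel's component away from the anchor,
    the component with the largest anchor overlap is kept instead.
    """
    labeled, n = ndi.label(region, structure=_STRUCT8)
    if n <= 1:
        return region
    rr, cc = np.nonzero(anchor)
    r0 = int(np.clip(round(rr.mean()), 0, region.shape[0] - 1))
    c0 = int(np.clip(round(cc.mean()), 0, region.shape[1] - 1))
    lab = labeled[r0, c0]
    if lab == 0:
        overlap = np.bincount(labeled[anchor], minlength=n + 1)
        overlap[0] = 0
        lab = int(overlap.argmax()) if overlap.any() else 1
    return labeled == lab


def region_grow(img: GrayImage, seed: BinaryMask, params: GrowParams | None = None
                ) -> SegmentationResult:
    """Grow (and prune) a region from ``seed`` on the enhanced image.

    See the module docstring for the acceptance rule.  ARV is recomputed
    once per sweep, never per pixel, so the outcome does not depend on
    the order pixels are visited within a sweep.
    """
    if params is None:
        params = GrowParams()
    if img.shape != seed.shape:
        raise ParameterError("seed shape must match image shape")
    anchor = seed.pixels.copy()
    if not anchor.any():
        raise ParameterError("seed is empty")

    px = img.pixels
    region = anchor.copy()
    converged = False
    sweeps = 0
    arv = float(px[region].mean())
    for sweeps in range(1, params.max_iterations + 1):
        if params.update_arv:
            arv = float(px[region].mean())
        half = max(params.tolerance_frac * arv, params.abs_floor)
        ok = np.abs(px - arv) <= half
        frontier = ndi.binary_dilation(region, structure=_STRUCT8) & ~region
        new = region | (frontier & ok)
        if params.allow_deletion:
            new &= ok | anchor
        new = _seed_component(new, anchor)
        new |= anchor  # anchor is never deleted, even if disconnected
        if np.array_equal(new, region):
            converged = True
            break
        region = new

    evaporated = bool(np.array_equal(region, anchor)) and params.allow_deletion
    return _finalize(region, img, sweeps, converged, evaporated=evaporated)


def _finalize(region: np.ndarray, img: GrayImage, iterations: int,
              converged: bool, *, evaporated: bool = False,
              preliminary: BinaryMask | None = None,
              params: dict | None = None) -> SegmentationResult:
    mask = BinaryMask(region)
    rr, cc = np.nonzero(region)
    return SegmentationResult(
        mask=mask,
        area_mm2=compute_area_mm2(mask, img.field_mm),
        circularity=compute_circularity(mask),
        centroid=(float(rr.mean()), float(cc.mean())),
        converged=converged,
        iterations=iterations,
        evaporated=evaporated,
        preliminary_mask=preliminary,
        params=params,
    )


def compute_area_mm2(mask: BinaryMask, field_mm: float) -> float:
    """Physical area of a mask: ``a * field_mm^2 / (height * width)``.

    ``a`` is the foreground pixel count; each pixel covers
    ``field_mm^2 / (height*width)`` square millimeters.
    """
    if not field_mm > 0:
        raise ParameterError("field_mm must be positive")
    a = int(mask.pixels.sum())
    return a * float(field_mm) ** 2 / (mask.height * mask.width)


def circularity(area: float, perimeter: float) -> float:
    """Shape circularity ``4*pi*A/P^2``, clipped to ``[0, 1]``.

    1 for a perfect circle, decreasing with contour irregularity.
    """
    if perimeter <= 0:
        raise ParameterError("perimeter must be positive")
    return float(np.clip(4.0 * np.pi * area / perimeter**2, 0.0, 1.0))


def compute_circularity(mask: BinaryMask) -> float:
    """Circularity of a mask with A in pixels and P from the standard
    digital perimeter estimator shared with the candidates module."""
    a = int(mask.pixels.sum())
    if a == 0:
        raise ParameterError("mask is empty")
    return circularity(a, region_perimeter(mask.pixels))


def segment_faz(img: GrayImage, config: "PipelineConfig | None" = None
                ) -> SegmentationResult:
    """Run the full pipeline: enhance -> edges -> candidates -> growing.

    Raises
    ------
    NoFazFoundError
        If no candidate survives false-positive removal (localization
        failure; batch callers should record this, not crash).
    """
    from .config import PipelineConfig  # local import: config depends on params here

    if config is None:
        config = PipelineConfig()
    cfg = config.resolved(img.width)

    enhanced = white_tophat(img, cfg.tophat.selem_radius)
    edges = adaptive_canny(
        enhanced,
        CannyParams(cfg.canny.sigma, cfg.canny.low_frac, cfg.canny.high_frac),
    )
    closed = close_edges(edges, cfg.morph.close_radius)
    opened = invert_and_open(closed, cfg.morph.open_radius)
    cands = label_candidates(opened)
    cands = remove_false_positives(
        cands,
        img.shape,
        border_margin_frac=cfg.fp.border_margin_frac,
        max_center_offset_frac=cfg.fp.max_center_offset_frac,
        min_solidity=cfg.fp.min_solidity,
    )
    faz = select_faz(cands, img.shape)
    preliminary = BinaryMask(faz.mask)

    grow = GrowParams(
        tolerance_frac=cfg.grow.tolerance_frac,
        seed_erosion_radius=cfg.grow.seed_erosion_radius,
        max_iterations=cfg.grow.max_iterations,
        # the floor adapts to the image brightness, like the Canny thresholds
        abs_floor=cfg.grow.abs_floor_frac * float(enhanced.pixels.mean()),
    )
    seed = erode_seed(preliminary, grow.seed_erosion_radius)
    res = region_grow(enhanced, seed, grow)
    return _finalize(
        res.mask.pixels,
        img,
        res.iterations,
        res.converged,
        evaporated=res.evaporated,
        preliminary=preliminary,
        params=cfg.to_dict(),
    )
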