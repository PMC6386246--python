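"""Vessel edge detection with a mean-adaptive Canny detector.

OCT-A acquisitions vary widely in overall brightness, so fixed hysteresis
thresholds do not transfer between images.  Here both thresholds are
expressed as multiples of the mean intensity of the (enhanced) image:

    low  = low_frac  * mean(img)
    high = high_frac * mean(img)

which makes the edge map invariant to a global intensity rescaling — the
operational sense in which the detector adapts to the image average.
Only the thresholds adapt; the Gaussian smoothing scale is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

from skimage import feature

from .errors import DegenerateInputError
from .image_io import BinaryMask, GrayImage

__all__ = ["CannyParams", "adaptive_canny"]


@dataclass(frozen=True)
class CannyParams:
    """Parameters of the adaptive Canny detector.

    Attributes
    ----------
    sigma
        Gaussian smoothing scale in pixels.
    low_frac, high_frac
        Hysteresis thresholds as multiples of the mean image intensity;
        must satisfy ``0 < low_frac < high_frac``.
    """

    sigma: float = 1.0
    low_frac: float = 0.66
    high_frac: float = 1.33

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.low_frac < self.high_frac:
            raise ValueError("need 0 < low_frac < high_frac")


def adaptive_canny(img: GrayImage, params: CannyParams | None = None) -> BinaryMask:
    """Detect vessel edges with hysteresis thresholds scaled to mean(img).

    The standard Canny stages apply (Gaussian smoothing, Sobel gradients,
    non-maximum suppression, hysteresis), producing thin binary curves
    along vessel boundaries.

    Raises
    ------
    DegenerateInputError
        If the image mean is zero (nothing to detect, thresholds undefined).
    """
    if params is None:
        params = CannyParams()
    mean = float(img.pixels.mean())
    if mean <= 0:
        raise DegenerateInputError("image mean is zero; no edges definable")
    low = min(params.low_frac * mean, 1.0 - 1e-9)
    high = min(params.high_frac * mean, 1.0 - 1e-9)
    if low >= high:  # only possible after clamping very bright images
        low = high * (params.low_frac / params.high_frac)
    edges = feature.canny(
        img.pixels, sigma=params.sigma, low_threshold=low, high_threshold=high
    )
    return BinaryMask(edges)
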