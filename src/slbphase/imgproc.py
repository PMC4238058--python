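"""Image correction: background subtraction, flat-field division, rolling-ball.

TIRF/epifluorescence images of supported lipid bilayers carry three
instrumental artifacts that must be removed before any intensity-based
statistic is meaningful: a camera offset plus dark background (measured on
non-fluorescent bilayers), smooth uneven illumination / detector sensitivity
(vignetting), and slowly varying local background. The corrections here are
the standard ones: per-pixel background subtraction, division by a
normalized flat-field ("correction factors in a 0 to 1 range" derived from a
homogeneous reference bilayer), and rolling-ball flattening implemented as
grayscale opening with a disk structuring element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening

__all__ = [
    "RasterImage",
    "CorrectionField",
    "compute_flatfield",
    "correct_image",
    "rolling_ball",
    "FACTOR_FLOOR",
]

#: Flat-field factors below this value are not corrected; the pixel is
#: flagged invalid instead (division by a tiny factor amplifies noise
#: unboundedly).
FACTOR_FLOOR = 0.01


@dataclass(frozen=True)
class RasterImage:
    """A single-channel 2D intensity image with physical pixel size.

    Parameters
    ----------
    values : ndarray
        2D array of finite intensities (camera counts), stored as float64.
    pixel_size : float
        Edge length of one pixel in micrometres.
    """

    values: np.ndarray
    pixel_size: float = 0.16

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"image must be 2D and non-empty, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size**2


@dataclass(frozen=True)
class CorrectionField:
    """Pixel-by-pixel flat-field factors in (0, 1], max-normalized.

    ``valid`` marks pixels whose factor is above :data:`FACTOR_FLOOR`;
    only valid pixels are divided during correction.
    """

    factors: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if f.ndim != 2:
            raise ValueError("correction factors must be 2D")
        if not np.all(f > 0):
            raise ValueError("correction factors must be strictly positive")
        if not np.isclose(f.max(), 1.0):
            raise ValueError("correction factors must be normalized to max 1")
        object.__setattr__(self, "factors", f)
        if self.valid is None:
            object.__setattr__(self, "valid", f >= FACTOR_FLOOR)


def compute_flatfield(reference: RasterImage, median_radius: int = 3) -> CorrectionField:
    """Derive flat-field correction factors from a homogeneous reference image.

    The reference is an image of a uniformly fluorescent bilayer *after*
    background subtraction. It is median-filtered (so isolated hot pixels
    cannot set the maximum) and divided by its maximum, giving factors in
    (0, 1] that encode relative illumination/detection efficiency per pixel.

    Parameters
    ----------
    reference : RasterImage
        Background-subtracted homogeneous-bilayer image; must be strictly
        positive everywhere.
    median_radius : int
        Radius of the median pre-filter in pixels; 0 disables smoothing.

    Returns
    -------
    CorrectionField
    """
    vals = reference.values
    if np.any(vals <= 0):
        raise ValueError(
            "reference has non-positive pixels; background subtraction "
            "appears to be missing or overdone"
        )
    if median_radius > 0:
        size = 2 * median_radius + 1
        vals = ndimage.median_filter(vals, size=size, mode="nearest")
    factors = vals / vals.max()
    return CorrectionField(factors=factors, valid=factors >= FACTOR_FLOOR)


def correct_image(
    image: RasterImage,
    background: RasterImage | float = 0.0,
    flatfield: CorrectionField | None = None,
) -> RasterImage:
    """Background-subtract and flat-field-correct an image.

    ``out = clip((image - background) / factors, 0)``. Pixels flagged
    invalid in the flat-field (factor below :data:`FACTOR_FLOOR`) are left
    at their background-subtracted value rather than divided.

    Parameters
    ----------
    image : RasterImage
    background : RasterImage or float
        Per-pixel background image (same shape) or a scalar offset.
    flatfield : CorrectionField, optional
        If omitted, only background subtraction is applied.
    """
    if isinstance(background, RasterImage):
        if background.shape != image.shape:
            raise ValueError("background shape does not match image")
        bg = background.values
    else:
        bg = float(background)
    out = image.values - bg
    if flatfield is not None:
        if flatfield.factors.shape != image.shape:
            raise ValueError("flat-field shape does not match image")
        out = np.where(flatfield.valid, out / flatfield.factors, out)
    return RasterImage(values=np.clip(out, 0.0, None), pixel_size=image.pixel_size)


def rolling_ball(image: RasterImage, radius: int = 50) -> RasterImage:
    """Subtract a local background estimated by grayscale opening.

    Grayscale opening with a flat disk of the given radius removes every
    bright feature narrower than the disk, leaving the slowly varying local
    background, which is then subtracted. This is the flat-structuring-
    element formulation of rolling-ball flattening.

    Parameters
    ----------
    image : RasterImage
    radius : int
        Disk radius in pixels; must be >= 1 and smaller than the shorter
        image side.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(image.shape):
        raise ValueError("radius must be smaller than the shorter image side")
    background = opening(image.values, disk(radius))
    flattened = np.clip(image.values - background, 0.0, None)
    return RasterImage(values=flattened, pixel_size=image.pixel_size)
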