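"""Preprocessing chain: green channel, contrast stretch, pseudo-background.

The standard punctate-staining preprocessing chain: isolate the green
channel of the RGB photograph (fluorescein emits green), widen the intensity
distribution with a saturated linear contrast stretch computed over ROI
pixels, build a heavily smoothed *pseudo-background* (disc-mean convolution
followed by a Gaussian blur) and subtract it from the image, leaving bright
punctate lesions as the residual foreground.

All filtering is carried out in exact integer arithmetic (integral-image
disc means; an integer-quantised separable Gaussian kernel), with
edge-replication at the borders and round-half-up back to 8 bit after each
stage.  This makes every stage a pure function whose output is bit-identical
across reruns and exactly equivariant under horizontal mirroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ._util import round_half_up_div
from .errors import ValidationError
from .image_io import RGBImage

#: intermediate gray images are plain uint8 numpy arrays
GrayImage8 = np.ndarray

_GAUSS_SCALE = 1 << 16  # integer quantisation scale for the Gaussian kernel


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable preprocessing parameters.

    saturation_fraction
        Fraction of ROI pixels saturated by the contrast stretch (the
        long-standing default of the classic enhance-contrast command).
    background_radius
        Radius in pixels of the disc-mean convolution (default 14).
    background_sigma
        Sigma in pixels of the Gaussian blur (default 2.0).
    kernel_shape
        ``"disc"`` (default) or ``"square"`` mean-filter footprint, exposed
        for sensitivity checks.
    """

    saturation_fraction: float = 0.0035
    background_radius: int = 14
    background_sigma: float = 2.0
    kernel_shape: str = "disc"

    def __post_init__(self):
        if not 0.0 <= self.saturation_fraction < 0.5:
            raise ValidationError("saturation_fraction must be in [0, 0.5)")
        if self.background_radius < 1:
            raise ValidationError("background_radius must be >= 1")
        if not self.background_sigma > 0:
            raise ValidationError("background_sigma must be > 0")
        if self.kernel_shape not in ("disc", "square"):
            raise ValidationError("kernel_shape must be 'disc' or 'square'")


def extract_green_8bit(img: RGBImage) -> GrayImage8:
    """The green channel, unchanged (I/O already guarantees 8 bit)."""
    return np.ascontiguousarray(img.pixels[:, :, 1])


def enhance_contrast(img: GrayImage8, roi: np.ndarray,
                     saturation_fraction: float = 0.0035) -> GrayImage8:
    """Saturated linear stretch of the ROI intensity histogram.

    lo/hi are the intensities at the ``saturation_fraction/2`` and
    ``1 - saturation_fraction/2`` quantiles of the ROI pixels; ROI pixels
    map through ``clamp(round((v - lo) * 255 / (hi - lo)), 0, 255)``,
    pixels outside the ROI pass through unchanged.  A flat histogram
    (hi == lo) returns the image unchanged with a warning.
    """
    if not roi.any():
        raise ValidationError("ROI is empty")
    vals = img[roi]
    lo = int(np.quantile(vals, saturation_fraction / 2, method="lower"))
    hi = int(np.quantile(vals, 1 - saturation_fraction / 2, method="higher"))
    if hi == lo:
        warnings.warn("degenerate ROI histogram (hi == lo); image unchanged",
                      stacklevel=2)
        return img.copy()
    out = img.copy()
    v = vals.astype(np.int64)
    stretched = round_half_up_div((v - lo) * 255, hi - lo)
    out[roi] = np.clip(stretched, 0, 255).astype(np.uint8)
    return out


def _disc_half_widths(radius: int) -> np.ndarray:
    """Per-row half-widths of the digital disc {(dy,dx): dy^2+dx^2 <= r^2}."""
    dy = np.arange(-radius, radius + 1)
    return np.floor(np.sqrt(radius * radius - dy * dy + 1e-9)).astype(np.int64)


def _mean_filter_exact(img: GrayImage8, radius: int, shape: str) -> GrayImage8:
    """Disc (or square) mean filter, exact integers, edge replication."""
    r = radius
    padded = np.pad(img.astype(np.int64), r, mode="edge")
    csum = np.cumsum(padded, axis=1)
    csum = np.pad(csum, ((0, 0), (1, 0)))  # csum[i, j] = sum of cols < j
    H, W = img.shape
    if shape == "square":
        widths = np.full(2 * r + 1, r, dtype=np.int64)
    else:
        widths = _disc_half_widths(r)
    total = np.zeros((H, W), dtype=np.int64)
    npix = 0
    for k, w in enumerate(widths):
        dy = k - r
        rows = slice(r + dy, r + dy + H)
        total += csum[rows, r + w + 1:r + w + 1 + W] - csum[rows, r - w:r - w + W]
        npix += 2 * int(w) + 1
    return round_half_up_div(total, npix).astype(np.uint8)


def _gaussian_kernel_int(sigma: float) -> np.ndarray:
    """Symmetric 1-D Gaussian quantised to integers (scale 2^16)."""
    radius = max(1, int(round(4.0 * sigma)))
    i = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-(i * i) / (2.0 * sigma * sigma))
    k = np.round(w * _GAUSS_SCALE).astype(np.int64)
    k[k < 1] = 1  # keep support positive so the kernel stays symmetric
    return k


def _gaussian_filter_exact(img: GrayImage8, sigma: float) -> GrayImage8:
    """Separable Gaussian blur with an integer kernel; exact, edge replication.

    Both passes accumulate integers (max value < 2^53, so float64
    accumulation inside ndimage is still exact), and the division back to
    8 bit happens once, round-half-up.
    """
    k = _gaussian_kernel_int(sigma)
    ksum = int(k.sum())
    a = img.astype(np.int64)
    a = ndi.correlate1d(a, k, axis=0, mode="nearest")
    a = ndi.correlate1d(a, k, axis=1, mode="nearest")
    return round_half_up_div(a, ksum * ksum).astype(np.uint8)


def pseudo_background(img: GrayImage8, params: PreprocessParams) -> GrayImage8:
    """Disc-mean convolution then Gaussian blur: the pseudo-background."""
    smoothed = _mean_filter_exact(img, params.background_radius, params.kernel_shape)
    return _gaussian_filter_exact(smoothed, params.background_sigma)


def subtract_background(img: GrayImage8, bg: GrayImage8) -> GrayImage8:
    """Per-pixel ``max(img - bg, 0)``."""
    if img.shape != bg.shape:
        raise ValidationError(f"shape mismatch: {img.shape} vs {bg.shape}")
    return np.maximum(img.astype(np.int16) - bg.astype(np.int16), 0).astype(np.uint8)


def preprocess_pipeline(img: RGBImage, roi: np.ndarray,
                        params: PreprocessParams | None = None,
                        return_stages: bool = False):
    """Green channel -> contrast stretch -> pseudo-background -> subtraction.

    Returns the residual foreground image; with ``return_stages=True``
    returns ``(residual, stages)`` where ``stages`` maps stage names to the
    intermediate images (for debugging / figure-style output).
    """
    params = params or PreprocessParams()
    green = extract_green_8bit(img)
    enhanced = enhance_contrast(green, roi, params.saturation_fraction)
    bg = pseudo_background(enhanced, params)
    residual = subtract_background(enhanced, bg)
    if return_stages:
        return residual, {"green": green, "enhanced": enhanced,
                          "background": bg, "residual": residual}
    return residual
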