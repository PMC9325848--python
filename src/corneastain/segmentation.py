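"""Triangle thresholding, particle extraction, morphometry and filtering.

The analysis half of the staining pipeline: build the intensity histogram of
the residual image over the cornea ROI, place an automatic threshold with
the triangle method (bright-object variant), binarize, extract 8-connected
particles, measure area / perimeter / circularity, and drop everything that
is too large (> ``max_area`` pixels, tear-film pooling) or not round enough
(circularity < ``min_circularity``, mucus strands and other artifacts).

Conventions, held fixed and tested:

* foreground is *strictly above* the threshold;
* components are 8-connected; particles touching the ROI or image border
  are retained (no border exclusion by default, no hole filling);
* the perimeter is scikit-image's weighted crack-length estimator
  (unit edges between foreground and background with corner-smoothing
  weights); circularity is capped at 1, and degenerate particles whose
  estimated perimeter is 0 (single pixels, dominoes) count as circular;
* a particle with area exactly ``max_area`` or circularity exactly
  ``min_circularity`` is kept (the elimination rules are strict
  inequalities: *bigger than* / *below*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, NamedTuple, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .errors import ValidationError
from .image_io import RGBImage, ROISpec, rasterize_roi
from .preprocess import GrayImage8, PreprocessParams, preprocess_pipeline


@dataclass(frozen=True)
class Histogram256:
    """A 256-bin intensity histogram."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,) or (c < 0).any():
            raise ValidationError("histogram needs 256 non-negative counts")
        if c.sum() < 1:
            raise ValidationError("histogram is empty")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_image(cls, img: GrayImage8, roi: np.ndarray) -> "Histogram256":
        return cls(np.bincount(img[roi].ravel(), minlength=256))


@dataclass(frozen=True)
class Particle:
    """One connected bright component and its morphometry."""

    label: int
    area: int
    perimeter: float
    circularity: float
    centroid: Tuple[float, float]  # (row, col)
    bbox: Tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


class RejectedParticle(NamedTuple):
    particle: Particle
    reason: str  # "area" | "circularity"


@dataclass(frozen=True)
class FilterParams:
    """Particle acceptance rules: area <= max_area and circularity >= min."""

    max_area: int = 200
    min_circularity: float = 0.7

    def __post_init__(self):
        if self.max_area < 1:
            raise ValidationError("max_area must be >= 1")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValidationError("min_circularity must be in [0, 1]")


@dataclass
class StainingResult:
    """Outcome of the full counting pipeline on one image."""

    count: int
    accepted: List[Particle]
    rejected: List[RejectedParticle]
    threshold: int
    binary_mask: np.ndarray
    params: PreprocessParams = field(default_factory=PreprocessParams)
    filters: FilterParams = field(default_factory=FilterParams)

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "threshold": self.threshold,
            "accepted": [_particle_record(p) for p in self.accepted],
            "rejected": [dict(_particle_record(p), reason=r)
                         for p, r in self.rejected],
            "params": {
                "saturation_fraction": self.params.saturation_fraction,
                "background_radius": self.params.background_radius,
                "background_sigma": self.params.background_sigma,
                "kernel_shape": self.params.kernel_shape,
                "max_area": self.filters.max_area,
                "min_circularity": self.filters.min_circularity,
            },
        }

    def particles_frame(self) -> pd.DataFrame:
        """One row per particle (accepted and rejected), CSV-ready."""
        rows = [dict(_particle_record(p), status="accepted", reason="")
                for p in self.accepted]
        rows += [dict(_particle_record(p), status="rejected", reason=r)
                 for p, r in self.rejected]
        cols = ["label", "area", "perimeter", "circularity", "centroid_row",
                "centroid_col", "min_row", "min_col", "max_row", "max_col",
                "status", "reason"]
        return pd.DataFrame(rows, columns=cols)


def _particle_record(p: Particle) -> dict:
    return {
        "label": p.label, "area": p.area,
        "perimeter": round(p.perimeter, 4),
        "circularity": round(p.circularity, 4),
        "centroid_row": round(p.centroid[0], 2),
        "centroid_col": round(p.centroid[1], 2),
        "min_row": p.bbox[0], "min_col": p.bbox[1],
        "max_row": p.bbox[2], "max_col": p.bbox[3],
    }


def triangle_threshold(hist: Histogram256, bright_objects: bool = True) -> int:
    """Automatic threshold by the triangle construction.

    A line is drawn from the histogram peak to the last nonzero bin of the
    longer tail; the threshold is the bin whose histogram point lies
    farthest (perpendicular distance) below that line, ties broken toward
    the bin nearer the peak.  With ``bright_objects`` (the default,
    matching bright staining on a dark cornea), the histogram is flipped
    first when the longer tail is on the dark side, and the result mapped
    back, so that downstream foreground is always *strictly above* the
    returned threshold.
    """
    counts = hist.counts
    nz = np.flatnonzero(counts)
    first, last = int(nz[0]), int(nz[-1])
    if first == last:
        warnings.warn("degenerate single-bin histogram; returning that bin",
                      stacklevel=2)
        return first
    peak = int(np.argmax(counts))
    left, right = peak - first, last - peak
    flip = left > right if bright_objects else left >= right
    if flip:
        t = _triangle_core(counts[::-1])
        return 255 - t
    return _triangle_core(counts)


def _triangle_core(counts: np.ndarray) -> int:
    """Triangle search on the bright (right-hand) tail of the histogram."""
    peak = int(np.argmax(counts))
    last = int(np.flatnonzero(counts)[-1])
    if last <= peak:
        return peak
    b = np.arange(peak, last + 1, dtype=np.float64)
    h = counts[peak:last + 1].astype(np.float64)
    # signed perpendicular distance below the peak->tail-end line; the common
    # line-length denominator is dropped because it does not move the argmax:
    # d(b) ∝ (h_last - h_peak)·(b - peak) - (last - peak)·(h_b - h_peak)
    d = (h[-1] - h[0]) * (b - peak) - (last - peak) * (h - h[0])
    return peak + int(np.argmax(d))  # argmax takes the first (nearest peak) tie


def binarize(img: GrayImage8, roi: np.ndarray, threshold: int) -> np.ndarray:
    """Mask of pixels strictly above the threshold, gated to the ROI."""
    if not 0 <= threshold <= 255:
        raise ValidationError("threshold must be in [0, 255]")
    return (img > threshold) & roi


def label_particles(mask: np.ndarray) -> List[Particle]:
    """Measure every 8-connected component of a boolean mask."""
    labels = measure.label(mask, connectivity=2)
    out: List[Particle] = []
    for rp in measure.regionprops(labels):
        area = int(rp.area)
        perim = float(rp.perimeter)
        circ = 1.0 if perim <= 0 else min(1.0, 4.0 * np.pi * area / perim**2)
        out.append(Particle(label=int(rp.label), area=area, perimeter=perim,
                            circularity=circ, centroid=tuple(rp.centroid),
                            bbox=tuple(rp.bbox)))
    return out


def filter_particles(particles: List[Particle], params: FilterParams
                     ) -> Tuple[List[Particle], List[RejectedParticle]]:
    """Split particles into accepted and rejected (area checked first)."""
    accepted, rejected = [], []
    for p in particles:
        if p.area > params.max_area:
            rejected.append(RejectedParticle(p, "area"))
        elif p.circularity < params.min_circularity:
            rejected.append(RejectedParticle(p, "circularity"))
        else:
            accepted.append(p)
    return accepted, rejected


def count_staining(img: RGBImage, roi: ROISpec | np.ndarray,
                   pre_params: PreprocessParams | None = None,
                   filt: FilterParams | None = None,
                   fill_holes: bool = False,
                   exclude_border: bool = False) -> StainingResult:
    """The full counting pipeline on one photograph.

    ``roi`` may be an :class:`ROISpec` (rasterized here) or a boolean mask.
    Deterministic end to end: reruns are bit-identical, and mirrored input
    with a mirrored ROI yields the same count.
    """
    pre_params = pre_params or PreprocessParams()
    filt = filt or FilterParams()
    if img.height < 32 or img.width < 32:
        raise ValidationError("pipeline needs an image of at least 32 x 32")
    if isinstance(roi, ROISpec):
        roi_mask = rasterize_roi(roi, img.height, img.width)
    else:
        roi_mask = np.asarray(roi, dtype=bool)
        if roi_mask.shape != (img.height, img.width):
            raise ValidationError("ROI mask shape does not match the image")
        if not roi_mask.any():
            raise ValidationError("ROI mask is empty")
    residual = preprocess_pipeline(img, roi_mask, pre_params)
    hist = Histogram256.from_image(residual, roi_mask)
    thr = triangle_threshold(hist, bright_objects=True)
    mask = binarize(residual, roi_mask, thr)
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if exclude_border:
        from skimage.segmentation import clear_border
        mask = clear_border(mask)
    particles = label_particles(mask)
    accepted, rejected = filter_particles(particles, filt)
    return StainingResult(count=len(accepted), accepted=accepted,
                          rejected=rejected, threshold=int(thr),
                          binary_mask=mask, params=pre_params, filters=filt)
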