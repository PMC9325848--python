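"""Image and ROI input/output, plus the horizontal mirror transform.

Coordinate convention (used everywhere in this package): arrays are
row-major and 0-based, pixel centers sit at integer coordinates, and a
coordinate pair ``(x, y)`` in an ROI file means ``(column, row)``.

ROI files are small JSON documents::

    {"kind": "ellipse", "center": [cx, cy], "semi_axes": [rx, ry]}
    {"kind": "polygon", "vertices": [[x0, y0], [x1, y1], ...]}

A pixel belongs to the mask iff its center lies inside (or exactly on the
boundary of) the shape: even-odd rule for polygons, the standard ellipse
inequality ``((x-cx)/rx)**2 + ((y-cy)/ry)**2 <= 1`` for ellipses.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from ._util import round_half_up_div
from .errors import FormatError, ROIError, ValidationError

logger = logging.getLogger(__name__)

_BOUNDARY_TOL2 = 1e-18  # squared distance tolerance for "center on the edge"


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB raster (H x W x 3, uint8)."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValidationError(f"expected H x W x 3 pixels, got shape {p.shape}")
        if p.dtype != np.uint8:
            if np.issubdtype(p.dtype, np.integer) and p.min() >= 0 and p.max() <= 255:
                p = p.astype(np.uint8)
            else:
                raise ValidationError("pixel values must be integers in [0, 255]")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROISpec:
    """Corneal region of interest: a polygon or an ellipse.

    ``polygon`` vertices and the ellipse ``center`` use (x, y) =
    (column, row) order.
    """

    kind: str
    vertices: tuple = field(default=())
    center: tuple = field(default=())
    semi_axes: tuple = field(default=())

    def __post_init__(self):
        if self.kind == "polygon":
            v = tuple((float(x), float(y)) for x, y in self.vertices)
            if len(v) < 3:
                raise ROIError(f"polygon needs >= 3 vertices, got {len(v)}")
            if not all(np.isfinite(c) for xy in v for c in xy):
                raise ROIError("polygon vertices must be finite")
            object.__setattr__(self, "vertices", v)
        elif self.kind == "ellipse":
            cx, cy = (float(c) for c in self.center)
            rx, ry = (float(r) for r in self.semi_axes)
            if not (np.isfinite([cx, cy, rx, ry]).all() and rx > 0 and ry > 0):
                raise ROIError("ellipse needs finite center and positive semi-axes")
            object.__setattr__(self, "center", (cx, cy))
            object.__setattr__(self, "semi_axes", (rx, ry))
        else:
            raise ROIError(f"unknown ROI kind {self.kind!r}")

    @classmethod
    def ellipse(cls, cx: float, cy: float, rx: float, ry: float) -> "ROISpec":
        return cls(kind="ellipse", center=(cx, cy), semi_axes=(rx, ry))

    @classmethod
    def polygon(cls, vertices: Sequence[Sequence[float]]) -> "ROISpec":
        return cls(kind="polygon", vertices=tuple(tuple(v) for v in vertices))

    def mirrored(self, width: int) -> "ROISpec":
        """The ROI matching a horizontally mirrored image of the given width."""
        if self.kind == "ellipse":
            cx, cy = self.center
            return ROISpec.ellipse((width - 1) - cx, cy, *self.semi_axes)
        return ROISpec.polygon([((width - 1) - x, y) for x, y in self.vertices])

    def to_json(self, path: str | os.PathLike) -> None:
        if self.kind == "ellipse":
            doc = {"kind": "ellipse", "center": list(self.center),
                   "semi_axes": list(self.semi_axes)}
        else:
            doc = {"kind": "polygon", "vertices": [list(v) for v in self.vertices]}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ROISpec":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ROIError(f"cannot read ROI file {path}: {exc}") from exc
        kind = doc.get("kind")
        if kind == "ellipse":
            return cls.ellipse(*doc["center"], *doc["semi_axes"])
        if kind == "polygon":
            return cls.polygon(doc["vertices"])
        raise ROIError(f"unknown ROI kind {kind!r} in {path}")


def load_image(path: str | os.PathLike) -> RGBImage:
    """Read a PNG/TIFF/JPEG image as an 8-bit RGB raster.

    Grayscale sources are rejected (the pipeline needs a green channel);
    an alpha channel is dropped; 16-bit sources are linearly rescaled to
    8 bit per channel (v * 255 / 65535, rounded half-up).
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise FormatError(f"{path}: single-channel image; an RGB image is required")
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise FormatError(f"{path}: unsupported image shape {arr.shape}")
    if arr.shape[2] == 4:
        logger.debug("%s: dropping alpha channel", path)
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = round_half_up_div(arr.astype(np.int64) * 255, 65535).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported pixel type {arr.dtype}")
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".jpg", ".jpeg"):
        logger.warning("%s: JPEG compression may perturb particle counts", path)
    return RGBImage(arr)


def save_image(img: RGBImage, path: str | os.PathLike) -> None:
    """Write an 8-bit RGB raster as PNG or TIFF (bit-exact round trip)."""
    try:
        iio.imwrite(path, img.pixels)
    except OSError as exc:
        raise FormatError(f"cannot write image {path}: {exc}") from exc


def mirror_horizontal(img: RGBImage) -> RGBImage:
    """Reverse the column order. An exact involution."""
    return RGBImage(np.ascontiguousarray(img.pixels[:, ::-1, :]))


def rasterize_roi(spec: ROISpec, height: int, width: int) -> np.ndarray:
    """Rasterize an ROI spec to an H x W boolean mask.

    Pixel-center-inclusive: a center exactly on the shape boundary is in.
    Raises :class:`ROIError` if no pixel falls inside the shape.
    """
    xs = np.arange(width, dtype=np.float64)[None, :]
    ys = np.arange(height, dtype=np.float64)[:, None]
    if spec.kind == "ellipse":
        cx, cy = spec.center
        rx, ry = spec.semi_axes
        mask = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0 + 1e-12
    else:
        mask = _polygon_mask(spec.vertices, ys, xs)
    if not mask.any():
        raise ROIError("ROI covers no pixel centers inside the image bounds")
    return mask


def _polygon_mask(vertices, ys, xs) -> np.ndarray:
    """Even-odd interior test plus exact on-boundary inclusion."""
    inside = np.zeros(np.broadcast_shapes(ys.shape, xs.shape), dtype=bool)
    on_edge = np.zeros_like(inside)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # even-odd ray cast toward +x, half-open in y so vertices count once
        crosses = (y1 > ys) != (y2 > ys)
        if np.any(crosses):
            xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1) if y2 != y1 else np.inf
            inside ^= crosses & (xs < xint)
        # distance of each pixel center to the closed segment
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            d2 = (xs - x1) ** 2 + (ys - y1) ** 2
        else:
            t = np.clip(((xs - x1) * dx + (ys - y1) * dy) / seg2, 0.0, 1.0)
            d2 = (xs - (x1 + t * dx)) ** 2 + (ys - (y1 + t * dy)) ** 2
        on_edge |= d2 <= _BOUNDARY_TOL2
    return inside | on_edge


def save_overlay(img: RGBImage, result, path: str | os.PathLike,
                 roi_mask: np.ndarray | None = None) -> None:
    """Write a presentation overlay PNG plus the binary particle mask.

    Accepted particles are outlined in red on the original image and the ROI
    boundary in yellow; the mask (two pixel values, 0 and 255) is written
    next to the overlay with a ``_mask`` suffix.  Purely presentational.
    """
    from skimage.measure import label as sk_label
    from skimage.segmentation import find_boundaries

    canvas = img.pixels.copy()
    if result.accepted:
        labels = sk_label(result.binary_mask, connectivity=2)
        accept_mask = np.isin(labels, [p.label for p in result.accepted])
        edges = find_boundaries(accept_mask, mode="outer")
        canvas[edges] = (255, 0, 0)
    if roi_mask is not None:
        rim = find_boundaries(roi_mask, mode="inner")
        canvas[rim] = (255, 255, 0)
    root, ext = os.path.splitext(str(path))
    try:
        iio.imwrite(path, canvas)
        iio.imwrite(f"{root}_mask.png", (result.binary_mask.astype(np.uint8) * 255))
    except OSError as exc:
        raise FormatError(f"cannot write overlay {path}: {exc}") from exc
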