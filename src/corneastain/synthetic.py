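"""Seeded generator of synthetic slit-lamp-like corneal images.

The generator emulates the structure the counting pipeline assumes: a dark
surround (lids/sclera), a corneal ellipse behind which the iris and pupil
are visible through the green fluorescein glow, bright near-circular
punctate lesions with Gaussian intensity profiles, and tear-film/mucus
artifacts (large pooling blobs and elongated strands) that the particle
filters are supposed to reject.  Every image carries its ground truth, and
a fixed seed reproduces the image bit for bit.

Scene intensity design mirrors how these photographs are actually taken.
A yellow barrier filter passes almost pure fluorescence, so iris and pupil
leak into the green channel only as faint, heavily defocused modulation at
spatial scales the pseudo-background removes; the analysis ROI is drawn
inside the limbus, as a clinician draws it, so the bright-to-dark step at
the corneal border stays outside the analysed region; and every frame
carries the corneal light reflex (flash specular highlight) — a large,
round, saturated blob that the > 200 px area filter rejects but that
anchors the intensity histogram's bright tail, which keeps the triangle
threshold stable whether or not the cornea carries staining.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ._util import round_half_up
from .errors import ValidationError
from .image_io import RGBImage, ROISpec
from .preprocess import PreprocessParams
from .segmentation import FilterParams, count_staining

#: severity grade -> inclusive (min, max) planted compliant spot count.
#: Log-like steps; even a grade-0 dry-eye cornea shows trace staining.
DEFAULT_GRADE_COUNTS: Dict[int, Tuple[int, int]] = {
    0: (1, 3), 1: (4, 9), 2: (10, 30), 3: (31, 80), 4: (81, 160), 5: (161, 300),
}

#: fixed count -> grade bins induced by DEFAULT_GRADE_COUNTS (upper edges)
GRADE_BIN_EDGES: Tuple[int, ...] = (3, 9, 30, 80, 160)

# geometry defaults (pixels)
_SHAPE = (600, 600)
_CORNEA_CENTER = (300.0, 300.0)  # (cx, cy)
_CORNEA_AXES = (315.0, 285.0)    # rendered corneal disc (rx, ry)
_ROI_AXES = (270.0, 245.0)       # analysis ROI, drawn inside the limbus
_PUPIL_RADIUS = 60.0

# placement margins (pixels): keep spots clear of the ROI rim, the pupil
# margin, other spots and artifacts, so planted spots stay isolated
# particles after thresholding.
_RIM_MARGIN = 25.0
_PUPIL_BAND = 14.0
_MIN_SPOT_SEP = 14.0
_ARTIFACT_CLEARANCE = 16


def count_to_grade(count: int) -> int:
    """Map a particle count to the ordinal 0-5 severity bin."""
    return int(np.searchsorted(GRADE_BIN_EDGES, count, side="left"))


@dataclass(frozen=True)
class SpotSpec:
    """One punctate lesion: Gaussian profile, near-circular."""

    x: float
    y: float
    radius: float = 3.0        # nominal radius; profile sigma = radius / 2
    peak: float = 140.0        # added green intensity at the center
    eccentricity: float = 0.0  # 0 = circular; axes scaled by (1 ± e)
    angle: float = 0.0         # orientation of the long axis, radians


@dataclass(frozen=True)
class ArtifactSpec:
    """A tear-film/mucus mimic: 'pool' (large blob) or 'strand' (elongated)."""

    kind: str                  # "pool" | "strand"
    x: float
    y: float
    intensity: float = 110.0
    size: float = 30.0         # pool: arc reach; strand: half-length
    angle: float = 0.0
    seed: int = 0              # shapes the pool's random blob lobes


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic cornea image."""

    shape: Tuple[int, int] = _SHAPE
    cornea_center: Tuple[float, float] = _CORNEA_CENTER
    cornea_axes: Tuple[float, float] = _CORNEA_AXES
    roi_axes: Tuple[float, float] = _ROI_AXES
    pupil_radius: float = _PUPIL_RADIUS
    base_green: float = 225.0        # peak fluorescein glow level
    shading: float = 0.45            # radial glow fall-off fraction at the rim
    tilt: float = 0.05               # illumination gradient, gray levels / px
    highlight: Tuple[float, float, float, float] | None = (300.0, 190.0, 18.0, 320.0)
    #: corneal light reflex (x, y, radius, intensity): the flash specular
    #: blob every slit-lamp photograph carries; big and round, it is
    #: rejected by the area filter but anchors the intensity histogram
    spots: Tuple[SpotSpec, ...] = ()
    artifacts: Tuple[ArtifactSpec, ...] = ()
    noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self):
        H, W = self.shape
        if H < 32 or W < 32:
            raise ValidationError("scene must be at least 32 x 32")
        cx, cy = self.cornea_center
        rx, ry = self.roi_axes
        for s in self.spots:
            rho2 = ((s.x - cx) / rx) ** 2 + ((s.y - cy) / ry) ** 2
            if rho2 > 0.97:
                raise ValidationError(
                    f"spot at ({s.x:.0f}, {s.y:.0f}) lies outside the cornea")
            if s.radius <= 0 or s.peak <= 0:
                raise ValidationError("spot radius and peak must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-image truth record for a generated scene."""

    planted_compliant_count: int
    planted_artifact_count: int
    severity_grade: int
    spots: Tuple[SpotSpec, ...] = ()
    artifacts: Tuple[ArtifactSpec, ...] = ()


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-std smooth random field (iris texture / surround mottle)."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _render_spots(green: np.ndarray, spots: Sequence[SpotSpec]) -> None:
    H, W = green.shape
    for s in spots:
        sig = s.radius / 2.0
        sx, sy = sig * (1.0 + s.eccentricity), sig / (1.0 + s.eccentricity)
        reach = int(np.ceil(4 * max(sx, sy))) + 1
        x0, x1 = max(0, int(s.x) - reach), min(W, int(s.x) + reach + 1)
        y0, y1 = max(0, int(s.y) - reach), min(H, int(s.y) + reach + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - s.x, yy - s.y
        c, sn = np.cos(s.angle), np.sin(s.angle)
        u, v = c * dx + sn * dy, -sn * dx + c * dy
        green[y0:y1, x0:x1] += s.peak * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def _render_artifacts(green: np.ndarray, artifacts: Sequence[ArtifactSpec]) -> None:
    H, W = green.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    for a in artifacts:
        if a.kind == "pool":
            arng = np.random.default_rng([int(a.seed), 2])
            n_lobes = int(arng.integers(5, 9))
            along = arng.uniform(-a.size, a.size, n_lobes)
            across = arng.uniform(-0.3 * a.size, 0.3 * a.size, n_lobes)
            sig = arng.uniform(8.0, 14.0, n_lobes)
            amp = a.intensity * arng.uniform(0.6, 1.0, n_lobes)
            c, sn = np.cos(a.angle), np.sin(a.angle)
            for t, q, sg, am in zip(along, across, sig, amp):
                lx, ly = a.x + c * t - sn * q, a.y + sn * t + c * q
                green += am * np.exp(-((xx - lx) ** 2 + (yy - ly) ** 2) / (2 * sg**2))
        elif a.kind == "strand":
            c, sn = np.cos(a.angle), np.sin(a.angle)
            u = c * (xx - a.x) + sn * (yy - a.y)
            v = -sn * (xx - a.x) + c * (yy - a.y)
            u_clamped = np.clip(u, -a.size, a.size)
            d2 = (u - u_clamped) ** 2 + v**2
            green += a.intensity * np.exp(-d2 / (2 * 1.4**2))
        else:
            raise ValidationError(f"unknown artifact kind {a.kind!r}")


def artifact_support(spec: SceneSpec) -> np.ndarray:
    """Boolean mask of pixels materially touched by the scene's artifacts."""
    layer = np.zeros(spec.shape, dtype=np.float64)
    _render_artifacts(layer, spec.artifacts)
    return layer > 2.0


def generate_cornea_image(spec: SceneSpec) -> Tuple[RGBImage, ROISpec, GroundTruth]:
    """Render a scene. Identical spec (incl. seed) => identical image."""
    H, W = spec.shape
    rng = np.random.default_rng([int(spec.seed), 1])
    cx, cy = spec.cornea_center
    rx, ry = spec.cornea_axes
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    rho2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    cornea = rho2 <= 1.0
    pupil_d = np.hypot(xx - cx, yy - cy)

    # Background structure seen through the glow.  With a yellow barrier
    # filter the green channel is almost pure fluorescence: the iris and
    # pupil leak through only as faint, heavily defocused modulation, at
    # spatial scales well above the background-subtraction kernel (radius
    # 14), so the pseudo-background removes them; punctate lesions are the
    # only small-scale bright structure, as the counting method assumes.
    texture = _smooth_field(rng, (H, W), 20.0)
    theta = np.arctan2(yy - cy, xx - cx)
    striation = np.sin(8.0 * theta + rng.uniform(0, 2 * np.pi))
    pupil_dip = np.where(pupil_d <= spec.pupil_radius, 1.0, 0.0)
    pupil_dip = ndi.gaussian_filter(pupil_dip, 30.0, mode="nearest")
    leak = 0.96 + 0.0015 * texture + 0.001 * striation - 0.02 * pupil_dip

    # one-sided diffuse illumination: a gentle intensity tilt across the
    # globe; keeps the glow free of flat plateaus
    tilt_ang = rng.uniform(0, 2 * np.pi)
    tilt = spec.tilt * (np.cos(tilt_ang) * (xx - cx) + np.sin(tilt_ang) * (yy - cy))
    glow = spec.base_green * (1.0 - spec.shading * rho2) + tilt
    green = np.where(cornea, glow * np.clip(leak, 0.0, 1.2) + 6.0, 0.0)
    surround = 14.0 + 4.0 * _smooth_field(rng, (H, W), 11.0)
    green = np.where(cornea, green, np.clip(surround, 0, None) * 0.6)

    if spec.highlight is not None:
        hx, hy, hr, hi_int = spec.highlight
        d2 = (xx - hx) ** 2 + (yy - hy) ** 2
        green += hi_int * np.exp(-d2 / (2 * (hr / 1.6) ** 2))
    _render_spots(green, spec.spots)
    if spec.artifacts:
        _render_artifacts(green, spec.artifacts)

    iris_vis = 0.55 + 0.3 * np.clip(texture, -1, 1) - 0.4 * pupil_dip
    red = np.where(cornea, 40.0 * np.clip(iris_vis, 0, 1.2) + 10.0, surround)
    blue = np.where(cornea, 22.0 * np.clip(iris_vis, 0, 1.2) + 8.0,
                    0.8 * surround)
    img = np.stack([red, green, blue], axis=-1)
    if spec.noise_sigma > 0:
        # mild demosaicing correlation, as camera pipelines produce
        noise = rng.normal(0.0, 1.0, img.shape)
        noise = ndi.gaussian_filter(noise, (0.6, 0.6, 0.0), mode="wrap")
        noise *= spec.noise_sigma / noise[:, :, 1].std()
        img = img + noise
    pixels = np.clip(round_half_up(img), 0, 255).astype(np.uint8)

    roi = ROISpec.ellipse(cx, cy, *spec.roi_axes)
    truth = GroundTruth(planted_compliant_count=len(spec.spots),
                        planted_artifact_count=len(spec.artifacts),
                        severity_grade=count_to_grade(len(spec.spots)),
                        spots=spec.spots, artifacts=spec.artifacts)
    return RGBImage(pixels), roi, truth


# ---------------------------------------------------------------------------
# random scene construction

def _derive_image_seed(master_seed: int, index: int) -> int:
    """Stated counter scheme: seeds are a fixed affine function of the index."""
    return int((int(master_seed) * 1_000_003 + 7_919 * int(index)) % (2**31))


def _sample_spot_centers(rng: np.random.Generator, n: int, spec: SceneSpec,
                         keepout: np.ndarray | None) -> np.ndarray:
    """Dart-throwing placement respecting rim/pupil/artifact/spot margins."""
    cx, cy = spec.cornea_center
    rx, ry = spec.roi_axes
    placed = np.empty((0, 2))
    attempts = 0
    max_attempts = 4000 + 1200 * n
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(cx - rx, cx + rx)
        y = rng.uniform(cy - ry, cy + ry)
        if ((x - cx) / (rx - _RIM_MARGIN)) ** 2 + ((y - cy) / (ry - _RIM_MARGIN)) ** 2 > 1:
            continue
        if abs(np.hypot(x - cx, y - cy) - spec.pupil_radius) < _PUPIL_BAND:
            continue
        if spec.highlight is not None:
            hx, hy, hr, _ = spec.highlight
            if np.hypot(x - hx, y - hy) < hr + 25.0:
                continue
        if keepout is not None and keepout[int(round(y)), int(round(x))]:
            continue
        if len(placed) and (np.hypot(placed[:, 0] - x, placed[:, 1] - y)
                            < _MIN_SPOT_SEP).any():
            continue
        placed = np.vstack([placed, (x, y)])
    if len(placed) < n:
        raise ValidationError(
            f"could not place {n} spots with the required separation")
    return placed


def random_scene(n_spots: int, seed: int, noise_sigma: float = 0.25,
                 with_artifacts: bool = False,
                 base: SceneSpec | None = None) -> SceneSpec:
    """A reproducible random scene with ``n_spots`` compliant spots."""
    base = base or SceneSpec(seed=seed, noise_sigma=noise_sigma)
    rng = np.random.default_rng([int(seed), 0])
    cx, cy = base.cornea_center
    rx, ry = base.cornea_axes

    artifacts: List[ArtifactSpec] = ()
    keepout = None
    if with_artifacts:
        arts = []
        if rng.random() < 0.75:  # tear-film pool low on the cornea
            ang = rng.uniform(0.25 * np.pi, 0.75 * np.pi)
            rad = rng.uniform(0.45, 0.7)
            arts.append(ArtifactSpec(
                kind="pool", x=cx + rad * rx * np.cos(ang) * 0.9,
                y=cy + rad * ry * np.sin(ang) * 0.9,
                intensity=rng.uniform(90, 130), size=rng.uniform(24, 40),
                angle=rng.uniform(0, np.pi), seed=int(rng.integers(2**31))))
        if rng.random() < 0.6:  # mucus strand
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.2, 0.55)
            arts.append(ArtifactSpec(
                kind="strand", x=cx + rad * rx * np.cos(ang),
                y=cy + rad * ry * np.sin(ang),
                intensity=rng.uniform(90, 130), size=rng.uniform(18, 28),
                angle=rng.uniform(0, np.pi)))
        artifacts = tuple(arts)
        if artifacts:
            probe = replace(base, spots=(), artifacts=artifacts)
            support = artifact_support(probe)
            dist = ndi.distance_transform_edt(~support)
            keepout = dist < _ARTIFACT_CLEARANCE

    centers = _sample_spot_centers(rng, n_spots, base, keepout)
    spots = tuple(
        SpotSpec(x=float(x), y=float(y),
                 radius=float(rng.uniform(2.0, 4.0)),
                 peak=float(rng.uniform(110.0, 170.0)),
                 eccentricity=float(rng.uniform(0.0, 0.2)),
                 angle=float(rng.uniform(0.0, np.pi)))
        for x, y in centers)
    return replace(base, seed=seed, noise_sigma=noise_sigma,
                   spots=spots, artifacts=artifacts)


def verify_spot_compliance(spot: SpotSpec, base: SceneSpec | None = None) -> bool:
    """Render the spot alone (noise-free) and run it through the pipeline.

    Operational compliance check: the isolated spot must binarize into a
    single particle with area <= 200 px and circularity >= 0.7.
    """
    base = base or SceneSpec()
    cx, cy = base.cornea_center
    centred = replace(spot, x=cx, y=cy + base.pupil_radius + 60.0)
    scene = replace(base, spots=(centred,), artifacts=(), noise_sigma=0.0)
    img, roi, _ = generate_cornea_image(scene)
    res = count_staining(img, roi, PreprocessParams(), FilterParams())
    return res.count == 1 and not any(r.reason for r in res.rejected
                                      if abs(r.particle.centroid[0] - centred.y) < 8
                                      and abs(r.particle.centroid[1] - centred.x) < 8)


def generate_dataset(n_images: int,
                     grade_to_count_map: Dict[int, Tuple[int, int]] | None = None,
                     seed: int = 0, noise_sigma: float = 0.25,
                     with_artifacts: bool = True
                     ) -> Tuple[List[Tuple[RGBImage, ROISpec, GroundTruth]],
                                pd.DataFrame]:
    """A severity-graded synthetic dataset with its truth table.

    Grades cycle 0..5 so every grade is represented once ``n_images >= 6``;
    the planted count is drawn uniformly from the grade's range.  Per-image
    seeds derive from the master seed by a fixed counter scheme, so the
    dataset is reproducible element-wise.
    """
    if n_images < 1:
        raise ValidationError("n_images must be >= 1")
    gmap = grade_to_count_map if grade_to_count_map is not None else DEFAULT_GRADE_COUNTS
    if not gmap:
        raise ValidationError("grade_to_count_map must not be empty")
    grades = sorted(gmap)
    items, rows = [], []
    for i in range(n_images):
        g = grades[i % len(grades)]
        img_seed = _derive_image_seed(seed, i)
        rng = np.random.default_rng([img_seed, 3])
        lo, hi = gmap[g]
        n_spots = int(rng.integers(lo, hi + 1))
        scene = random_scene(n_spots, seed=img_seed, noise_sigma=noise_sigma,
                             with_artifacts=with_artifacts)
        img, roi, truth = generate_cornea_image(scene)
        truth = replace(truth, severity_grade=g)
        items.append((img, roi, truth))
        rows.append({"image_index": i, "seed": img_seed, "grade": g,
                     "planted_count": truth.planted_compliant_count,
                     "n_artifacts": truth.planted_artifact_count})
    return items, pd.DataFrame(rows)
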