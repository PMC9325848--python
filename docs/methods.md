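# Methods

## The counting model

The package treats superficial punctate keratopathy as a collection of
small, bright, near-circular objects superimposed on a smooth fluorescent
background. The pipeline assumes:

* staining is *brighter* than its local surroundings in the green channel;
* background structure (iris, pupil, tear film, illumination shading)
  varies on spatial scales well above the lesion scale, so a heavily
  smoothed copy of the image (the pseudo-background) captures it;
* artifacts that survive background subtraction are either large
  (tear-film pooling, specular reflexes) or elongated (mucus strands),
  and are separable from lesions by area and circularity.

Stages, all pure functions of their inputs:

1. green channel (8-bit by the I/O contract; 16-bit sources are linearly
   rescaled at load, `v·255/65535` rounded half-up);
2. saturated linear contrast stretch over ROI pixels: `lo`/`hi` are the
   `s/2` and `1−s/2` ROI quantiles (default saturated fraction
   s = 0.0035), `v ↦ clamp(round((v−lo)·255/(hi−lo)), 0, 255)`;
   pixels outside the ROI pass through unchanged;
3. pseudo-background = disc-mean filter (radius 14 px) then Gaussian blur
   (σ = 2 px), borders by edge replication, each stage rounded half-up
   back to a legal 8-bit image;
4. residual = `max(image − background, 0)`;
5. triangle threshold on the 256-bin ROI histogram of the residual:
   a line joins the histogram peak to the last nonzero bin of the longer
   tail; the threshold is the bin farthest (perpendicular distance) below
   that line, ties broken toward the peak. With bright objects (the
   default) the histogram is flipped first if the longer tail lies on the
   dark side and the result mapped back, so foreground is always
   *strictly above* the threshold;
6. 8-connected components, measured with scikit-image regionprops;
   perimeter is the weighted crack-length estimator (unit foreground/
   background edges with corner-smoothing weights); circularity
   `min(1, 4πA/P²)`, with degenerate particles of estimated perimeter 0
   (single pixels, dominoes) counted as circular — tiny round lesions
   must not be rejected by a perimeter convention;
7. accept iff `A ≤ 200` and `circularity ≥ 0.7` (both boundaries
   inclusive: the elimination rules are strict inequalities). Rejected
   particles carry their first violated rule, area checked first.
   Border particles are retained; holes are not filled (both behaviours
   are exposed as flags, off by default).

### Numerical choices

Exactness is load-bearing: the headline claim about automated grading is
perfect self-agreement, including under horizontal mirroring. Floating
convolutions do not guarantee that (summation order changes under
mirroring, and a value landing on a rounding boundary could flip). The
disc-mean filter therefore runs on integer integral images, and the
Gaussian blur uses a symmetric integer-quantised kernel (weights
`round(2^16·exp(−i²/2σ²))`, support radius `round(4σ)`), with a single
exact round-half-up division at the end. Every intermediate sum stays
below 2^53, so the arithmetic is exact, order-independent, and mirror
equivariance holds bit-for-bit inside any ROI at least
`radius + 4σ` pixels from the image border.

Degenerate inputs: a single-bin residual histogram returns that bin with
a warning (zero particles downstream); a flat ROI histogram makes the
contrast stretch a warned no-op; an empty ROI raster is an error.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `saturation_fraction` | 0.0035 | fraction of ROI pixels saturated by the stretch |
| `background_radius` | 14 px | disc-mean radius of the pseudo-background |
| `background_sigma` | 2.0 px | Gaussian blur of the pseudo-background |
| `kernel_shape` | disc | mean-filter footprint (square available for sensitivity checks) |
| `max_area` | 200 px | largest accepted particle |
| `min_circularity` | 0.7 | roundness floor, `4πA/P²` |

The size filter counts raw pixels: it is resolution-dependent, and counts
are comparable only between images taken at the same magnification.
"Automatic contrast enhancement" is implemented as the saturated stretch
with the 0.35% convention (the long-standing default of the classic
enhance-contrast command) computed over ROI statistics; stretching happens
before background subtraction, and the pseudo-background applies the mean
filter first, then the blur. Both orderings are fixed conventions of this
implementation.

## The synthetic cornea generator

The generator renders the structure the algorithm assumes, with per-image
ground truth:

* a dark lid/sclera surround; a corneal disc (ellipse, semi-axes 315×285
  px on a 600×600 frame) carrying a fluorescein glow (peak 225, radial
  fall-off 45% at the rim) with a gentle one-sided illumination tilt
  (0.05 gray/px) so the field has no flat plateaus;
* faint, heavily defocused iris/pupil leak-through in the green channel.
  With a yellow barrier filter the green channel is almost pure
  fluorescence, so background structure is weak and smooth (texture
  fields smoothed at σ ≥ 20 px); the red/blue channels carry a visible
  iris/pupil for appearance only;
* the analysis ROI is an ellipse (270×245 px) strictly inside the limbus,
  as a clinician draws it, keeping the bright-to-dark corneal border out
  of the analysed region;
* the corneal light reflex: a large saturated specular blob (~1100–1600
  px after thresholding) present in every frame. The area filter rejects
  it, and its clipped tail anchors the residual histogram at 255, which
  stabilises the triangle threshold whether or not the image carries
  staining;
* punctate lesions: Gaussian profiles, radius 2–4 px (profile σ =
  radius/2), peak 110–170 gray, eccentricity ≤ 0.2. Compliance (one
  particle, area ≤ 200, circularity ≥ 0.7) is verified operationally by
  rendering a lesion in isolation and running the measurement chain
  (`verify_spot_compliance`);
* artifacts: tear-film "pools" (clusters of 5–8 Gaussian lobes, rendered
  area ≫ 200 px) and mucus "strands" (elongated ridges, circularity ≪
  0.7) — both kinds the particle filters must reject;
* placement by dart throwing with margins: ≥ 30 px inside the ROI rim,
  ≥ 14 px between lesion centres, outside a ±14 px band at the pupil
  margin, ≥ 16 px from artifact support and ≥ 43 px from the reflex, so
  planted lesions stay isolated particles after thresholding;
* additive Gaussian sensor noise, default σ = 0.25 gray with mild spatial
  correlation (σ = 0.6 px), emulating well-exposed flash photography
  after in-camera demosaicing; rounded half-up and clipped to 8 bit.

The default severity map assigns lesion-count ranges per Oxford-like
grade: 0 → 1–3, 1 → 4–9, 2 → 10–30, 3 → 31–80, 4 → 81–160, 5 → 161–300 —
roughly tripling per grade, matching the logarithmic character of
pictogram scales, and reflecting that a DED cohort shows trace staining
even at grade 0. Per-image seeds derive from the master seed by the fixed
counter scheme `(seed·1000003 + 7919·i) mod 2^31`, so datasets are
reproducible element-wise.

### Noise tolerance (and its limits)

The triangle construction places the threshold near the elbow of the
residual histogram's main peak — at roughly 3–3.5 standard deviations of
the post-stretch noise. Over an ROI of ~1.4·10^5 pixels, noise alone
would then push hundreds of pixels over the threshold; with no minimum
particle size in the published filter rules, each isolated speck counts.
Two properties keep the default regime clean: the contrast stretch gain
is bounded (the scene spans a wide intensity range, and the specular
reflex pins the upper quantile), and at post-stretch noise ≲ 1.5 gray the
8-bit quantisation pushes the discrete threshold to an effective 4–5σ,
beyond which the expected speck count is ~0–5 per image. This envelope
(stretch × noise σ ≲ 1.5 gray) is the algorithm's operating regime; at
several gray levels of pixel noise the counter sees hundreds of
supra-threshold specks and its counts are no longer meaningful. The
pipeline contains no denoising stage, faithfully to the method it
reimplements, so the generator's default noise is chosen inside the
envelope and the limitation is stated here rather than patched.

### What passing tests show — and what they do not

Noise-free, artifact-free scenes are recovered *exactly* at planted
counts 0–300; artifact insertion never changes the accepted count on
noise-free fixtures; at default noise, counts carry a small (+0–5)
speck bias and artifact borders can absorb or shed a chance speck.
The synthetic severity benchmark (Spearman ρ ≈ 0.98 over 30 images)
demonstrates that the pipeline orders *well-separated, compliant* lesion
burdens correctly — it is a clean-regime lower-bound surrogate, not a
clinical validation. Real photographs add confluent staining (merged
lesions counted as one or rejected by size), limbal irregularity,
variable magnification (the 200 px filter!), tear-film dynamics and
focus/exposure variation, none of which the generator models.
Human-grader statistics (the deviation-table summaries) are computed
from a bundled reference panel of 22 graders and exercise only the
statistics code, not the image pipeline.

## Agreement statistics

* **Estimated-true grade**: per-image mode across graders, all sessions
  pooled by default (a session switch is provided); ties break to the
  *lower* grade by default (conservative severity; `higher` and
  rounded-`mean` rules available).
* **Deviation tables**: per grader, the percentage of gradings at each
  absolute deviation 0–4 from the estimated-true grade, to 2 decimals.
  Row sums are asserted to reach 100% only for internally generated
  tables; imported tables are summarised as-is.
* **Cohen's κ**: unweighted, categories 0–5, pairwise-complete deletion;
  if both raters use one identical category, chance agreement is 1 and κ
  is reported as 1 by convention, flagged in the report.
* **Fleiss' κ**: standard formula; requires an equal number of raters per
  image (subset to pairwise-complete data first).
* **Spearman's ρ**: midrank ties, t-approximation p-value (n−2 df);
  p < 0.05 is flagged significant.
* **ICC(2,1)**: two-way random effects, absolute agreement, single rater,
  from the mean-squares decomposition. The variant is fixed and named,
  since ICC values are not comparable across conventions.
* **Landis–Koch bands**: <0 poor, 0–0.20 slight, 0.21–0.40 fair,
  0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect.
  Values are rounded half-up to the table's printed two decimals before
  banding, so 0.405 → moderate and 0.404 → fair.

Cohen/Fleiss/ICC are direct numpy implementations of the closed-form
definitions (they are also exercised against scikit-learn, statsmodels
and pingouin in the test suite, and against Monte-Carlo nulls at 10^4
replicates); Spearman delegates to scipy. Weighted κ and concordance
correlation are deliberately out of scope: the toolkit mirrors an
unweighted-κ study design, where κ asks "identical grade or not" and
ICC credits near-misses — the contrast between the two is part of the
intended analysis.

## Design choices that were genuinely open

* **Coordinate convention**: row-major, 0-based, pixel centres at integer
  coordinates; `(x, y)` in ROI files means (column, row). Polygon
  rasterization uses the even-odd rule with centres on the boundary
  included (checked against a shapely `covers` oracle).
* **Binarization convention**: foreground strictly above the threshold.
  The other closed convention would shift every count; one had to be
  declared and held fixed.
* **Connectivity**: 8-connected, the usual choice for bright-spot
  counting; a diagonal pair is one particle.
* **Triangle variant semantics**: the flip-and-map-back behaviour for
  dark-tailed histograms is declared (threshold maps to `255 − t`),
  tested against an independent brute-force oracle on 1000 random
  histograms, and scale-invariance of the construction is asserted.
* **Histogram scope**: ROI pixels only, so structure outside the cornea
  cannot shift the threshold.
* **JPEG**: accepted with a logged warning (slit-lamp cameras commonly
  emit JPEG), but excluded from bit-exact round-trip guarantees.

## Known limitations

Resolution-dependent size filter; no confluent-staining area measure; no
color calibration between cameras; no interactive ROI drawing; the noise
envelope above. The synthetic benchmark bounds the method's behaviour
from the clean side only.
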