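# Methods

`neoscan` quantifies neonatal cranial B-mode ultrasound frames along two
axes used in clinical echogenicity assessment: **echo intensity** (how
bright a region is relative to a reference structure) and **echo
homogeneity** (how uniform its speckle texture is).  The pipeline is
crop → adaptive median filter → CLAHE → region masks → quantification;
every stage is deterministic, so a run is reproducible bit for bit from
its configuration.

## Preprocessing

**Margin crop.** Exported sector images carry black annotation margins.
A row or column is classified as margin iff its fraction of zero-valued
pixels is at least `zero_fraction_threshold` (default **0.95**); the crop
window is bounded by the first and last non-margin row/column scanned
inward from each edge.  The 0.95 default tolerates occasional zero-valued
speckle pixels inside the sector while still catching margins that
contain overlay text (a margin row need not be perfectly black).  A fully
black image has no content region and is rejected.  Cropping is
idempotent: a cropped image contains no margin rows, so a second crop is
the identity.

**Adaptive median filter.** Two-level scheme with a growing square
window (defaults: initial **3**, maximum **7**, both odd; borders by edge
replication).  Per pixel with value `f`:

* *Level A*: compute `z_min`, `z_med`, `z_max` over the window.  If
  `z_min < z_med < z_max` the window median is not itself an extreme
  (impulse) value — proceed to Level B.  Otherwise grow the window by 2;
  if it would exceed the maximum, output `z_med` from the largest window.
* *Level B*: if `z_min < f < z_max` the center pixel is not an impulse —
  output `f` unchanged; otherwise output `z_med`.

The strict inequalities make the decision unambiguous on constant or
two-valued neighborhoods (both degenerate to `z_med` of the largest
window, which is the background value).  A window limit of 7 restores
essentially all corrupted pixels at impulse fractions up to ~10% on
homogeneous tissue while leaving clean pixels untouched — the suite
checks ≥ 99% restoration at 5% noise on a 256×256 constant phantom, and
100% of uncorrupted pixels unchanged.  The window statistics come from
`scipy.ndimage` rank filters; the Level A/B control flow is applied
vectorised over the undecided pixel set.

**Histogram equalization (baseline).** The classical global mapping
`s_k = round((L−1) · Σ_{j≤k} n_j / MN)` with `L = 256`.  It is monotone
non-decreasing by construction and maps a constant image to level 255
(its single level has cumulative fraction 1).  Kept as the comparison
baseline: on frames mixing bright and dark areas it over-amplifies the
bright side.

**CLAHE.** Contrast-limited adaptive histogram equalization with:

* a tile *grid* (default **8×8 tiles**; the right/bottom tiles absorb
  the remainder when the image dimensions are not divisible);
* per tile, the average count over occupied gray levels
  `G_bar = (m×n)/G_n` (tile pixels over occupied levels) and a truncation
  value `C = clip_factor × G_bar` (default `clip_factor` **4**, rounded
  to an integer; `clip_factor → ∞` degenerates to unclipped per-tile
  equalization).  Bins are capped at `C`; the excess `S` is redistributed
  in one pass, `S ÷ G_n` to every occupied level with the integer
  residual assigned one unit each to the lowest-indexed occupied levels.
  This conserves the tile's pixel count exactly and is fully
  deterministic.  Redistribution may lift a bin slightly above `C`
  again; the single pass accepts that, as is conventional.
* per-tile equalization of the clipped histogram, then per-pixel
  bilinear interpolation between the four nearest *tile-center*
  mappings; outside the outer tile-center lattice the nearest mapping is
  clamped.  With one tile and no clipping this reproduces plain
  histogram equalization bit-exactly.

All gray-level roundings are half away from zero, applied after clipping
to [0, 255].

## Region geometry

Pixel `(i, j)` has its center at coordinates `(i, j)`, 0-based.  ROIs
are closed polygons (freehand outlines are supplied as dense vertex
lists): a pixel belongs to the ROI iff its center is inside under the
even-odd rule, with centers exactly on an edge included — a
deterministic tie-break that makes e.g. an 11×11 vertex-aligned square
select exactly 121 pixels.  The reference region is a disc: centers at
Euclidean distance ≤ radius.  The reference radius is a required
configuration value (no principled default exists; the clinical
workflow fixes "a circle of fixed size" without stating it).  Boundary
extraction returns the selected pixels with at least one 4-neighbor
outside the mask (or on the image border), for overlay rendering.

## Echo intensity

The gray mean `M = Σ_r r·p(r)` over a masked region equals the
arithmetic mean of the masked pixel values and is kept at full floating
precision.  The **relative gray value** is `100 × M_roi / M_ref`.  The
×100 scale is deliberate: the published convention reports the ratio on
a percent-like scale (144.2773 / 252.7574 is reported as 57.0813), and
this package emits the same scale.  Presentation rounding is 4 decimals,
half away from zero; full precision is always retained in the JSON
reports.

## Echo homogeneity

Texture is summarised by gray-level co-occurrence matrices (GLCMs).
Gray values are first binned into `G` equal-width levels by
`floor(v·G/256)` (default **G = 16**: coarse enough that an ROI of a few
thousand pixels populates the matrix, and consistent with published
energy magnitudes of ~0.07–0.14, which a 256-level matrix could not
produce).  For a compass offset `(Δr, Δc)` and distance `d` (default
**1**), ordered pairs are counted over all pixels whose pair partner
also lies inside the mask — the mask itself, not its bounding box,
defines the region.  By default the transpose is added (**symmetric**
GLCM) and the matrix normalised to sum 1.

Four standard features are computed per direction:

* energy `ENE = Σ P²` (angular second moment),
* inverse difference moment `IDM = Σ P/(1+(i−j)²)`,
* contrast `CON = Σ (i−j)²·P` (inertia),
* entropy `ENT = −Σ_{P>0} P·log P`, base **2** by default (base *e*
  configurable; the choice is recorded in every report since published
  entropy scales cannot be pinned down without the source images).

All four are transpose-invariant, so opposite directions are equal
whether or not the GLCM is symmetrised — which is why reported tables
duplicate E at W, N at S, and so on.  Aggregates follow the reported
column layout: `E–W = (E+W)/2`, `N–S = (N+S)/2`, `Cross` the mean of the
four axis-aligned directions, `Circle` the mean of all eight.  In
heterogeneous tissue ENT and CON rise while ENE and IDM fall; the suite
asserts this ordering between a lesion ROI and an equal-sized background
ROI on a seeded phantom.

## Synthetic phantoms

The generator emulates the features of a cranial frame that the
pipeline's stages act on, with exact ground truth:

* **Speckle** — multiplicative gamma noise: each pixel is its mean gray
  value times a gamma factor with unit mean and standard deviation
  `speckle_scale` (shape `1/s²`, scale `s²`), the conventional
  multi-look amplitude model.  `speckle_scale = 0` gives a noise-free,
  piecewise-constant phantom whose region means are recovered exactly.
* **Lesions** — polygons with a raised mean; heterogeneity is a
  low-frequency modulation of the lesion mean (a coarse Gaussian grid at
  8 px pitch, bilinearly upsampled, scaled by the heterogeneity
  parameter and floored at −95%).  The modulation has zero expectation,
  so lesion pixels keep their nominal expected mean, while measured ENT
  and CON rise monotonically with the heterogeneity scale on matched
  seeds (the field is drawn on a fixed stream so phantoms differing only
  in amplitude share their speckle realisation).
* **Margins** — an exact zero band of configurable width, the crop
  stage's target.
* **Impulse noise** — exactly `round(fraction × pixels)` replaced, half
  (rounding up) with 0 and half with 255, reproducibly from the seed;
  inside `generate_phantom` it is confined to the interior so the margin
  stays exactly zero.

Values are clipped to [0, 255] then rounded half away from zero.
Identical specs (including the seed) are bit-identical.

The phantom is *not* an acoustic simulation: no beamforming, attenuation,
shadowing, anisotropic point-spread, or anatomy.  Passing tests
therefore demonstrate the correctness of the measurement pipeline, not
the clinical performance of the measures on patient images — the
original study's absolute table values and figures depend on source
images that are not available and are deliberately not numeric targets
here; only the arithmetic that connects printed means to relative gray
values and printed directional cells to their aggregates is reproduced
exactly.

**Parameter recovery.** On phantoms with lesion mean 200 and reference
mean 250, the recovered relative gray value is checked to lie within 3
standard errors of 80.0 over 20 seeds.  This experiment uses
`speckle_scale = 0.01`: near gray 250 the 8-bit ceiling truncates the
upper tail of multiplicative noise, biasing the reference mean downward
(≈ 0.4 gray at scale 0.02, ≈ 0.02 gray at 0.01), so the scale is chosen
to keep that saturation bias negligible against the Monte-Carlo band.
At larger speckle scales the ceiling makes the ratio estimator biased
high — a genuine limitation of ratio-based echogenicity near saturation,
not of the phantom.

## Numerical and design choices

* Rounding: gray-level outputs half away from zero; 4-decimal table
  presentation via decimal `ROUND_HALF_UP` (published tables mix half-up
  and half-down at exact halves, so cross-checks against them use an
  absolute tolerance of 1e−4).
* Degenerate inputs: empty masks, fully black images, polygons with
  fewer than 3 vertices or empty interior, circles outside the image,
  offsets with no valid pixel pair, and zero reference means are all
  rejected with explicit errors rather than propagating NaNs.
* The pipeline config is versioned YAML with unknown keys rejected
  (fail-fast); per-plane failures are recorded as machine-readable
  records while remaining planes continue; the run log records all
  parameters and SHA-256 checksums of every stage raster.
* Test problem sizes — phantoms up to 256×256, GLCM oracle images up to
  8×8 at G ≤ 4, 20-seed recovery runs — are chosen so the full suite
  settles in seconds while each check retains its statistical power.

## Known limitations

* The interactive freehand/ellipse selection of the original workflow is
  replaced by explicit geometry in the config; there is no GUI.
* GLCM quantization, distance, entropy base and the reference radius are
  exposed as configuration because no authoritative values exist; the
  defaults above are this package's own choices.
* Only single-frame 8-bit grayscale input is supported (no DICOM, cine
  loops, or color Doppler).
* No clinical decision rule is implemented; the package reports numbers
  only.
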