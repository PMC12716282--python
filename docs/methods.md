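# Methods

`wingfa` measures bilateral asymmetry of paired insect wings — the kind of
measurement used to assess developmental instability in odonates under
environmental stress — and relates it to stressor covariates through a GLM
layer. This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations.

## The measurement model

For one individual the input is a left and a right wing, each represented as
a `WingGeometry`: the outer outline polygon, the membrane cells (polygons
tiling the outline interior), and the vein junctions (points where at least
three veins meet), all in micrometres with anatomical "up" as +y.

**Alignment.** The right wing is reflected across the vertical axis, both
wings are translated to their outline area-centroids, and the right wing is
rotated to minimize the mean nearest-point distance between the two
outlines, resampled to 500 arc-length-uniform points. The rotation is found
by a coarse grid search (2° steps over a configurable range) refined by
bounded golden-section search to 1e-4 rad; the zero angle is always
evaluated so that an exact mirror pair aligns exactly. No scaling is
applied: size asymmetry is part of the signal and is reported separately.

**Sister matching.** Cells are matched one-to-one by the Hungarian
algorithm on centroid distances, junctions likewise; pairs farther apart
than 25% of the wing length stay unmatched. Unmatched elements are excluded
from trait comparisons but counted in the subtract values.

**The asymmetry inventory.** Per pair the record holds: NRMSE of cell area,
length, width and circularity over matched sister cells — RMSE divided by
the mean of the reference side, computed in both comparison directions
(left as reference, then right) and averaged; mean Euclidean distances over
matched junctions and cell centroids; the symmetric mean nearest-point
distance between resampled outlines; the absolute cell- and junction-count
differences (subtract values); and pair-mean size variables (area,
perimeter, length, width — outline-based, reported in mm/mm²) plus their
absolute side differences. Cell length and width are principal-axis extents
of the vertex cloud (rotation invariant); circularity is the isoperimetric
quotient 4πA/P². Wing load is wet weight over pair-mean wing area (mg/mm²).

**Landmark FA.** Twelve landmarks per wing enter a generalized Procrustes
analysis (translation to centroid, unit centroid size, iterative rotation
to the consensus; convergence 1e-10, at most 100 iterations), fitted
separately per sex so shape dimorphism cannot leak into asymmetry
components; right configurations are reflected first (matching symmetry —
wings are paired organs, not one symmetric object). Each individual's
left-minus-right difference in shape space splits into the cohort mean
(directional asymmetry) and an individual FA component; the FA score is the
full Euclidean norm of that component (tangent projection is omitted — at
the shape variances involved, ~1e-2, the difference is far below the noise).
FA components sum to zero across individuals by construction. No automatic
outlier exclusion is applied.

**Screening.** Before an FA interpretation, signed left-minus-right trait
differences are screened: a one-sample t-test against a zero mean flags
directional asymmetry; a D'Agostino normality test combined with Sarle's
bimodality coefficient (> 5/9) flags antisymmetry. The bimodality
coefficient replaces a dip-statistic gate: it needs no resampled critical
values, and for the relevant alternative (a ±c mixture) its population
value (~0.94) is far above the gate while a Gaussian sits at ~0.33.

**Spatial maps.** Per matched sister pair, a local asymmetry value — the
absolute trait difference as a percentage of the reference side, averaged
over both directions, or the sister-centroid distance in µm — is anchored
at the mean sister-centroid position. All wings are superimposed into a
common frame: the outline is brought into its principal-axis frame (major
axis horizontal, tip direction fixed by the sign of the third moment along
the axis, which makes the construction rotation invariant), a line fitted
through the upper-edge points (top 10% of y within the middle 80% of x)
gives a final refinement rotation about the centre of gravity, and the
centre of gravity is translated to the origin. Each wing's scattered values
are linearly (barycentric, Delaunay-based) interpolated onto a 300 × 300
grid over its convex hull; the group grid is the pointwise mean over wings,
with nodes outside every hull left missing rather than zero-filled. For
circularity and width the pooled lower and upper 5% of values are excluded
per group before gridding (a reproducible form of the usual visualization
trim; a switch allows global trimming instead). Difference maps are
treatment minus control on co-valid nodes, Gaussian-blurred with σ = 10
grid cells using mask-normalized blurring (blur of values over blur of the
validity mask), so missing regions never fabricate low asymmetry. Positive
values mean asymmetry increased under the stressor.

## The model layer

Count responses (days to emergence, cell and junction counts, subtract
values) are fitted with Poisson GLMs with log link; all other responses
with gaussian identity-link models. Pair means of counts can be
half-integers and are rounded with a warning. Per-coefficient inference
uses t-tests (gaussian) and Wald z-tests (Poisson). For the 2 × 2 factorial
mode, Type-II likelihood-ratio χ² tests compare nested fits per term
(each main effect against the additive model without it; the interaction
against the full model). For gaussian models the LR statistic uses the
fixed-scale profile-deviance convention n·log(RSS_reduced/RSS_full). The
dose mode enters concentration as a continuous covariate in mg/L by
default; a factor coding is available for per-level contrasts. No
multiple-testing correction is applied by default (a Benjamini–Hochberg
switch exists). Model fitting is delegated to statsmodels (OLS / GLM-IRLS);
the test suite cross-checks coefficients against independent normal-
equation and Newton-scoring oracles.

Effect sizes are predicted percentage changes relative to the control
group: predictions are generated for every observed covariate row with the
contrasted factor set counterfactually (hence averaged over the levels of
the other factors), and group means are compared with the baseline mean.
Two standard errors are reported: `se_pred`, the within-combination
prediction spread divided by √n relative to the baseline mean — a
descriptive spread, not a sampling SE — and `se_wald`, a delta-method SE
propagated from the coefficient covariance, which is the one to use for
coverage statements about the estimate.

Residual diagnostics are numerical stand-ins for the usual visual checks: a
normality test on (deviance) residuals and the slope of √|standardized
residual| against fitted values.

## The synthetic study conditions

The generator emulates the data structure of a damselfly wing-pair study;
its defaults are the package's study conditions:

- **Geometry.** Wing length 20 mm, length/width 4.5, ~250 target cells per
  wing (real damselfly wings carry roughly 100–400; the per-wing count is
  configurable and the realized count follows from the lattice).
  The tessellation is a rectangular lattice, smoothly deformed by a
  low-frequency random field (per individual) and clipped to an
  elliptical-teardrop outline; the outline is the boundary of the kept
  cells, so cells tile the interior exactly. This is deliberately not a
  biological venation model: every downstream metric is geometry-agnostic.
- **FA channel.** Independent per-side Gaussian jitter on all lattice nodes
  (junctions), default sd 50 µm; cell polygons follow their nodes, so the
  same noise drives positional and shape asymmetry. The matched-junction
  displacement is then Rayleigh with scale sd·√2 (mean ≈ 1.25·sd·√2
  ≈ 89 µm at default), putting mean distances near the ~100 µm scale seen
  in real material. `fa_shape_sd` adds node jitter proportional to the
  lattice pitch (a per-cell polygon perturbation would break the tiling).
  A regional switch multiplies the jitter sd (default × 3) in the proximal
  or distal half only, for localization experiments.
- **Directional asymmetry / antisymmetry.** A constant translation applied
  to right-wing nodes; an antisymmetry switch applies it with a random sign
  per individual.
- **Count perturbation.** With probability 0.5 per wing, one merge (remove
  a shared edge) or split (halve a quad through mid-edge nodes, updating
  neighbours) event, giving subtract values of 0–2 per pair.
- **Landmarks.** Twelve anchors at fixed relative positions (leading-edge
  nodus, basal cross veins, interior radius points, media branches,
  pterostigma margin analogues), passed through the same deformation field
  and per-side jitter. At default settings FA scores land near 0.013 shape
  units, matching the order of magnitude reported for real wings.
- **Cohort.** Sexes alternate within design cells; males are 5% smaller
  (size) and 12% lighter. Wet weight is lognormal (female median 24 mg,
  CV 12%); days to emergence Poisson with mean 28.2. Between-individual
  wing length is lognormal with CV 4%. An `effect_map` scales generator
  parameters per factor — multiplicatively at the active level of a binary
  factor, linearly interpolated up to the maximum of a continuous dose.
- **Determinism.** One master seed; per-individual streams are derived by
  counter-based `SeedSequence` spawning, so cohorts are bit-reproducible
  and independent of generation order.

What the generator does *not* emulate: real venation topology (longitudinal
veins, pterostigma), correlated measurement error from photography,
allometry beyond a single size multiplier, and wing damage. Passing tests
therefore demonstrate that the measurement and inference machinery is
correct and calibrated on data with known truth — not that any biological
effect size in real wings is reproduced.

## Numerical choices and degenerate inputs

- Exact mirror pairs produce exactly zero asymmetry (the zero angle is
  always a rotation candidate; reflection and centroid translation are
  exact in floating point).
- Principal-axis extents are unstable for near-isotropic polygons (a
  square's axes are arbitrary); on rasterized near-square cells this puts a
  floor of roughly 0.1 on NRMSE(length/width) at 20 µm/px, while area and
  circularity floors are ~0.03 and ~0.005. Geometry-path inputs do not
  suffer from this (mirrored cells have identical covariance).
- Skeleton branch points localize junctions to about 1–2 px at 2 px vein
  width; degree counts branches leaving a small ring around the branch
  cluster, which is robust to 4-way crossings skeletonizing as two 3-way
  points.
- Hungarian matching slightly *underestimates* true correspondence
  distances: the optimal assignment can beat the true bijection, and the
  attenuation grows with jitter relative to cell pitch (about −25% at
  jitter 1.5× the default against an ~800 µm pitch). Truth-calibrated
  recovery checks therefore use the landmark FA score, which involves no
  assignment and scales exactly linearly in the jitter sd; matched-distance
  responses are checked for significance and direction.
- Alignment couples the wing halves: strong regional jitter degrades the
  global outline fit and inflates matched distances everywhere, so regional
  injections raise the distal signal most but not exclusively.
- Degenerate tessellations (multiple boundary loops) are regenerated from a
  perturbed stream, at most 10 attempts. Collinear landmark configurations,
  open vein networks, empty match sets and zero-area cells raise explicit
  errors or warnings rather than propagating silently.
- The side-swap invariance of the pair record holds to ~1e-3 relative, not
  exactly: the rotation objective is evaluated right-onto-left.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at desk scale, chosen as the package's own
test conditions: effect-recovery replicates use 2×2 cohorts with 30
individuals per cell (60 per factor arm) and ~100-cell wings, combining the
size effect (×1.25 on one factor) and the jitter effect (×1.5 on the
other) in one factorial; type-I calibration uses 500 measurement-free null
cohorts of 160 individuals; screening power uses n = 100 with 200
replicates; spatial localization uses 20 wings per group. The acceptance
script reruns the same computations with fewer replicates (12 recovery
cohorts, 200 null cohorts) and reports the measured quantities.
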