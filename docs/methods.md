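# Methods

## Scope and data model

The unit of analysis is one fundus image with a set of disc tracings:
an expert `ground_truth` plus one tracing per rater (`od1`, `od2`).  A
tracing is either a filled binary raster (`TraceMask`) or an ordered
boundary path (`Polyline`, sub-pixel vertices).  Coordinates are
0-based raster coordinates, `x` = column, `y` = row, `y` down; angles
are measured in degrees from +x toward +y.  Every image carries a
dataset label (resolution cohort) and a retinal-condition label
(`glaucoma`, `dr`, `normal`); all stratified results group by these.

Polylines are rasterized by inclusive pixel-center coverage: a pixel
is foreground iff its center lies inside or on the closed polygon.
Ellipses are rasterized with the same center rule, so polygon and
ellipse rasters are comparable without a systematic half-ring bias.
Boundary extraction returns the ordered outer contour (Moore-neighbor
tracing with Jacob's stopping criterion) of the largest 8-connected
component: stray islands are annotation artifacts, and interior holes
are not part of a disc outline.

## Agreement and precision statistics

**Bounding-box Cohen's kappa.**  Pixels far from the disc are
background for every rater, so whole-image kappa saturates; the
statistic is therefore computed inside the tight union bounding box of
the two compared masks (margin 0 by default; an `all`-tracings box and
a margin are available as options).  `P_o` is the fraction of box
pixels with equal labels, `P_e = p_a p_b + (1−p_a)(1−p_b)` from the
foreground fractions, `κ = (P_o − P_e)/(1 − P_e)`, with `κ := 1` when
`P_e = 1` (both masks constant and equal — trivial perfect agreement
rather than 0/0).  The *border* variant applies the same formula to
the outer-contour bands of the two masks dilated by a disk of radius
`border_tolerance` (default 2 px): identical borders give 1, borders
offset by more than twice the tolerance give chance-level values near
0.  The border construction is this package's definition; it is the
natural strict counterpart of the region variant.

**Dice.**  `2|A∩B|/(|A|+|B|)` over foreground pixels; undefined (an
error) only when both masks are empty.

**Average boundary distance μ_d.**  Rays are cast from the *reference*
tracing's area centroid (ground truth when it is part of the pair) at
a fixed direction set; along each ray, the distance to the farthest
foreground sample (0.25 px sampling, half-up pixel rounding) is the
boundary distance of that tracing.  μ_d is the mean absolute
difference between the two tracings' distances over directions where
both are defined; undefined directions are excluded and counted, and a
result with a majority of undefined directions is flagged.  The
farthest-sample rule is deterministic for filled masks, insensitive to
interior holes, and deliberately sensitive to detached misaligned
strokes (they *should* register as boundary error).  The default
direction set is uniform 30° spacing (12 directions); an alternative
irregular 12-direction list (with one 20° entry, as sometimes printed)
is available as `angle_set="paper-literal"` for sensitivity analysis.
μ_d is reported in pixels of the native grid; no physical calibration
is attempted.  For the rater-vs-rater pair, which has no ground truth,
`od1` is the declared reference and the row is flagged accordingly.

**Interpretation bands.**  Aggregate kappas carry the conventional
labels (poor / fair / moderate / substantial / almost perfect, plus
less-than-chance below zero).  The customary two-decimal cut-offs
(0.21–0.40 fair, …) are realized with half-step edges (0.205, 0.405,
…) so every real value falls in exactly one band.

## Direct least-squares ellipse fitting

The repair for misaligned tracings fits the conic
`Ax² + Bxy + Cy² + Dx + Ey + F = 0` under the ellipse constraint
`4AC − B² = 1` by minimizing summed squared algebraic distance.  The
design matrix is split into a quadratic block `D1` (rows `x², xy, y²`)
and a linear block `D2` (rows `x, y, 1`); with `S1 = D1ᵀD1`,
`S2 = D1ᵀD2`, `S3 = D2ᵀD2` and the constraint matrix
`C1 = [[0,0,2],[0,−1,0],[2,0,0]]`, the quadratic half is the
eigenvector of `M = C1⁻¹(S1 − S2 S3⁻¹ S2ᵀ)` with positive constraint
value `4a₁a₃ − a₂²` (unique in exact arithmetic; numerically the
largest positive value is taken), and the linear half follows as
`a₂ = −S3⁻¹S2ᵀa₁`.  Points are centered on their mean and scaled to
RMS radius √2 before the fit and the conic mapped back — raw pixel
coordinates in the thousands make `S1` ill-conditioned; the
conditioning is mathematically equivalent.  The geometric parameters
(center, semi-axes, rotation in [0, π), circle → rotation 0) come from
the gradient-zero center and the eigen-decomposition of the quadratic
form.  A 6×6 one-shot constrained generalized eigenproblem serves as
an independent test oracle, never as the implementation.

When the fit input is a mask contour, both fitted semi-axes are grown
by 0.5 px: contour pixel centers lie on average half a pixel inside
the underlying boundary, and without the compensation every
mask-contour refit shrinks systematically.  Polyline input is fitted
as-is — including misaligned segments, since absorbing them is the
purpose of the fit.

In the study pipeline, ellipse fitting is applied to rater tracings
only; ground truth stays fixed (refitting the reference would change
the thing being measured — a `refit_ground_truth` flag exists for
sensitivity analysis).  A failed fit (degenerate points) falls back to
the raw tracing and flags the record.

### What ellipse fitting can and cannot repair

A radially displaced stroke arc is not orthogonal to the ellipse
family: a 60°-wide arc projects substantially onto the constant,
first- and second-harmonic components of the boundary, which an
ellipse *can* represent, so the fit follows part of the displacement
(measured: roughly three quarters of an 8 px offset at arc center)
while distributing the rest around the boundary.  Consequently the fit
reliably reduces the *peak* boundary error inside the arc but does not
necessarily increase per-image dice; across a study with occasional
misalignments the median dice and rater-pair region kappa do improve,
because most images are arc-free and there the fit simply removes
jitter.  Conversely, when the true disc is materially non-elliptic,
forcing an ellipse strictly loses shape information and dice drops.
Both directions are asserted by the test suite; neither is assumed.

## The synthetic observer model

`generate_study` emulates the conditions of a two-rater tracing study:

* **True discs.**  Per image an ellipse with semi-axes uniform in
  8–14% of the image width, rotation uniform in [0, π), center in the
  middle 38–62% of the frame (discs must fit with margin).  A smooth
  angular perturbation (harmonics 2–4, random coefficients and phases,
  normalized peak amplitude; default amplitude 0.05) makes truths
  slightly non-elliptic, as real discs are.
* **Raters.**  The true boundary is sampled at 1° by ray casting from
  the true center; each rater adds zero-mean Gaussian radial jitter
  (od1 sd 1.5 px, od2 sd 2.5 px — od1 is deliberately the more precise
  rater so rater-order bugs are detectable), then with probability
  0.1 per image one contiguous 60° arc is displaced radially by +8 px
  (the misalignment model: a parametric stand-in for a stylus
  calibration slip), and the radii are smoothed by a circular 5-sample
  moving average (hand strokes are smooth).  Boundaries are generated
  in polar form about the true center and are therefore star-convex
  outside misaligned arcs, keeping the ray-casting metrics well
  defined.
* **PPA confusion.**  For glaucomatous images only, both raters get a
  systematic +6 px outward bias in the superior (60–120°) and inferior
  (240–300°) sectors — the regions where distinguishing disc border
  from peripapillary atrophy is hardest.  This single mechanism
  reproduces the qualitative study findings: glaucoma shows the lowest
  border kappa and the highest boundary distance of the three
  conditions, while region kappa and dice barely move.
* **Composition and resolution.**  69 glaucoma + 37 normal images on a
  724×486 grid (a quarter-scale high-resolution cohort, keeping
  desk-scale runtimes) and 53 diabetic-retinopathy images at 768×576
  (native low-resolution cohort) — 159 images, preserving the
  resolution asymmetry that makes pixel distances larger in the
  high-resolution cohort.

None of the rater-error magnitudes is documented for the real study;
the values above are this package's calibration choices, fixed once.
Determinism: every image receives a child RNG spawned from the study
seed, so studies are bit-reproducible and per-image content does not
depend on the composition of other strata.

**What passing tests show — and what they do not.**  The generator
produces star-convex, radially perturbed discs with parametric error
modes.  Real tracings add effects it does not model: vessel-bend
shortcuts, blur- and illumination-dependent boundary uncertainty,
freehand stroke topology (self-crossings, gaps), and rater fatigue.
Tests passing on synthetic studies validate the *metrics, the fit, and
the pipeline logic* — including the direction of every effect built
into the generator — not the magnitudes one should expect from human
annotators.  Absolute synthetic agreement values are higher than
human ones.

## Pipeline and aggregation

`run_study` scores the three pairs (od1–od2, od1–gt, od2–gt) for every
image, twice (raw and ellipse-fitted rater tracings), and aggregates
by unweighted per-image means within (pair × dataset × fitted) and
(pair × condition × fitted) strata — distributions of per-image
values, never pooled pixels, so large images do not dominate.  A
single-row stratum equals its row.  Flags (fit fallback, excluded
directions, empty tracings, μ_d reference choice) travel from the
metric level into the per-image report rows.  Reports serialize to
per-image CSV, aggregate CSV/JSON, and a markdown summary laid out as
pairs × (metric × stratum) with separate before/after blocks.

## Numerical choices and edge cases

* Ray sampling 0.25 px with half-up rounding (`floor(x+0.5)`): half-up
  keeps all metrics exactly invariant under joint integer translation
  of the scene; banker's rounding does not.  Diagonal rays carry an
  inherent half-pixel-diagonal (≈0.71 px) quantization.
* Kappa `P_e = 1` → κ := 1; empty tracings flag the pair and skip its
  metrics rather than erroring the study; a study whose rows are all
  unusable is an error.
* Eigenvector choice in the fit: largest positive constraint value;
  complex eigenpairs (numerical) are skipped.
* Simulated radii are clipped below at 1 px; undefined cast radii on a
  non-star-convex truth are repaired by circular interpolation before
  the observer noise is applied.
* Problem sizes in the shipped tests were chosen for desk-scale runs:
  unit fixtures use ~200–360 px grids, study-level checks use 10–50
  images, and the full 159-image default study is exercised at three
  seeds; the acceptance script runs one full study per invocation.

## Known limitations

* The border-kappa construction (dilated boundary bands) is a
  reasonable strict-agreement definition but not the only possible
  one; tolerance changes its scale.
* μ_d assumes the centroid lies inside the disc and rays meet the
  boundary once per direction; grossly non-star-convex tracings are
  only partially captured (flagged via undefined directions).
* The ellipse repair is global: it cannot fix a misalignment without
  touching the rest of the boundary (quantified above).
* Synthetic magnitudes are not calibrated to human raters; only
  directions of effects are meaningful for comparison with real
  studies.
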