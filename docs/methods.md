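# Methods

This note documents the models, conventions and numerical choices behind
`dwidistort`, and what the synthetic generator does and does not emulate.

## Coordinate and anatomical conventions

Volumes are arrays indexed `(slice k, row j, column i)` with spacing
`(dz, dy, dx)` in mm. The fixed anatomical convention is slice index apex →
base (Superior), row index anterior → posterior, column index patient-right →
patient-left, i.e. nibabel axis codes `(S, P, L)`. NIfTI volumes stored in
any orientation are permuted/flipped to this convention on read (the applied
transform is logged), so "posterior" means the same thing in supine and prone
acquisitions — prone data are assumed stored in patient-anatomical
orientation, not scanner orientation.

Voxel indices are 0-based; physical in-plane coordinates are voxel-center
based: a voxel center sits at `(x, y) = (i·dx, j·dy)`. Contours are closed
planar polygons in these mm coordinates within each axial slice.

## Rasterization and contour extraction

A voxel belongs to a contour iff its center is inside the polygon under the
even-odd crossing rule with the conventional half-open boundary treatment
(lower/left boundary in, upper/right out). This makes rasterization
deterministic and tiling-consistent: an axis-aligned W×H mm rectangle on
1 mm voxels covers exactly W·H voxels. Boundary coincidences only arise for
exactly axis-aligned synthetic shapes; real and generated contours meet voxel
centers with probability zero.

Contours are recovered from masks by subpixel marching squares at the 0.5
level of the binary mask, which places the polygon midway between inside and
outside voxel centers; rasterize → extract → rasterize is therefore
idempotent on the voxel set. When a slice fragments into several connected
components, the largest-area outline is kept and a warning is emitted —
prostate slices have one outline; phantom apex slices may fragment.

## Registration

Default registration is translation-only, aligning binary-mask centers of
mass. EPI susceptibility distortion is predominantly a local displacement
along the phase-encode axis; rigid rotation risks absorbing genuine
distortion into pose, so the rigid mode (principal-axis alignment with the
axis sign — 180° ambiguity — resolved by maximizing Dice, near-ties resolved
to the smallest rotation) is provided only for sensitivity analysis.
Registration uses masks, never intensities, and sub-voxel translations are
applied to contours in continuous mm space rather than by resampling masks,
which would add rasterization noise to a metric whose interesting scale is
a fraction of a voxel. The chosen transform never has lower Dice than the
identity. Through-plane translations reassign contour slices by rounding the
transformed slice coordinate to the nearest index, halves rounding down.

## Polar distortion metric

For each slice paired by index between the reference and the (registered)
ADC contour set, both outlines are sampled at 1° increments about a single
origin: the **reference** contour's area centroid. Using each contour's own
centroid instead would cancel bulk displacement of the ADC outline, which is
genuine distortion once rigid motion has been removed by registration.

The radius at angle θ is the distance to the farthest boundary intersection
of the ray — deterministic for mildly non-star-shaped contours (rays crossing
the boundary more than twice are counted and reported). The ray–segment
solver uses a ±1e−9 endpoint tolerance so rays passing exactly through a
shared polygon vertex register on at least one adjacent segment; duplicate
hits are harmless since only the farthest is kept. Signed residuals
Δr(θ) = r_ADC − r_ref are stored; only their squares enter the reduction.

The whole-gland RMS pools every (slice, angle) sample with equal weight; the
posterior RMS restricts to θ ∈ [1°, 180°] (exactly 180 angles; 0° = +x =
patient left, 90° = +y = posterior). Pooling across slices versus averaging
per-slice RMS values is a genuine ambiguity; both are implemented
(`pooling="pooled"` default, `"per_slice"` alternative) and differ only when
slice counts or residual variances are unbalanced. Identical contour sets
give exactly zero. Slices present in only one acquisition are dropped and
counted.

## Rectal air and proximity volume

Air is segmented as voxels inside the rectum outline with intensity below a
threshold, split into face-connected components, discarding components of
fewer than 5 voxels as noise. The threshold is user-supplied; the `"auto"`
default takes the 2.5th percentile of the volume's intensity distribution,
appropriate for T1/DCE volumes where air is far darker than any tissue.

`Rectal Air_prox` is the volume of air whose Euclidean distance to the
nearest prostate voxel is at most 20 mm, computed with an
anisotropic-spacing-aware distance transform — equivalent to dilating the
prostate volume by 20 mm and intersecting with air, and verified
voxel-exactly against an all-pairs distance oracle in the tests. Distance is
measured to the prostate surface, not its centroid, because proximity to the
rectoprostatic interface is what drives the susceptibility artefact.
Volumes are voxel counts × voxel volume, reported in cm³.

## Cohort statistics

* **Descriptives** — median and quartiles with the linear-interpolation
  convention.
* **Wilcoxon signed-rank** (paired, two-sided) — zero differences dropped
  (Wilcoxon's original convention); exact null distribution for n ≤ 25
  without ties in |d|, otherwise normal approximation with continuity and
  tie correction. Delegates to scipy; tests verify the exact branch equals
  full sign-assignment enumeration.
* **Fisher exact** (two-sided, minimum-likelihood summation) on the
  dichotomized Likert table; verified against fixed-margin enumeration.
* **Gwet's AC2** for two raters with quadratic weights
  w_kl = 1 − (k−l)²/(q−1)²: observed agreement is the mean weighted
  agreement across subjects; chance agreement is
  p_e = T_w/(q(q−1)) · Σ_k π_k(1−π_k) with π_k the category propensity
  averaged over raters and T_w the sum of all weights (Gwet, *Br J Math Stat
  Psychol* 2008). AC2 = (p_a − p_e)/(1 − p_e), with the usual verbal
  benchmark bands attached. Implemented from scratch (no installed package
  provides it) and checked against a hand-worked ten-subject example.
* **Air threshold** — univariate logistic regression
  P(appreciable) = σ(β₀ + β₁·air) on supine proximal air volumes versus the
  Likert ≥ 4 judgement; `V_thresh-air = −β₀/β₁`, the volume at predicted
  probability 0.5 (for a univariate monotone model, coincident with the
  Youden-optimal probability cut). Perfect separation is reported as the
  midpoint between the class-extreme volumes with a flag rather than a
  divergent estimate; a non-positive slope is refused. β is estimated by
  statsmodels and cross-checked against an independent Newton–Raphson fit.
* **Subgroup analysis** — the paired comparisons are repeated in the
  subgroup with supine air above the threshold; subgroups under 5 patients
  are reported as not evaluable. The 5-point rectal-air Likert scale uses
  ≥ 4 as "appreciable" throughout.

No multiplicity correction is applied across tests.

## Synthetic generator

**Phantoms.** An ellipsoidal prostate (semi-axes 20×16×18 mm in x/y/z, with
a smooth low-order angular surface perturbation) on a 20×96×96 grid at
3×1×1 mm; an elliptical-tube rectum posterior to it on the same slices; an
air pocket of exactly the requested volume (voxel-quantized, hence within
5% for ≥ 0.5 cm³) filling the rectum voxels nearest the prostate when
supine and farthest when prone, mimicking gravity; an intensity volume with
tissue ≈ 100 ± 3 and air ≈ 5 signal units. Same seed ⇒ bitwise-identical
volumes.

**Deformation.** The ADC outline is emulated by displacing reference-contour
vertices posteriorly (+y) by A·exp(−(θ−90°)²/2σ²), tapered across slices by
a Gaussian in slice index, or by uniform radial dilation. Because the
deformation acts on contours in continuous space, its expected RMS is
computable by an independent dense-resampling/interpolation helper
(`expected_distortion`), which the ray-casting metric must reproduce within
2% — rasterization effects are tested separately.

**Cohorts.** Supine proximal air ~ log-normal(μ = ln 1.96, σ = 1.4, capped
at 20 cm³), giving a ~2 cm³ median and ~a third of patients above 4 cm³;
prone air = supine × Beta(1.5, 3.5). Posterior distortion = patient baseline
(log-normal, median 3 mm, σ = 0.4) + 0.4 mm/cm³ of air above the 4 cm³ knee
+ N(0, 0.5 mm) per acquisition; the prone baseline is inflated by a factor
1.08, reflecting the mild geometric penalty of prone acquisitions, which is
what makes the whole-cohort paired test typically null while the high-air
subgroup shows a clear prone benefit. Likert scores arise from air volume
plus logistic noise (scale 1.5 cm³) against cutpoints (0.5, 1.5, 4, 8), so
P(score ≥ 4) = σ((air − 4)/1.5) exactly — the logistic threshold model is
well-specified with a true crossover at 4 cm³. The second rater moves ± 1
category with probability 0.4, landing quadratic-weighted AC2 near 0.93
(quadratic weighting is deliberately forgiving of one-step disagreement).
These defaults were chosen once to reproduce the study conditions'
qualitative structure and magnitudes and are not tuned per test.

**What the generator does not emulate:** B0 field physics and k-space EPI
simulation (the deformation is a geometric surrogate), fecal matter versus
gas ambiguity, inter-observer contouring variability on the imaging side,
non-ellipsoidal gland pathology, and any correlation between Likert scores
and image features other than air volume. Passing tests therefore show the
*pipeline* is correct and the statistics behave as designed under the
assumed data-generating process — not that the clinical effect sizes would
reproduce on real scanners.

## Problem sizes and numerical choices

Tests and the acceptance script run phantoms of ~11–13 contoured slices at
360 polygon vertices, 50-grid proximity oracles up to 14³ voxels, 50
simulated cohorts of n = 200 for threshold recovery and 20 default cohorts
of n = 52 for the subgroup significance pattern — sizes at which every
oracle comparison is exact or tightly bounded while the whole suite runs in
well under a minute per module. Ray casting uses a 1e−12 lower bound on the
ray parameter to ignore the origin itself, and centroids of zero-area
polygons are rejected as degenerate rather than returning NaN.

## Known limitations

* Slice pairing is by index after the through-plane translation; acquisitions
  with different slice grids must be resampled upstream.
* The farthest-intersection rule makes strongly non-convex (non-star-shaped)
  outlines give conservative radii; such rays are counted and reported but
  not excluded.
* The rigid registration estimates only in-plane rotation (prostate MRI
  slices are axial; through-plane rotation is negligible at 3 mm slices).
* `segment_air`'s automatic threshold assumes air occupies a small fraction
  of the volume; for fields of view dominated by air, pass an explicit
  threshold.
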