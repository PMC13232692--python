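# dwidistort

Quantitative analysis of echo-planar (EPI) geometric distortion of the
prostate on diffusion-weighted MRI, and of the rectal air that causes it.

## The problem

Prostate DWI/ADC maps are acquired with single-shot EPI, which warps
geometrically near air–tissue interfaces. Gas in the rectum sits directly
against the posterior prostate, so the posterior gland outline on the ADC map
can be displaced by several millimetres relative to its true shape, as
depicted by a geometrically faithful contrast-enhanced (DCE) reference.
Scanning the patient prone moves the gas away from the prostate; deciding
when that is worth the extra scan time requires measuring both the distortion
and the offending air. This package implements that measurement pipeline and
the paired supine/prone cohort statistics around it, for researchers studying
prostate MRI image quality:

1. **Volume masks from outlines** — per-slice closed contours (mm
   coordinates) are rasterized onto the voxel grid, and outlines are
   recovered from masks (`volumes.py`, `contours.py`).
2. **Co-registration** — the ADC mask is aligned to the reference mask by
   center-of-mass translation (optionally rigid) to remove bulk motion
   without cancelling the distortion itself (`registration.py`).
3. **Polar distortion metric** — on each paired slice, both outlines are
   sampled at 1° increments about the reference contour centroid, giving
   signed radial residuals Δr(θ) = r_ADC(θ) − r_ref(θ) in mm
   (`distortion.py`).
4. **RMS reduction** — residuals pool into a whole-gland RMS and a
   posterior-half RMS (θ ∈ [1°, 180°], +y = posterior), the
   *posterior distortion* `Distortion_post` in mm.
5. **Rectal air proximity** — air is segmented inside the rectum outline by
   an intensity threshold; `Rectal Air_prox` is the air volume (cm³) within
   20 mm of the prostate, via an anisotropic Euclidean distance transform
   (`air.py`).
6. **Cohort statistics** — median/IQR descriptives, paired Wilcoxon
   signed-rank tests, Fisher exact test on dichotomized 5-point Likert air
   scores (≥ 4 = appreciable air), quadratic-weighted Gwet's AC2 two-rater
   agreement, and the logistic-regression air threshold
   `V_thresh-air = −β₀/β₁` from P(appreciable) = σ(β₀ + β₁·air)
   (`stats.py`, `study.py`).

A seeded synthetic generator (`synthetic.py`) produces paired phantoms and
cohorts with this exact structure — including the knee-shaped air→distortion
response around 4 cm³ — so every stage is testable without patient data.

## Worked example

```python
from dwidistort import (CohortSpec, DistortionStudy, make_cohort)

cohort = make_cohort(CohortSpec(seed=21))
results = DistortionStudy(cohort.table, cohort.scores).fit()
print(results.summary())
```

prints

```
Paired supine/prone distortion study
======================================================
patients: 52    high-air subgroup (supine air > 4.16 cm3): 17
V_thresh-air = 4.16 cm3, slope p = 0.0015
------------------------------------------------------
whole cohort
  rectal_air_prox_cm3    supine   2.26 (0.74-6.33)  prone   0.61 (0.22-1.48)  p=3.61e-10
  distortion_post_mm     supine   3.52 (2.77-5.00)  prone   3.64 (2.85-4.57)  p=0.185
------------------------------------------------------
subgroup
  rectal_air_prox_cm3    supine   8.10 (6.44-16.25)  prone   1.80 (1.04-4.02)  p=1.53e-05
  distortion_post_mm     supine   5.81 (3.75-7.60)  prone   4.04 (2.59-4.71)  p=1.53e-05
Fisher exact, appreciable air supine vs prone: p = 0.0343
Gwet AC2 [rectal_air_prone]: 0.940 (almost perfect)
Gwet AC2 [rectal_air_supine]: 0.928 (almost perfect)
```

Reading: prone positioning drains rectal air near the prostate (2.26 →
0.61 cm³, p ≪ 0.001) but does not change posterior distortion across the
whole cohort (p = 0.19); in the subgroup whose supine air exceeds the fitted
`V_thresh-air` the posterior distortion falls significantly when prone
(5.81 → 4.04 mm, p < 0.001). The two simulated raters agree almost
perfectly on the air Likert scale.

The imaging half of the pipeline works the same way from files or phantoms:

```python
from dwidistort import (DeformationSpec, PhantomSpec, air_proximity_volume,
                        distort_contours, make_phantom, measure_distortion,
                        segment_air)

ph = make_phantom(PhantomSpec(air_volume_cm3=6.0, seed=1))
air = segment_air(ph.intensity, ph.rectum, "auto")
print(air_proximity_volume(air, ph.prostate, 20.0).proximal_cm3)  # 6.021
adc = distort_contours(ph.contours, DeformationSpec(amplitude_mm=3.0))
print(measure_distortion(ph.contours, adc).rms_posterior)         # 0.963...
```

There is also a CLI (`dwidistort distortion|air|cohort|synth --help`) over
the same functions.

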