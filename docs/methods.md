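# Methods

## Measurement model

Each located landmark coordinate (or each signed vertical distance) is
modelled as

```
y_ijk = m_j + B_i + e_ijk
```

for subject *j*, operator *i* and replicate (session) *k*, with a persistent
operator effect `B_i ~ N(0, s_L²)` shared across subjects and sessions, and
independent session noise `e_ijk ~ N(0, s_r²)`. This is the interlaboratory
precision model with operators as "laboratories" and subjects as "levels";
the assumption that the within-subject SD is common across subjects is what
licenses pooling a heterogeneous patient cohort into one record per
landmark/axis.

### Estimators

With cells indexed by (operator *i*, subject *j*) holding `n_ij` replicates:

* `s_r²` — within-cell variances pooled with weights `n_ij − 1`; cells with a
  single replicate are excluded from the pooling but still contribute their
  mean to the operator comparison.
* For every subject seen by `p_j ≥ 2` operators, `s_d,j²` is the sample
  variance of the operator cell means; `s_L² = max(0, mean_j(s_d,j²) −
  s_r²/n̄)` with `n̄` the mean replicate count over the cells entering those
  variances (on a balanced design, simply the number of sessions). The
  pre-truncation value is retained in the output (`s_L_sq_raw`) as a
  diagnostic; truncation at zero is standard and the only source of the
  (slight) upward bias in `s_R` when `s_L = 0`.
* `s_R² = s_r² + s_L²`.

On balanced data this reduces exactly to the one-way-per-subject ANOVA
mean-squares solution, which the test suite verifies against an
independently coded brute-force oracle to 1e-10. Estimation is
location-invariant per subject and invariant to relabelling of subjects,
operators and sessions.

A single operator in a stratum yields `s_L = 0` with a warning rather than
an error; a stratum whose every cell is a singleton is not estimable and is
dropped with a logged reason.

### Reported quantities

Confidence intervals are reported as the value `2·SD` (not an interval
pair), matching how such studies tabulate precision, and classified as
*acceptable* (≤ 1 mm), *useful* (1–2 mm) or *caution* (> 2 mm); both
boundaries are inclusive on the lower class and configurable.

### Cohort size

`sample_size(A, n, z)` returns `round(z² / (2·A²·(n−1)))`: the number of
subjects for which the relative uncertainty of an SD estimated from `n`
repetitions each is `A` at the `z`-level. Rounding is to the *nearest*
integer, not the ceiling: the quantity is itself a first-order
approximation, and at `A = 0.15, n = 6` (17.07) the practical answer is 17.

## Head reorientation

The subject frame is built from the 6-repetition mean Po-R, Po-L and Or-L
(after outlier removal): origin at mid-porion, x from Po-R to Po-L
(right→left), z along the FH-plane normal, y = z × x (front→back),
right-handed. The normal's sign is fixed by a `superior_hint` direction
(default scanner +z, the usual CT patient orientation); if the hint is
orthogonal to the normal the sign is chosen so that mean Menton — a point
unambiguously below FH — comes out inferior. The transform is rigid, so all
distances and angles are preserved; degenerate geometry (triangle area
≤ 1e-6 mm²) is an error rather than an arbitrary plane.

Two distinct plane constructions are used on purpose: the *mean* FH plane
(per subject, from mean landmarks) defines the reorientation frame for the
positional R&R analysis, while *session* planes (from that session's own
raw landmarks) are used for the vertical-measurement analysis, so that
plane-construction noise propagates into the vertical R&R exactly as it
would in practice.

## Vertical measurements and parallelism

The vertical measurement of a landmark is its *signed* orthogonal distance
to the session's reference plane (conventional FH = Or-L/Po-R/Po-L; novel
FH = Or-R/Or-L/mid-IAF). Signed rather than absolute distances are the
measurand: folding at zero would convert sign noise near the plane into
spurious bias. Each plane's three defining points have identically zero
distance, so e.g. Or-L has zero vertical variance under the conventional
plane by construction — this is a property of the measurand, not an
artefact.

Parallelism is assessed per subject from mean-landmark planes: the angle
between the mean conventional and mean novel planes (`arccos |n_a · n_b|`,
in [0°, 90°]), summarized over the cohort as mean ± SD of the absolute
angles, plus the signed vertical distances of every IAF repetition to the
mean conventional plane. Computing the angle from mean planes (rather than
averaging per-session angles) matches the reading of the cohort angle as a
property of each subject's anatomy rather than of session noise.

## Outlier screening

* **Gross rule** (primary, deterministic, removal): an observation farther
  than `gross_mm` (3D Euclidean) from the cross-operator median position of
  that landmark for that subject. The default is 5 mm: more than ten
  standard deviations above realistic landmarking noise (sub-millimetre),
  comfortably below genuine mislocalizations such as a wrong-end-of-foramen
  error (~8 mm), and robust because the median over six repetitions ignores
  a single-operator, single-session fault.
* **Grubbs test** (removal): two-sided, on operator cell means per
  subject/landmark/axis at α = 0.01; needs ≥ 3 operators, else skipped and
  logged. With exactly 3 operators the test statistic is bounded near its
  critical value, so it fires only on near-degenerate configurations — in
  practice it catches the session-averaged shadow of a gross error.
* **Mandel h / k** (advisory): interlaboratory consistency statistics at
  α = 0.01, reported but not removed by default.

Removed observations are flagged (`outlier_removed`, `missing`) and excluded
from every downstream statistic; every removal and skipped stratum is
logged.

## Synthetic data generator

The generator draws the exact model the analysis estimates. Per subject:
template skull + per-landmark anatomical offsets (SD `subject_sd`, default
4 mm — cohort-scale anatomical variation for a deformity population) + a
random rigid pose (rotations ≤ 10° per axis, translations ≤ 20 mm,
representing un-reoriented scanner acquisitions). Operator bias and session
noise are drawn **in the anatomical frame before the pose is applied**, so
per-axis variance components stated anatomically are the ones the
FH-reoriented analysis recovers; with isotropic noise the distinction
vanishes.

The template is synthetic: plausible adult craniofacial coordinates chosen
only to satisfy ordering constraints (FH plane near-horizontal, IAF medial
to porion, menton inferior to nasion, bilateral symmetry), not measured
from any subject.

Cant injection: when a cant is requested, the subject's true Or-R is
projected onto the conventional FH plane (orbitale points are near-coplanar
with FH by anatomical definition), the IAF pair is projected onto that
plane (zero-cant baseline) and rotated about the inter-orbital axis by the
drawn angle — making the dihedral angle between the novel and conventional
planes equal the drawn angle to machine precision. The realized per-subject
angles are returned with the truth, and they — not the nominal
distribution — are the recovery target.

The packaged `paperlike_scenario` emulates a 20-subject × 3-operator ×
2-session study: anisotropic noise for orbitale/porion (large along x),
gonion (y/z) and B point (z), sub-millimetre dental/foraminal noise
(baseline σ_r = 0.15 mm, σ_L = 0.10 mm), an 8 mm mental-foramen offset for
operator 3's first session on subjects 4–20, and per-subject cant
|N(0, 2.4°)|.

What the generator does **not** model: inter-axis error covariance per
landmark (axis-independent Gaussians only), voxel-size-dependent
localization error, heavy-tailed operator blunders other than the explicit
offset injections, and operator biases that drift over subjects (a
per-subject-varying bias would violate the persistent-laboratory-effect
assumption the estimator is built on). Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not that
real landmarking errors are Gaussian.

## Numerical choices

* Plane/frame degeneracy: triangle area ≤ 1e-6 mm² → error; unit-normal and
  orthonormality contracts enforced at 1e-12 / 1e-10.
* Zero-angle comparisons between near-parallel planes carry ~1e-7°
  floating-point noise (arccos near 1); tolerances that touch them use
  1e-6°, while rigid-invariance comparisons hold at 1e-9.
* Serialized coordinates use 17 significant digits (double round-trip
  exact).
* `s_L²` truncated at zero; pre-truncation value kept as a diagnostic.
* Grubbs/Mandel critical values: Grubbs via the t-quantile formula at
  α/(2N); Mandel h via the t-based ISO expression; Mandel k via the
  F-based expression with ν = n̄ − 1.

## Problem sizes

Default verification runs use 20 subjects × 3 operators × 2 sessions × 33
landmarks (3 960 observations) for end-to-end checks; variance-component
recovery uses 200 Monte-Carlo replicates of p = 3, q = 200, n = 2 per
(σ_r, σ_L) setting; the outlier false-alarm check uses 500 simulated clean
studies; cant recovery uses 10 cohorts of 20 subjects. These sizes give
Monte-Carlo standard errors several times smaller than the tolerances they
are tested against.

## Known limitations

* The estimator pools across subjects assuming a common within-subject SD;
  strongly heteroscedastic cohorts would call for per-subject reporting.
* With 3 operators, `s_L` (hence `s_R`) is intrinsically noisy; the
  recovery contract is 10% on the mean of `s_R` versus 5% for `s_r`.
* The XML dialect is a minimal stand-in schema, not the export format of
  any particular annotation software.
* Mandel statistics are advisory only; no iterative re-screening after
  removal is performed (a single screening pass precedes estimation).
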