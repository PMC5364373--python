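# Methods

## Overview

`hippomorph` implements surface-based hippocampal morphometry as four
stages — template construction, progressive template-to-mask fitting,
correspondence/deformation extraction, and vertex-wise regression with
FDR control — plus a synthetic cohort generator that provides planted
ground truth for every stage. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
test bed does and does not establish.

## Coordinate conventions

Binary masks are boolean 3-D grids with a NIfTI-style affine; voxel
*centers* map through the affine, and all distances are computed in
world millimetres so anisotropic voxels (default 1 × 1 × 1.3 mm) are
handled correctly. Meshes live in world mm as closed, outward-oriented
genus-0 triangulations.

## Signed distance and surface-to-mask distances

The signed field is EDT(background) − EDT(foreground) with anisotropic
sampling. Because the EDT measures center-to-center, this raw field has
slope ≈ 2 across the binary boundary and overestimates distances away
from it by about half a voxel. Two corrections are used:

* point-to-boundary distances divide by the sampled gradient magnitude
  clipped to [1, 2] (a Newton estimate of the distance to the zero
  level) and subtract an h/4 digitization-phase term away from the
  boundary, where h is the mean voxel dimension;
* sub-voxel surface edits (the planted deformations) and the
  planted-magnitude measurement instead use the distance to the
  Taubin-smoothed marching-cubes iso-surface, which resolves geometry
  the voxel-center EDT cannot.

Vertices outside the grid get the clamped-field value plus the
world-space excess, so far outliers measure correctly.

## Template construction

Masks are coregistered by center-of-mass translation (sub-voxel, linear
interpolation) — the pipeline assumes its inputs are grossly
co-oriented, which the generator guarantees and which standard
segmentation pipelines provide — then averaged into an occupancy atlas.
The 0.5 iso-surface is extracted by marching cubes, smoothed with 10
Taubin iterations (λ = 0.5, µ = 0.53; volume change < 2%), and remeshed
to exactly 4002 vertices, the vertex count of a frequency-20 geodesic
subdivision of the icosahedron and the fixed cardinality every
downstream stage relies on.

No installed remesher guarantees an exact vertex count, so remeshing is
constructive: split the longest edge while below target (one vertex,
two faces per split), collapse the shortest link-condition-safe edge
while above it, then 10 sweeps of uniform Laplacian relaxation with
re-projection onto a 60k-point sampling of the input surface
(collisions resolved to second-nearest samples). Splits and collapses
preserve the Euler characteristic; measured Hausdorff distance to the
input stays well under one voxel diagonal (1.94 mm) and enclosed volume
within 3%.

## Progressive fitting

Per iteration each vertex moves by `(1 − α)·external + α·internal`,
clipped to 0.5 mm:

* **external** — the nearest sign change of the signed distance field
  along the vertex normal, sampled at 21 points over ±5 mm with linear
  interpolation of the crossing; vertices whose rays miss a crossing
  fall back to a gradient-descent step on the field. The occupancy is
  pre-smoothed with a 0.5-voxel Gaussian (re-binarised) before the EDT:
  enough to suppress single-voxel staircase roughness, while a 1-voxel
  kernel was found to erode the thin tail of the structure and drag
  fitted vertices off the true boundary.
* **internal** — Laplacian-coordinate preservation over the current
  k-ring: the vertex is pulled toward (ring centroid + template rest
  differential), so the template's local point distribution resists
  distortion.

A stage ends when the maximum vertex step falls below 0.01 mm or after
200 iterations; the default ladder is α ∈ {0.9, 0.7, 0.5, 0.3, 0.1}
with ring levels {3, 3, 2, 2, 1}. The template is initialized by
centroid translation plus cube-root volume scaling (no initial rotation,
per the co-orientation assumption). After the last stage a single
similarity-invariant regularization pass runs: for every vertex a
least-squares rotation+scale+translation is estimated from its 2-ring
template→fitted correspondence (batched 3×3 SVDs) and the vertex moves
halfway (blend 0.5) to that transform's prediction. This is exact on
global similarity motions and suppresses isolated vertex outliers.
Whether such regularization belongs after every stage or once at the end
is an open design point; once-at-end is the default and is configurable.

Fits are accepted when the mean vertex-to-boundary distance is at most
half the largest voxel dimension (0.65 mm); failures re-run down a
ladder of two more flexible schedules (lower α floor, more iterations,
wider ray reach) and budget exhaustion is flagged, never raised.

## Correspondence and deformation

Fitted meshes are scaled isotropically about their centroids by
(ICV_ref / ICV_subject)^(1/3), rigidly Procrustes-aligned (Umeyama, no
reflection) to a reference subject, and averaged vertex-wise into the
sample-specific template. The deformation of subject s at vertex v is
computed in native space: the average template is mapped through the
inverse of s's alignment transform, and

    vector_v = x_subject,v − x_template,v
    scalar_v = vector_v · n̂_v        (outward positive)

with n̂ the area-weighted outward normal of the mapped template. The
signed scalar — not the 3-vector or its magnitude — is the regression
predictor: reported effects carry an inward/outward direction per
vertex, which implies a scalar; the full vector is retained in outputs
for diagnostics, and magnitude-based analysis remains possible from
those files.

## Statistics

Vertex-wise OLS uses Frisch–Waugh–Lovell residualization on the shared
covariate block (intercept, age in days, sex 0/1, vascular risk 0–8),
which is algebraically identical to per-vertex full OLS (verified to
1e-8 against a normal-equations oracle) and runs vectorized across all
4002 vertices in either direction (deformation as predictor or as
response; for simple regression the two directions share t and p
exactly). Standardized betas are b · SD(x)/SD(y) with unstandardized
covariates. Missing data are handled by listwise deletion with n
recorded in the map.

The FDR family is one map (4002 vertices of one side for one model),
BH step-up via statsmodels; the family choice is configurable but
per-map is the default convention. Significant vertices are grouped
into connected components on the template edge graph, split by beta
sign; the peak is the maximum |beta| (ties: smaller p, then lower id).
Clusters are descriptive — there is no cluster-mass permutation null.

The vascular risk aggregate is the sum of five self-reported binaries
(hypertension, diabetes, high cholesterol, cardiovascular disease,
previous stroke), smoking coded never/ex/current = 0/1/2, and an
imaging-infarct binary — range 0–8. Cognitive composites are first
unrotated principal components of correlation-matrix PCA, scores scaled
to SD 1, loadings sign-oriented so the first battery column loads
positively. Volume analysis reports Pearson correlations and
covariate-adjusted standardized betas, optionally after residualizing
hippocampal volume on total brain volume.

## The synthetic cohort

Each subject's hippocampus is a bent, tapered ellipsoid (long axis y,
default semiaxes 8 × 20 × 5 mm, bend 0.015 /mm, taper 0.35), mirrored
for the right side, digitized on a 64 × 64 × 48 grid at 1 × 1 × 1.3 mm.
A numeric calibration scale (cached fixed-point iteration on the voxel
count) pins the noise-free shape to the reference volume means:
3333.80 mm³ left, 3095.29 mm³ right. Between-subject variation is a
degree-2 real-spherical-harmonic radial perturbation (SD 3%) plus three
0.4 mm Gaussian surface bumps, and a global scale combining an ICV draw
(lognormal, mean 1.45 × 10⁶ mm³, log-SD 0.09), a hippocampus-specific
lognormal factor (log-SD 0.103, shared across sides) and a small
per-side residual (log-SD 0.03) — together reproducing a realistic
volume CV of ~14%.

Covariates: age ~ N(72.5 y, 0.71 y) in days, sex ~ Bernoulli(0.5),
vascular items at reference prevalences (the pooled "previous stroke,
history or imaging" rate is split roughly in half between the
self-report and imaging items). The planted effect is a localized
inward/outward displacement at a geodesic cap (center vertex 210,
radius 5 mm) of the canonical surface: per subject a magnitude
m ~ N(0, 1 mm) truncated at ±2 SD (a 1×1×1.3 mm grid cannot faithfully
carry larger local displacements) moves the cap region of the mask by
m × w, where w falls off with geodesic distance on the canonical
surface so that normal displacement does not change the weight the
displaced surface sees. Cap voxels are re-classified by majority vote
over a 2×2×2 sub-voxel sample against the displaced smoothed
iso-surface — binary boundaries lie exactly half a voxel from the
nearest centers, and center-only classification coherently swallows
sub-voxel displacements. The cognitive score is
β·z_m + covariate terms + noise with total variance ≈ 1 (z_m is the
truncated-normal-standardized magnitude), and a full subtest battery is
derived from the score and a general factor with loadings chosen so the
verbal-memory PCA reproduces realistic structure (loadings ~0.85–0.9,
~70–80% first-component variance).

What the generator does **not** emulate: anatomically faithful subfield
geometry, T1 intensities, segmentation errors beyond digitization,
scanner or rater effects, spatially correlated measurement noise, and
missing data. Passing tests therefore establish the correctness and
internal consistency of the chain under smooth, correspondence-friendly
variation — not segmentation robustness on real MRI.

## Evaluation runs and problem sizes

The standard quality benchmark is a 50-subject cohort (both sides, 100
fits) — enough for stable medians while keeping a full run in minutes on
one CPU. The generator-calibration check uses 100 masks; the planted-
effect recovery study runs 50 replicates of n = 200 at β = 0.3 on
simulated deformation matrices (background surface noise 0.2 mm,
matching the pipeline's measured fit-noise floor); detection means an
FDR-significant cluster whose peak lies in the planted vertex set, the
cluster-level localization the reporting is based on. Under these
conditions the analytic power is ≈ 0.7–0.8, not higher: detection
requires a replicate's realized z–score sample correlation (SE ≈ 0.065
at n = 200) to clear the BH cutoff (~0.24 with ~50 true vertices).

## Known limitations

* Mask coregistration is translation-only; cohorts with rotated
  acquisitions would need an upstream rigid pre-alignment.
* The fitting ladder assumes genus-0, single-component masks; cavities
  or touching structures are out of scope.
* The planted-deformation amplitude is limited by what a binary grid at
  this resolution can represent (~±2 mm); recovered magnitudes for
  sub-half-voxel plants are attenuated toward zero.
* Cluster inference is descriptive; only vertex-level FDR is
  controlled.
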