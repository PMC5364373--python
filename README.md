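# hippomorph

Vertex-wise statistical shape analysis of the hippocampus from binary
segmentation masks, built around a deformable template model (DTM): a
fixed-topology triangular mesh is non-rigidly fit to every subject's
mask, establishing point correspondence across a cohort, and the
per-vertex deformation from the sample-average surface becomes the unit
of analysis for regression against cognitive scores.

It is aimed at researchers who have hippocampal (or similar subcortical)
segmentations and subject-level phenotypes and want *local* shape effects
— the kind of spatially confined association that total-volume analysis
averages away — with honest multiple-comparison control and a fully
synthetic, ground-truthed test bed.

## The method

1. **Template construction.** Coregistered binary masks are averaged into
   a probabilistic atlas; marching cubes at occupancy 0.5, Taubin
   smoothing and exact-count remeshing produce a closed genus-0 template
   of exactly 4002 vertices per side.
2. **Progressive fitting.** For each subject the template deforms
   iteratively; every vertex moves by

   step = (1 − α) · external + α · internal

   where the external force pulls the vertex to the nearest mask-boundary
   crossing along its normal (signed-distance-field ray cast) and the
   internal force is a multi-ring Laplacian restoring term that preserves
   the template's local point distribution. The rigidity α and the
   neighborhood level decrease stage by stage (default α ∈ {0.9, 0.7,
   0.5, 0.3, 0.1}), so global shape is captured before local detail. A
   rotation/scale-invariant per-vertex regularization follows, and any
   fit whose mean surface distance exceeds half the largest voxel
   dimension (0.65 mm at 1×1×1.3 mm) is re-run down a ladder of more
   flexible schedules. Fit quality is reported as Dice overlap, mean
   vertex-to-boundary distance, and the maximum distance (fiducial
   localization error).
3. **Correspondence and deformation.** Fitted meshes are scaled by the
   cube root of the ICV ratio, Procrustes-aligned, and averaged into the
   sample-specific template; mapping that average back through each
   subject's inverse transform yields per-vertex deformation vectors and
   the signed outward-positive scalar d_v = (x_subject − x_template) · n̂.
4. **Statistics.** At every vertex, ordinary least squares relates d_v
   to a cognitive score (either direction) with age in days, sex, and an
   aggregate vascular-risk score (0–8) as covariates. Effects are
   standardized betas (b · SD(x)/SD(y)); p-values are Benjamini–Hochberg
   corrected across the 4002 vertices of a map, and significant vertices
   are grouped into sign-consistent connected clusters with peak
   statistics. Cognitive composites (verbal memory, g, g-speed,
   g-memory) are first unrotated principal components of the relevant
   test batteries; spatial span is a plain forward+backward sum.

Because real cohort data of this kind is not redistributable, the
package ships a first-class synthetic cohort generator: bent, tapered
ellipsoid masks calibrated to reference hippocampal volumes
(left 3333.80 mm³, right 3095.29 mm³) with smooth per-subject shape
variability, ICV-coupled scale, a localized planted deformation at a
known vertex cap, and phenotypes wired to that deformation at a chosen
standardized effect size.

## Worked example

```python
from hippomorph import (make_cohort, build_template, quality_gate_refit,
                        align_cohort, average_mesh, compute_deformation,
                        vertexwise_regression, significant_clusters)
import numpy as np

cohort = make_cohort(20, seed=1)                   # masks + phenotypes + truth
masks = [s["left"] for s in cohort.masks]
template = build_template(masks)                   # 4002-vertex template
fits, reports = zip(*(quality_gate_refit(template, m) for m in masks))
print(np.median([r.dice for r in reports]),
      np.median([r.mean_distance for r in reports]))
```

```
0.9980276492139282 0.01626677064426684
```

A median Dice of 0.998 means the voxelized fitted surfaces reproduce the
input masks almost exactly; the median mean vertex-to-boundary distance
of 0.016 mm is far inside the half-voxel acceptance gate. Continuing,

```python
aligned, tfs = align_cohort(list(fits), cohort.phenotypes.icv_mm3.tolist())
avg = average_mesh(aligned)
d = np.vstack([compute_deformation(avg, f, tf).signed_normal
               for f, tf in zip(fits, tfs)])
stats = vertexwise_regression(
    d, cohort.phenotypes.planted_score.to_numpy(),
    cohort.phenotypes[["age_days", "sex", "vascular_risk_score"]].to_numpy())
clusters = significant_clusters(stats, avg, q_threshold=0.05)
```

gives the per-vertex standardized betas, BH q-values and (at adequate
sample size) the planted cap back as a significant outward cluster.

The same chain is available as numbered drivers (`analysis/01…05`) and a
CLI (`hippomorph run --n-subjects 50 --seed 1 --out scratch/run`); each
stage writes its artifacts plus a manifest with checksums and the full
config snapshot.

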