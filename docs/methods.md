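# Methods

`fetalatlas` builds an age-continuous (3D + gestational age) brain template
from a cohort of volumetric images and uses it for multi-atlas
segmentation.  This note records the model, the numerical choices, and what
the synthetic phantoms do and do not establish.

## Spatiotemporal atlas model

Given images $I_i$ with gestational ages $t_i$ (weeks), the atlas at age
$t$ is a template $\hat I(\cdot,t)$ and transformations $h_i$ minimizing
the kernel-weighted sum of registration energies

$$\frac{1}{\sum_i K(t-t_i)}\sum_i K(t-t_i)\,\big[E(I(t), I_i, h_i) + \lVert L v_i\rVert^2\big],$$

where $K$ is a Gaussian kernel in age ($\sigma = 1$ week; raw weights are
1 at zero age distance, subjects at or below the 0.01 cutoff are dropped —
an effective support of about $\pm 3$ weeks — and the survivors are
normalized to sum to one), $E$ is the negative local
cross-correlation similarity, and each $h_i$ is the unit-time flow of a
velocity field $v_i$.  The estimate is iterated:

1. symmetric diffeomorphic registration of the current template to every
   retained subject, giving stationary velocities $v_i$;
2. kernel-weighted averaging $\bar v = \sum_i w_i v_i$ (velocities — not
   displacements — are averaged, because averages of stationary velocities
   exponentiate to diffeomorphisms);
3. template update: every subject is pulled back through its transform
   composed with $\exp(-\bar v)$, and the kernel-weighted voxelwise mean is
   taken.  Composing the unbias warp into each subject's map means each
   subject is interpolated exactly once per rebuild.  The final rebuild
   after convergence uses cubic interpolation, which preserves the
   sharpness that repeated linear resampling erodes.

**Convergence** is declared when the mean transform stops changing: the
residual is the mean magnitude (in voxels, over the template foreground) of
the change in $\bar v$ between consecutive outer iterations (for the first
iteration, the change from identity), with tolerance 0.05 voxel and at
most 10 iterations by default.  The distance of $\bar v$ itself from
identity is *not* a usable stopping rule under noise: individual
registrations carry a noise-driven error floor of roughly 0.2 voxel whose
kernel-weighted mean levels off near 0.1 voxel, at which point the
template is stationary.  Unbiasedness is instead a property of the final
transforms: the kernel-weighted mean of the stored template-to-subject
displacement fields is within 0.1 voxel of identity, because the unbias
correction is folded into each stored field.

**Template labels** are fused by kernel-weighted averaging of the
subjects' propagated label probabilities — the label-space analog of the
intensity average that defines the template.  Structure volumes of a
labeled timepoint are reported as *probabilistic* volumes (the integral of
each fused probability map); hard argmax counts systematically shrink
structures only a few voxels across, because their boundary probability
falls below that of the surrounding tissue.

## Registration

The deformable registration is a symmetric, log-domain, fluid-type scheme
with a local normalized cross-correlation (LNCC) metric (5-voxel windows):

* Both images are deformed toward their midpoint by two half-velocities.
  Per iteration the LNCC gradient on each side is smoothed with the fluid
  regularizer (σ = 2 voxels), scaled, accumulated, and the accumulated
  half-velocity smoothed with the elastic regularizer (σ = 0.05 voxels).
  The pair of Gaussian regularizers is the practical surrogate for a
  Sobolev penalty on the velocity.
* The full fixed-to-moving velocity is the difference of the
  half-velocities (first-order Baker–Campbell–Hausdorff), so the forward
  and inverse maps are exact exponentials of one stationary field —
  inverse-consistent by construction and averageable across subjects.
* Exponentiation is scaling-and-squaring; 4 squarings resolve the short
  flows these cohorts produce (sub-voxel to a few voxels).
* Multiresolution pyramid 4×/2×/1× with an iteration ceiling of
  100/100/20 per level and a gradient step of 0.05 voxel; a level stops
  early when the best cost stops improving (relative change < 1e-4 over 3
  iterations).

Numerical safeguards that matter in practice:

* **Foreground mask.** The metric is restricted to the union of the two
  images' tissue support (10 % of the robust intensity maximum, dilated by
  2 voxels).  An "any nonzero voxel" mask silently becomes the whole
  volume once additive noise is present.
* **Variance floor.** LNCC windows whose local variance is below four
  times the background-noise variance (estimated from near-zero-intensity
  voxels) are treated as signal-free: they contribute neither cost nor
  force.  Without this, noise-only windows inject spatially correlated
  junk velocities that stall the atlas loop.
* **Force normalization.** Update fields are scaled so the 98th percentile
  of active force magnitudes maps to a full step, with per-voxel capping —
  normalizing by the global maximum lets a single outlier voxel freeze the
  update everywhere else.
* **Metric-side smoothing.** The finest-level images are smoothed by 0.7
  voxel for metric and force computation only (coarser levels are already
  smoothed by decimation).  This damps noise-driven forces; transforms are
  still applied to the original images.
* A Jacobian-determinant check after each level halves the gradient step
  if the accumulated transform folds (it does not in the test suite).

Rigid pre-alignment is first-order moment (centroid) matching, optionally
refined by multiresolution Mattes mutual-information registration (32
bins, dense sampling, so the result is deterministic), which SimpleITK
provides.

## Label fusion and segmentation

Candidate segmentations (probabilistic "raters") are fused with a
locally-adaptive probabilistic STAPLE: each rater has a confusion matrix
θ[true, observed] per 4³-voxel block (small enough that structures a
couple of voxels thick dominate their own blocks), rater probability
vectors are treated
as fractional label counts (closed-form EM updates, monotone objective),
and a Dirichlet pseudocount of 0.01 per cell regularizes the blocks.  The
recorded history is the penalized log-likelihood EM ascends.  The spatial
prior defaults to the voxelwise mean of the rater maps.  EM is a local
optimizer and tiny single-block problems are genuinely multimodal, so in
global mode on problems of ≤ 512 voxels a deterministic multi-start is run
(prior-seeded plus one start trusting each rater) and the best converged
objective wins.  A single rater is returned unchanged (its reliability is
unidentifiable).  Ties in the final argmax go to the lowest label id.

Multi-atlas segmentation registers each atlas to the query, propagates the
atlas labels (one-hot channels, linear interpolation, renormalization) and
fuses.  The two-pass bootstrapping strategy first segments every subject
from its three age-nearest atlas timepoints, then re-segments it using the
pass-1 segmentations of all subjects within one week of its age as
individual-subject atlases *in addition to* the same atlas timepoints
(using the peers alone is measurably worse).

A known limitation, demonstrated by the phantom experiments: because the
peer atlases carry *automatic* pass-1 labels, their errors are correlated
with the pass-1 consensus, which violates the rater-independence
assumption of STAPLE; on phantoms the second pass lands about one point of
mean DSC below the first, with the loss concentrated in structures a few
voxels across.  Extra atlases help when their labels are independent of
the first pass (e.g. manually delineated individual atlases); they do not
add information when they are recycled outputs of the same fusion.

Intensity clustering (k-component 1-D Gaussian
mixture, quantile-initialized, components sorted by mean; default k = 10)
and partial-volume correction (two-component Gaussian mixture over
intensities within one voxel of a tissue-pair boundary, voxels reassigned
to the more probable tissue) complete the segmentation toolbox.

## Growth phantoms

The synthetic cohorts emulate reconstructed fetal brain MRI at 1 mm
isotropic resolution over 19–39 weeks: a white-matter sphere (radius
14 mm at the 30-week reference age, +0.20 mm/week), a cortical
ribbon whose folding amplitude grows with age, two CSF-bright ventricles,
two deep nuclei, and a two-voxel-thin commissure bar — all analytic, so
structure volumes have closed forms.  T2-like intensities put CSF
brightest (mean 1000), which anchors the intensity normalization (the
99th percentile of positive voxels maps to 1000).  Subjects are the
canonical anatomy warped by a random diffeomorphism — a Gaussian-smoothed
(8 mm) white-noise velocity, windowed to the anatomy (variability deforms
tissue, not air), RMS-normalized to 1.0 mm, and exponentiated — with
additive Gaussian noise (σ = 20, i.e. 2 % of the CSF level) and an
optional linear bias field.  Per-subject seeds derive from the cohort seed
by an affine integer hash, so cohorts are bit-reproducible.

What the phantoms do *not* model: MR physics (bias beyond a linear ramp,
Rician noise, partial k-space artifacts), motion and slice-acquisition
effects, real cortical folding geometry, and tissue-contrast changes with
age.  Passing tests therefore establish the correctness and internal
consistency of the algorithms — convergence, unbiasedness, invertibility,
volume recovery, fusion behavior — not clinical segmentation accuracy.

## Problem sizes and defaults

The reference experiments use cohorts of 8–12 phantoms on 48³ grids
(atlas construction, registration checks) and 6 phantoms on 36³ grids at
the native 1 mm spacing — a cropped field of view rather than a coarser
one, so the commissure keeps its two-voxel thickness (the two-pass
bootstrapping run); the demo pipeline
(`fetalatlas run`) simulates 12 subjects at 32³/1.4 mm, builds three
timepoints (27/30/33 weeks), segments three subjects and evaluates them.
These sizes were chosen so a complete run of every experiment finishes on
a single CPU core in well under an hour while every structure, including
the two-voxel commissure, remains resolvable.
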