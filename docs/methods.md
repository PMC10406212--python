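# Methods

## Problem and approach

Cerebral microbleeds are small (typically < 10 mm) perivascular
hemosiderin deposits that appear as round, well-demarcated hypointense
foci on T2*-weighted MRI.  They are a marker of cerebral small-vessel
disease; counting and localizing them by hand is slow and subject to
rater variability, and most automated detectors trade patch-level
accuracy for large numbers of voxel-wise false positives.

`patchbleed` implements an automated segmentation pipeline that works
from routine, standardizable contrasts (T1w, T2w, T2*) rather than
susceptibility-weighted imaging:

1.  **Patch classification.**  Voxel-wise segmentation is cast as
    binary classification of 2D axial multi-contrast patches by their
    center voxel.  Patches combine the T2*, T2w and T1w windows as the
    three channels of one image, resized to the 224x224x3 input
    contract of standard image backbones.
2.  **Two-stage transfer learning.**  Manually labeled microbleeds are
    scarce, so the network is first trained on a proxy task for which
    labels are abundant — CSF vs. brain-tissue classification from the
    same contrasts (all layers trainable) — and then fine-tuned on
    microbleed vs. tissue with the first N weighted layers frozen.
    Optimization is SGD with momentum 0.9 on cross-entropy for a fixed
    10 epochs, no early stopping.
3.  **Voxel-wise reconstruction.**  The classifier is applied at every
    voxel of a search mask (stride 1, zero-padded borders), and
    positive voxels are reconstructed into 3D connected components
    (26-connectivity by default).
4.  **False-positive pruning.**  Each candidate lesion is dilated by
    two voxels; the dilated ring minus the lesion (its *shell*) is the
    local intensity reference.  Border voxels that are not sufficiently
    darker than the shell are removed iteratively to a fixed point;
    lesions with maximum diameter above 10 mm are discarded (large
    hemorrhages, elongated vessels); survivors are categorized into
    cortical GM, deep GM, WM, cerebellar GM or cerebellar WM by
    majority overlap with the (WMH-corrected) tissue labels.
5.  **Evaluation.**  Patch-level accuracy/sensitivity/specificity from
    confusion counts, and per-lesion sensitivity / precision / Dice
    with any-overlap detection: a manual lesion counts as detected if
    any of its voxels overlaps any automatic lesion.  Lesion-level
    specificity is undefined (there is no true-negative lesion count),
    so precision is reported instead.

## The intensity-ratio pruning rule

The rule as commonly printed — "remove a border voxel when
microbleed-intensity / shell-intensity is below a threshold" — is
inconsistent with thresholds of 1.2–1.4: true microbleeds are
hypointense, their ratio is below 1, and the literal rule would delete
every true lesion.  The package implements the consistent reading:

    keep a border voxel  iff  mean(shell T2*) / voxel T2*  >=  threshold,

i.e. only voxels darker than their surround by the threshold factor
survive.  Larger thresholds prune more (retained sets are nested), the
iteration terminates in at most |lesion| passes, and pruning is
idempotent.  A `literal_ratio=True` switch restores the printed formula
for auditing.  When per-region thresholds are used (e.g. 1.4 in deep
GM, whose boundaries are intrinsically darker, 1.2 elsewhere), the
region is determined *before* pruning.

Other conventions: "border voxel" means a lesion voxel with at least
one non-lesion 26-neighbor; the shell statistic is the arithmetic mean
of T2* over the shell, excluding voxels outside the brain mask; the
lesion diameter is the maximum pairwise voxel-center distance plus one
voxel extent, where the extent is the voxel cuboid's projection onto
the farthest-pair direction (so in-plane lesions on an anisotropic grid
are not inflated by the slice thickness); single-voxel lesions have
diameter max(spacing), hence nonzero, and the 10 mm cutoff is
inclusive.

## Backbone and freezing semantics

The default backbone is a compact CNN — four conv(3x3)–batch-norm–leaky-
ReLU blocks (8/16/32/32 channels, 2x2 max pooling between), a flatten,
a 32-unit dense layer and a 2-neuron softmax head — with a native input
of 28x28x3.  It honors the 224x224x3 input contract by resampling.
Three choices matter and were made deliberately:

* **Flatten, not global pooling.**  The label of a patch is defined by
  its *center* voxel; global average pooling destroys the positional
  information that both tasks depend on, and empirically prevents the
  CSF-pretrained features from transferring.
* **Batch normalization.**  Normalized activations keep the backbone
  well-conditioned across the task switch; without it, fine-tuning
  from the CSF minimum crawls for several epochs while a fresh random
  initialization converges quickly.
* **Leaky rectifiers (slope 0.1).**  Microbleeds are *hypointense*;
  strictly one-sided rectifiers trained on a bright-target task can
  silence the dark-contrast direction entirely.

"Layer" for freezing counts the ordered convolution/dense layers (6 in
the compact backbone).  Batch-norm scale/shift and running statistics
are not freeze units and keep adapting, as is standard fine-tuning
practice; frozen conv/dense parameters are bit-identical before and
after fine-tuning.  The published freezing grid {0, 5, 10, 15, 20}
refers to a ~50-layer residual backbone where 5 frozen layers are a
small fraction of the network; the phantom benchmark maps that
proportion onto the compact backbone by freezing its first 2 of 6
layers.  A `resnet50` backbone id is reserved for externally supplied
deep backbones; bundling one (or its pretrained weights) is out of
scope, and requesting it raises a clear error.

When fine-tuning starts, the decision head is re-initialized randomly
for the new task (configurable).  The CSF head enters the microbleed
task confidently polarized the wrong way — CSF is bright where
microbleeds are dark — which saturates the softmax and stalls the first
epochs if kept.

Training defaults follow the protocol's best combination: patch size
28, mini-batch 40, learning rate 0.006, momentum 0.9, 10 epochs,
`freeze_layers=5` in `TrainingConfig` (the published grid's optimum).
The published statement that rates above 0.004 degraded accuracy
coexists with a best combination at 0.006; the defaults follow the
explicitly stated best combination.

## Synthetic phantoms

Real cohort data are restricted, so every stage is validated on
phantoms that emulate the *statistical structure* of the study data,
not MR physics:

* **Geometry.**  96x96x32 voxels at 1x1x3 mm (the anisotropy of the
  T2* acquisitions): an ellipsoidal brain with a peripheral CSF rim, a
  cortical GM ribbon, central deep-GM nuclei, two ventricles, WM
  interior, and a posterior-inferior cerebellar compartment with its
  own GM/WM labels.
* **Contrast polarity.**  Mean intensities per (tissue, modality) put
  CSF hyperintense on T2w/T2* and dark on T1w; GM/WM contrast is
  realistic in sign on all three contrasts.  Values live on the
  [0, 100] standardized scale.
* **Microbleeds.**  Approximately spherical lesions rasterized in
  mm-space (nearest-k voxels to a center), placed in GM or WM without
  overlap, in three size classes — small 1–4, medium 5–15, large >15
  voxels — with T2* intensity far below tissue (shell-to-lesion ratio
  well above the default pruning threshold of 1.2, so true lesions
  survive pruning by construction).
* **Vessel confounders.**  In-plane cylinders (radius 1 voxel, length
  12–16 mm) hugging the cortical ribbon, as dark as microbleeds on
  T2*.  They keep a wide berth from the lesions (several voxels beyond
  the 2-voxel pruning shell) so that even partial-volume detection
  halos cannot bridge a lesion to a vessel — false positives stay
  unambiguous in tests.  Being longer than 10 mm, the size cutoff
  removes them, the same mechanism that excludes large hemorrhages.
* **Partial volume.**  A 0.5 mm Gaussian blur mixes thin CSF and small
  lesions with their surroundings before Gaussian noise (sd 3) is
  added.  This matters: without it, both classification tasks collapse
  to single-voxel thresholding, which no network needs context (or
  transferred features) to solve.
* **Determinism.**  A params+seed pair reproduces a case bit for bit;
  cohort generation derives per-subject seeds from one master seed.

What the phantoms do *not* model: susceptibility artifacts, bias
fields, motion, real sulcal geometry, WMH prevalence (only an optional
blob mask for testing the label-correction rule), or calcifications.
Passing the phantom benchmark therefore demonstrates that the pipeline
machinery — sampling, two-stage training, reconstruction, pruning,
metrics — is correct and that the method recovers lesions under the
stated contrast structure; it does not certify performance on clinical
data.

## Benchmark experiment (desk scale)

`patchbleed.experiments.run_phantom_benchmark` runs the whole pipeline
on a 12-subject cohort with a stratified 60/20/20 participant-level
split: 3,000 CSF patches (all layers trainable, 10 epochs), then 400
base microbleed patches augmented with 4 full-slice rotations per
positive and rebalanced (2,000 patches total), fine-tuned with the
first 2 layers frozen.  Validation/test sets are never augmented.
Held-out (test-split) subjects are segmented at stride 1 over the
restricted search mask (brain minus CSF minus the top 1% brightest T2*
voxels — none of which can contain a microbleed), and evaluated per
lesion before and after post-processing at threshold 1.2; the phantom's
vessel masks are injected into the raw segmentation so the
false-positive pruning stage is exercised deterministically.

The transfer benefit is measured with paired runs, averaged over 5
repeats as the protocol prescribes for its training experiments: the
two-stage model versus the identical fine-tuning protocol (same
freezing, data, seed) started from random weights.  The comparison
reports mean validation-accuracy curves and the first epoch at which
the averaged curve reaches 0.99 — a target chosen between the published
plateau of from-scratch training (at most 0.96) and that of the
transfer-learned models (at least 0.99).

Problem sizes (cohort of 12, thousands of patches rather than the
published 400,000/11,570, a compact backbone rather than a 50-layer
residual network) were chosen so a complete run takes minutes on one
CPU core; they are stated here so results are read at that scale.

## Numerical and degenerate-input conventions

* Intensity standardization maps the in-mask min/max linearly to
  [0, 100]; it is strictly monotone and idempotent; constant images are
  rejected explicitly.  An optional percentile-clipping variant exists
  for outlier robustness (off by default).  Standardization is computed
  over the brain mask (the whole-field alternative would let background
  air dominate the range).
* Metrics with zero denominators are reported as NaN with a warning,
  never silently as 0; two empty lesion maps score as perfect trivial
  agreement (1.0).
* Two-class decisions threshold the positive-class probability at 0.5,
  which coincides with argmax.
* Component labeling orders ids lexicographically by minimum voxel
  coordinate, so maps are reproducible across runs.
* Rotation augmentation rotates the full axial slice about the positive
  voxel (bilinear, zero fill) before patch extraction, so corners
  contain novel content; angle 0 reproduces the original patch exactly.
  Validation and test sets are never augmented.
* Patch centers for even patch sizes sit at in-patch index
  `patch_size // 2`; the published patch sizes (14, 28, 52, 56, 70) are
  interpreted as side lengths in voxels, which at ~1 mm in-plane
  spacing is numerically the same as the printed mm reading.
* Subject-level splitting uses largest-remainder allocation, exact for
  unstratified splits; stratification (by the subject's largest-lesion
  size class) allocates per stratum and is approximately proportional.
* Pruning guards: voxels with non-positive standardized intensity are
  treated as infinitely dark (kept); a lesion whose shell is empty
  (fills the grid) is an error.

## Known limitations

* The transfer-benefit comparison is implemented faithfully (paired
  runs, pre-training ablated, curves averaged over repeats), but
  whether CSF pretraining accelerates fine-tuning on *phantom* data is
  an empirical question the benchmark answers at run time.  Two
  structural reasons temper expectations: CSF is hyperintense where
  microbleeds are hypointense, so the source decision itself points the
  wrong way; and on piecewise-smooth phantoms a freshly initialized
  compact network is already a strong starting point, leaving little
  room for pretrained features to help.  The published effect was
  observed on a deep backbone with natural-image pretraining and on
  clinical images, where the pretraining stage additionally adapts
  generic features to MRI statistics.
* When pruning disconnects a candidate component (e.g. two lesions
  bridged by weak-contrast voxels), the remnants are re-labeled and
  size-filtered separately; all remnants inherit the parent component's
  region (which was determined before pruning).
* The 10 mm diameter cutoff is applied in the automated pipeline
  (configurable); whether to treat it as a manual-protocol-only rule is
  a user decision.
* Only axial 2D patches are supported; 3D patches and other planes are
  out of scope.
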