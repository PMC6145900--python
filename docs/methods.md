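# Methods

## Problem

Pathologic nodal metastasis (NM) and extranodal extension (ENE) drive
treatment selection in head and neck squamous cell carcinoma, but both are
ordinarily confirmed only after surgery.  `nodenet3d` implements a complete
pretreatment classification pipeline that predicts, per segmented cervical
lymph node on contrast CT, the multi-label pair (NM, ENE) — together with the
two standard baselines such a model must be compared against (a radiomics
random forest and a clinical-covariate logistic regression) and the shared
evaluation layer (ROC/AUC with DeLong intervals, Youden operating points,
calibration).  Because clinical CT cohorts with node-by-node pathologic
correlation are not publicly distributable, the package ships a synthetic
phantom generator that reproduces the class-conditional geometry and texture
statistics of such a cohort, so every stage is exercised end to end with
known ground truth.

## ROI preprocessing

Each node's manual segmentation is processed as:

1. **Convex hull** of the foreground voxel centers (3D by default; an
   option computes per-slice 2D hulls instead).  Membership is defined at
   voxel centers; degenerate point clouds (points on a line or plane) are
   handled by hulls in the spanned subspace.
2. **Dilation** by a discrete Euclidean ball (default radius 10 voxels),
   computed exactly via the distance transform of the background.  The
   dilation deliberately captures perinodal fat, where ENE expresses itself
   radiologically (fat stranding, loss of margin definition).
3. **In-plane resampling** to a common pixel spacing (default 0.75 mm),
   bicubic for intensities, bilinear + 0.5 threshold for the mask.  The
   slice axis is left at its native spacing by default; a spec flag enables
   z-resampling.
4. **Masked extraction**: voxelwise product, so background is exactly zero.
5. **Clipping** to the soft-tissue window [-400, +400] HU and per-ROI
   standardisation to zero mean / unit variance over in-mask voxels.  The
   normalisation scope is per-ROI because a reusable tool cannot assume
   access to cohort-level statistics; a constant ROI (zero variance) is
   flagged degenerate and its geometry (the binary mask) is used instead.
6. **Two inputs**: the *dimension-preserving* input embeds the ROI centered
   (floor of the half-margin on each side) in a fixed zero box — default
   118 x 118 x 32 voxels, the smallest box that holds the largest dilated
   node at full resolution — so absolute size remains encoded; the
   *size-invariant* input crops to the tight ROI extent and resizes each
   axis to a fixed cube (default 32^3; bicubic in-plane, linear along z),
   discarding size but preserving shape and texture.

The **short-axis ROI diameter** used as a clinical covariate is the minimum
over axes of the maximal foreground extent times spacing, measured on the
dilated, resampled mask.  It therefore runs systematically ~2 x dilation
radius larger than a radiologist's short-axis measurement; comparisons
between nodes are unaffected.  This choice (dilated rather than raw mask) is
deliberate and documented so it can be flipped.

## Network

Three 3D convolutional architectures share one engine:

* **BoxNet** — the dimension-preserving input through VGG-style blocks
  (convolution → batch norm → leaky ReLU → max pool) with strictly
  increasing filter counts, then dense layers.
* **SmallNet** — the size-invariant input through the same block type, ended
  by a 1x1x1 bottleneck convolution and a 1x1x1 network-in-network
  convolution before the head, limiting parameters.
* **DualNet** — both branches' penultimate dense representations
  concatenated into shared dense layers.  The binary HPV/p16 covariate can
  optionally be concatenated at the first shared dense layer.

The head is always two independent sigmoid units, because (NM, ENE) is a
multi-label target — ENE implies NM but the two are scored separately, and
the invalid state (0, 1) is excluded at the data layer, not by the model.
Activations are leaky ReLU with negative slope alpha = 0.03.  Weights are
He-initialised (variance 2/fan_in), biases zero.  Regularisation: dropout
(0.2 after conv blocks, 0.5 on dense layers), L2 penalty `l2 * sum(w^2)`
(default 1e-4) on convolution and dense weights only, and batch
normalisation with running statistics for inference.

Exact filter counts are configuration (`ModelSpec`), not code.  The
full-resolution default is BoxNet 32→64→128→256 (kernel 3^3, pool 2x2x2
with one z-pool skipped to respect the thin slice axis — the pooling
schedule along z is an open choice, flagged in config), dense 512/256;
SmallNet 32→64→128 plus bottleneck 64 and NiN 128.  The `desk` scale —
every routinely-tested configuration — divides filters by 4, takes
32 x 32 x 16 box and 16^3 small inputs, and prepends an input max-pool to
each branch ((2,2,1) box, (2,2,2) small) to trade spatial resolution for
CPU speed.

The engine itself (`nn.py`) is a compact numpy implementation with explicit
forward/backward passes — im2col convolution, floor-mode max pooling, batch
norm, inverted dropout — and Adam (β₁ = 0.9, β₂ = 0.999).  Activations and
parameters are float32 by default (`nn.DTYPE`); the gradient-check test runs
the engine in float64.  Every random stream is a seeded
`numpy.random.Generator`, so training histories are bit-reproducible.

## Splitting, oversampling, augmentation

Splits are node-level and stratified by class.  Counts use largest-remainder
apportionment with house size `ceil(n * fraction)`: 20% of a
380/153/120 cohort gives a test partition of 131 (76/31/24), and 20% of the
522 remaining gives validation 105 (61/25/19) and training 417 (243/97/77).
The ceil house size is the unique simple completion of largest-remainder
that reproduces both 131 and 105 at once.  Counts are deterministic; only
membership depends on the seed.

ENE samples in the training and validation partitions are oversampled x2 in
parallel (with replacement, seeded); the test partition is never oversampled
or augmented, which the pipeline asserts.  Training augmentation keeps the
original and adds: two axis flips and two in-plane rotations for every
sample, one extra rotation for metastatic samples, one extra flip-rotation
for ENE samples — totals 5/6/7 copies per negative/NM/ENE sample, which with
the oversampled 243/97/154 training partition gives exactly 2875 samples.
Rotation angles are uniform on ±30° (a design choice — small angles keep the
node inside the box), resampled bicubically with zero fill; oversampled
duplicates draw independent angles.

## Training schedule

Adam at initial LR 0.001, mini-batches of 20, up to 100 epochs (25 at desk
scale).  After each epoch the validation loss (binary cross-entropy summed
over the two endpoints, plus the L2 penalty) is computed on the oversampled
validation partition; any strict decrease (no minimum delta) checkpoints the
weights.  Five consecutive non-improving epochs halve the LR; twenty stop
training; both counters reset on improvement and the LR counter also resets
after a decay.  The returned model is the best checkpoint, and restoring it
reproduces the recorded best validation loss to float precision.  Five-fold
cross-validation (largest-remainder stratified folds; oversampling and
augmentation applied per-fold to the training side only) reports per-fold
and mean AUCs.

## Baselines

**Radiomics + random forest.**  ~30 standard features per node from the
resampled ROI: shape (voxel volume, mesh surface area from marching cubes on
a Gaussian-smoothed mask — smoothing suppresses the voxel staircase that
otherwise inflates surface area; sphericity uses the mesh-enclosed volume so
numerator and denominator describe the same surface; maximum 3D diameter,
per-axis extents, elongation and flatness from the coordinate covariance
eigenvalues), first-order intensity statistics (moments, energy, entropy,
percentiles, robust MAD), and GLCM texture on 32 fixed-width bins, distance
1, the 13 unique 3D directions, symmetric counts, features averaged over
directions with at least one pair (contrast, correlation, joint energy,
joint entropy, homogeneity, dissimilarity, cluster shade, cluster
prominence).  Features are scaled to unit variance with cohort-level scale
factors estimated on the fitting partition and reused on test.  The
classifier is a Gini random forest, bootstrap per tree, with *no* per-split
feature subsampling (every feature is a candidate at every split), fit on
the combined training+validation partitions — the deliberately literal
configuration for a ~100-feature problem.  Tree count defaults to 10,000 at
full scale and 300 at desk scale (forest performance is flat well below
that, which a test verifies).

**Clinical logistic benchmark.**  Covariates: ROI short-axis diameter,
HPV/p16 (unknown coded negative), primary site, clinical T and N stage.
Each covariate is screened univariably (likelihood-ratio test for
multi-level categoricals) and enters the multivariable model if P < 0.10.
The HPV x diameter interaction is always tested (Wald) and retained when
P < 0.05.  Coefficient intervals come from 100 bootstrap refits
(percentile).  The ENE model is fit only to nodes with diameter >= 10 mm.
Perfect separation falls back to a lightly L2-penalised fit, flagged in the
result.  The screening/interaction/bootstrap orchestration is bespoke; the
individual fits delegate to statsmodels' maximum-likelihood logit.

## Evaluation

AUC is computed as the Mann-Whitney statistic via midranks; its 95% interval
uses DeLong placement-value variance with a normal approximation, clipped to
[0, 1] (perfect separation yields a degenerate variance and a clipped
interval with a warning).  The operating threshold maximises the Youden
index over observed scores, ties broken toward higher specificity — for ENE
a false positive escalates a patient to tri-modality therapy, so the
conservative side is the larger threshold.  Confusion metrics follow from
the thresholded predictions; the reported Youden always equals
sensitivity + specificity − 1 recomputed from the confusion matrix.
Calibration uses quantile bins (sizes within one) of predicted probability
and the Hosmer-Lemeshow chi-square on bins − 2 degrees of freedom.  ENE
metrics are computed only on nodes with ROI diameter >= 10 mm (closed
bound) — sub-centimetre ENE is essentially absent pathologically and
including trivially negative small nodes would flatter the metrics; NM
metrics use every test node.  The two endpoints are always evaluated
independently.

## Synthetic phantoms

The generator draws, per node: a class from the mix 0.582/0.234/0.184
(negative / NM without ENE / NM with ENE), a diameter from a class-specific
truncated lognormal (medians 10/16/23 mm, ranges 4–20/6–42/10–64 mm,
log-SDs 0.30/0.35/0.35 — medians and ranges are the known cohort statistics,
the lognormal is the standard positive-size model), and HPV/p16 positivity
at prevalence 0.28.  Among metastatic nodes the final ENE label is re-drawn
from a logistic model,

    logit P(ENE | NM, d, h) = −3.6 + 0.17 d + h (2.0 − 0.15 d),

with d in mm and h the HPV indicator, and P = 0 below 10 mm.  The negative
interaction (−0.15/mm) encodes the finding that HPV-positivity attenuates
the diameter–ENE association; the remaining coefficients were calibrated
once so that the marginal class mix, the ENE diameter median (≈23 mm) and
the ENE fraction among metastatic nodes (≈0.40) land near their targets,
and then frozen.  Because ENE is re-drawn, a metastatic node's final class
can sit outside its nominal diameter band — that is the label model working
as intended.

Voxel-wise, a negative node is a smooth ellipsoid (short axis = the drawn
diameter; the other semi-axes up to 35%/20% longer) of ~+60 HU tissue with
mild texture noise; metastatic nodes add a hypodense core (−10 HU, inner
55% of the radius) emulating necrosis; ENE nodes additionally get a
spiculated boundary (radial perturbation 1 + 0.25 sin 5θ sin 5φ) and an
elevated-HU rim just outside the capsule (fat stranding), which the
10-voxel dilation in preprocessing deliberately captures.  Backgrounds are
fat (−100 HU) with muscle blobs (+50 HU) and Gaussian noise (SD 12 HU); all
structure HU lie within [−200, +200], inside the informative part of the
clip window.  Everything is deterministic under the spec seed.

What the phantoms do *not* emulate: real neck anatomy (vessels, glands,
airway), scanner physics (beam hardening, partial-volume blur, dose noise
spectra), inter-observer contour variability, and the correlation structure
of real radiomic features.  Passing the desk-scale tests therefore
demonstrates that the pipeline's machinery — preprocessing, optimisation,
model comparison, statistics — is correct and that the architectures can
learn 3D morphological signals of this kind; it does not certify clinical
performance on patient data.

## Desk scale

All routine tests and the acceptance script run a reduced configuration
chosen as the package's CPU-sized reference problem: 180 nodes (60 per
class, one per phantom volume, 64 x 64 x 24 voxels at 1.5 x 1.5 x 3.0 mm),
desk preprocessing (2-voxel dilation, 32 x 32 x 16 box, 16^3 small input),
the desk DualNet, 25 training epochs.  Class-conditional diameters are
scaled down (medians 8/12/16 mm, ENE floor kept at 10 mm) so dilated nodes
fit the smaller box.  A full desk comparison (DualNet + both baselines +
evaluation) takes a few minutes on one CPU core.

The desk suite includes a **shuffled-label permutation control**: the
radiomics features and split are kept, the fitting labels are permuted, and
the random-forest test AUC is averaged over 10 permutations per endpoint.
The mean sits at chance when (and only when) no label information leaks
through the pipeline.  The control deliberately uses the radiomics model
rather than the CNN: a network trained on permuted labels collapses to
near-constant outputs whose single-run AUC on a 36-node test set is
numerically unstable (its null distribution is far wider than +-0.15), so a
single CNN control run cannot distinguish leakage from noise, while the
replicate-averaged forest control can.

## Numerical and design notes

* Split house size `ceil(n·frac)`; fold apportionment and quantile bins
  differ by at most one in size.
* Mask binarisation after bilinear resampling thresholds at 0.5; an
  interpolated-empty mask keeps its maximum-occupancy voxel.
* Hull membership tolerance 1e-9 on facet half-spaces.
* Youden ties break toward higher specificity; the threshold set is the
  observed scores.
* The L2 penalty is `l2·Σw²` exactly (not halved), so total loss minus data
  loss equals the coefficient-weighted squared-parameter sum.
* LR-decay patience resets on both improvement and decay.
* The monotone-difficulty sanity check (more phantom noise ⇒ lower AUC) is
  asserted on the radiomics baseline, which is orders of magnitude cheaper
  than CNN training and tracks the same signal.
* Oversampling duplicates are augmented independently (fresh random
  angles per copy).

## Known limitations

* The full-resolution (118 x 118 x 32) configuration builds and runs
  forward, but training it is outside CPU test budgets; reported desk
  results do not predict full-scale AUCs.
* The radiomics set is a ~30-feature core chosen for testable standard
  formulas, not a 99-feature parity set; exact parity with any specific
  extractor's naming/binning conventions is a non-goal.
* The logistic benchmark's covariate screening follows the fixed covariate
  list above; real cohorts would add site-specific covariates.
* DICOM reading supports plain single-frame CT series (slope/intercept
  rescale, position-sorted); RT-STRUCT contours must be rasterised to voxel
  masks upstream.
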