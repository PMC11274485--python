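# Methods

## Problem and approach

Outcome prediction for head-and-neck cancer from FDG-PET/CT normally
requires manual delineation of the primary tumor and involved lymph
nodes, which is slow, subjective and hard to reproduce. This package
implements a segmentation-free alternative: instead of tumor masks, the
whole anatomical head-and-neck region is located automatically from bone
landmarks on CT projections, and image information is summarized from
many projection views of the cropped PET volume.

The pipeline, in the order it runs:

1. **Volume harmonization** (`volume_io`). PET and CT volumes are read
   from NIfTI, reoriented into a fixed RAS+ axis convention
   (x: left→right, y: posterior→anterior, z: inferior→superior), and
   optionally resampled to a 1.0 mm isotropic grid with third-order
   spline interpolation. All boxes and indices are 0-based, half-open.
2. **Bone-guided cropping** (`region_crop`). The CT is windowed to the
   hard-tissue Hounsfield range [700, 2000]; coronal and sagittal maximum
   intensity projections (MIPs) of the windowed CT show the skeleton.
   A 2D head-and-neck box per plane — vertically from the shoulder-girdle
   (sternoclavicular/acromioclavicular joint) level to the top of the
   head, horizontally spanning the head/spine column — is either loaded
   from an annotation file (Pascal-VOC-style XML or a JSON dialect) or
   proposed by a rule-based landmark heuristic. The two 2D boxes combine
   into one 3D box (x from coronal, y from sagittal, z from the union of
   the two vertical extents) which is mapped through physical coordinates
   onto the registered PET grid and applied as a crop.
3. **Multi-angle MIPs** (`projections`). The cropped PET volume is
   rotated about its superior-inferior axis in fixed steps (default 5°,
   i.e. 72 views per full turn) and each rotation is projected along the
   anterior-posterior axis, so the 0° view reproduces the coronal MIP.
4. **Frozen feature extraction** (`deep_features`). Each view is
   normalized, padded to square, resized and channel-standardized, then
   passed through a frozen convolutional encoder; the final activation
   tensor is reduced per channel by one of four global poolings (average,
   max, median, population standard deviation), giving a V×C matrix per
   patient (views × channels).
5. **Multi-view fusion** (`fusion`). The V view vectors are fused into a
   single patient vector by channel-wise statistics (mean / median /
   max / std), by per-channel one-component ICA across the cohort, or by
   an autoencoder bottleneck on the flattened V·C input.
6. **Survival analysis** (`survival`). Fused features are standardized,
   highly correlated features greedily removed, ICA-reduced, and fitted
   with a (optionally ridge-penalized) Cox proportional-hazards model.
   Discrimination is estimated by Harrell's concordance index under
   nested 5-fold cross-validation (80/20) repeated with different
   shuffles; inner folds grid-search the hyperparameters.

## The frozen encoder

The encoder registry (`small`, `medium`, `large`) contains deterministic
random-feature convolutional networks: stacks of stride-2 3×3
convolutions with ReLU whose He-scaled Gaussian weights are drawn once
from a counter-based generator keyed by the backbone id, then frozen.
Random convolutional features preserve spatial structure, need no
training or external weight files, and make every run bit-reproducible
on a platform. The three scales differ in depth and width (final channel
counts 64 / 160 / 384); the channel count is always read from the
instantiated model. Inputs are mapped to [0, 1] either per image
(min–max; shape information only) or through a fixed intensity window
(default [0, 12] SUV-like units) that keeps uptake magnitude comparable
across patients; cohort analyses default to the fixed window, since
per-image scaling discards the absolute-intensity signal that drives the
survival endpoint.

## Fusion details

* Statistical fusions are exact per-column reductions; `cw_std` uses the
  population (divide-by-N) convention, as a feature summary rather than
  a variance estimator.
* ICA fusion fits, for each channel, a one-component FastICA on the
  cohort's N×V matrix of that channel's view values. The stored
  unmixing vector is unit-norm with its sign fixed by non-negative
  correlation with the cross-view mean. Channels with zero variance
  bypass ICA with a uniform 1/V vector; non-convergent channels fall
  back to the first principal direction and are recorded in the model
  metadata. Fitted fusions are estimated on training-fold patients only.
* The autoencoder is a single-bottleneck network (encoder D→L, decoder
  L→D, inputs feature-standardized inside the model) trained by
  full-batch Adam on mean-squared reconstruction (defaults: latent 256,
  200 epochs, learning rate 1e-2, seeded initialization). The bottleneck
  activation is linear, so with an adequate latent size the fit
  converges toward the best linear (PCA-like) subspace; this makes small
  cohort fits stable and reproducible, at the cost of not modelling
  non-linear manifolds.

## Survival analysis details

* Standard scaling maps zero-variance features to 0.
* Correlated-feature elimination scans features in order and drops any
  feature with |Pearson r| ≥ 0.95 (default) to an earlier kept feature;
  zero-variance features are dropped. The kept-index set from the
  training fold is applied unchanged to test folds.
* ICA reduction uses FastICA with a convergence tolerance of 1e-3 and up
  to 5 seeded retries before raising; the transform is a
  dimensionality-reduction step feeding the Cox model, not an
  interpreted source separation, so a modest tolerance is appropriate.
  ICA presumes non-Gaussian feature directions — true of pooled image
  features, but FastICA may legitimately fail on near-Gaussian inputs;
  such splits are recorded as failures, never silently dropped.
* The Cox fit is a ridge-penalized partial-likelihood maximization
  (scikit-survival); on separation or non-convergence the penalty can be
  escalated tenfold up to a cap (the cross-validation default).
* Harrell's c-index: a pair is comparable when the smaller time carries
  an event; tied times with two events are not comparable, tied times
  with exactly one event are; tied risks score 0.5. Zero comparable
  pairs raise an error.
* Nested CV: outer 5 folds × R repetitions (default 20; cohort-level
  tests and the acceptance script use 2 to stay CPU-friendly); inner
  5 folds grid-search over component count {10, 20, 50} (clamped to the
  feasible maximum per split), ridge penalty {0, 0.1, 1.0} and the
  correlation threshold {0.95}. Ties resolve to the earliest grid entry;
  if the selected point fails on refit, the next-ranked point is used.
  Both the overall mean/std over all outer splits and per-repetition
  summaries are reported, since a "mean over five test folds" is
  ambiguous under repetition. Every fitted object is learned on
  outer-training rows only; per-split fingerprints (SHA-256 over scaler,
  kept indices, ICA components and Cox coefficients) allow an exact
  leakage audit by refitting from the recorded training indices.

## Synthetic phantom family

The generator emulates the data regime the pipeline assumes, making every
stage testable without gated clinical data:

* **CT**: soft tissue at 40 HU containing a vertical head/spine bone
  column (1200 HU) topped by a wider skull block, plus a shoulder-girdle
  slab (clavicle-like bar left-right, scapula/sternum-like bar
  anterior-posterior) marking the SC/AC level — the landmarks the crop
  heuristic keys on.
* **PET**: a low background (0.3) with 1–3 solid ellipsoidal lesions
  (radii 3–8 mm, peaks 2–10 SUV-like units) placed inside the true
  head-and-neck box, plus Gaussian noise (sd 0.05), clipped at zero.
* **Survival**: each patient's lesion burden s = log Σ peak·volume is
  standardized across the cohort; event times are exponential with
  hazard h₀·exp(β·s_std) (defaults h₀ = 0.1, β = 1.5) and censoring is
  uniform administrative, with the upper bound calibrated by bisection
  so the expected censored fraction matches the target (default 20%).

Passing tests on phantoms demonstrate the mechanics of the pipeline —
cropping, projection geometry, feature determinism, fold hygiene and the
recovery of a planted image-driven hazard — not clinical performance:
the phantoms have no attenuation or partial-volume physics, no scanner
or center effects, no anatomy beyond the bone landmarks, and a
single-scalar effect on hazard.

At the default β = 1.5 the concordance of the *true* risk score is
itself only ≈ 0.78–0.79: for an exponential-hazard Cox model the
concordance probability is E[σ(|β·(s_i−s_j)|)] (σ the logistic
function), ≈ 0.787 for a near-normal standardized s, and Harrell's
estimate under 20% censoring is essentially the same. This value is the
information-theoretic ceiling for any pipeline run on these cohorts; the
end-to-end image pipeline reaches within a few points of it.

## Reduced problem sizes

Cohort-level tests and the acceptance script run at deliberately modest
sizes chosen as the package's own defaults for CPU-only execution:
n = 200 patients, 48×48×64-voxel phantoms (crops around 24×24×44), a
30° rotation step (12 views), the small encoder, average pooling,
channel-wise mean fusion, and 2×5 nested CV splits. The full-resolution
settings (5° step / 72 views, deeper encoders, 20 repetitions) are
plain configuration changes.

## Known limitations

* The encoder is a random-feature network, not an ImageNet-pretrained
  model; absolute feature quality on real images will differ, although
  the surrounding contracts (frozen weights, pooling, fusion, CV) are
  identical.
* The trained 2D object detector of the original workflow is replaced by
  box-file ingestion plus a bone-landmark heuristic; detector training
  and evaluation are out of scope.
* PET intensities are treated as already SUV-like; no SUV computation
  from raw activity is performed.
* The union rule for reconciling the two planes' vertical extents, the
  post-rotation projection axis, and the pre-encoder normalization are
  deliberate design choices where the workflow is underdetermined; each
  is exposed in configuration.
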