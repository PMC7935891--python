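# Methods

## The pipeline

`dermseg` implements a two-phase analysis of camera photographs of skin with
erythema (abnormal redness from increased superficial hemoglobin):

1. **Chromophore decomposition.** Under the Beer–Lambert attenuation model,
   per-pixel optical density is a linear mixture of the two absorbers that
   dominate skin color: `L = d_m q_m + d_h q_h + Δ`, with channelwise
   density vectors `d_m` (melanin), `d_h` (hemoglobin), scalar quantity
   fields `q_m`, `q_h`, and a residual `Δ`. The intensity→density map is
   `L = −log((I+1)/256)`; the `+1` shift keeps `L` finite at intensity 0 and
   makes the inverse map exact on the integer grid. The mixing directions
   are blind-estimated by a two-component fixed-point ICA over the pixel
   cloud; the 2-unknown × 3-channel inverse is the Moore–Penrose
   pseudo-inverse, and subtracting the per-component minimum `E` makes the
   quantity maps non-negative with minimum exactly zero. Each constituent
   renders back to an image via `I = 256·exp(−d·q) − 1`.
2. **Segmentation.** A U-Net-shaped encoder–decoder (zero-padded
   convolutions, max-pool down-sampling, nearest-neighbor up-sampling, skip
   connections at equal resolution) maps the channelwise stack of original +
   hemoglobin + melanin images (9 channels) to a per-pixel probability of
   abnormal skin, thresholded at 0.5 into a binary mask.
3. **Localization.** Connected clusters of mask pixels (8-connectivity) are
   contour-traced, wrapped in convex hulls, boxed by the hull's axis-aligned
   bounding rectangle, padded by 15 % per side, squared, and cropped from
   the original photograph.
4. **Classification.** Each crop is classified independently (so one image
   can carry several diseases), with a softmax confidence and full
   per-class distribution.

## Estimator design

The stages are scikit-learn-style estimators — `ChromophoreDecomposer`
(fit/transform), `SkinSegmenter` and `LesionClassifier` (fit/predict,
`get_params`/`set_params`, fitted attributes with trailing underscores) — so
they compose with sklearn model-selection tooling. The module-level
functions (`decompose`, `predict_mask`, `localize`, `classify`,
`analyze_skin`) are thin wrappers used by the CLI.

## Networks and training

No GPU deep-learning framework is assumed: the networks are built on a
small numpy layer library with hand-written backpropagation
(`dermseg._nn`), which keeps the whole pipeline runnable and exactly
reproducible on one CPU. Two named profiles exist:

* **full-scale profile** — 304×304 input, depth 4; training recipe:
  binary cross-entropy, Adam, learning rate 5e-4, weight decay 5e-4, 60
  epochs, learning rate ×0.1 every 20 epochs (segmentation); categorical
  cross-entropy, Adam 1e-5, weight decay 5e-4, 80 epochs (classification);
  18 disease classes. The classifier's `efficientnet_b4` backbone name is a
  plug-in point for an external implementation; it is not shipped.
* **miniature profile** — the tested path: 96×96 (or 64×64) inputs, depth
  3, 8 base channels; small CNN classifier (3 conv blocks + global average
  pooling) on 32×32 crops. All results in the test-suite and acceptance
  script use this profile.

The segmentation head's bias is initialized to the logit of the foreground
rate of the training masks. Lesions cover only a few percent of the pixels,
and with a 0.5-probability start BCE spends many updates learning to predict
"background everywhere" before anything else; prior initialization removes
that plateau, which matters at miniature training budgets.

Hyperparameter selection follows a three-replica protocol
(`replica_grid_search`): three seeded 90/10 train/validation splits, every
grid point trained per replica, scores averaged, argmax returned with ties
broken by grid order. The declared grids cover {BCE, Dice loss} × {Adam,
RMSprop, SGD(momentum 0.9)} × learning rates × {40, 60, 80} epochs for the
segmenter, and {CCE, focal} × the same optimizers for the classifier.

## Synthetic data: what it emulates, and what it does not

The generator renders skin through the same attenuation model the
decomposition assumes, so ground truth for every stage is exact:

* **Base chromophore fields** are sparse Gaussian-bump fields (exponential
  amplitudes, widths 2–6 px, ≈0.013 bumps/px) rescaled into fixed ranges
  (`q_m` ∈ [0.2, 0.8], `q_h` ∈ [0.1, 0.5]): freckle-like melanin deposits
  and capillary hemoglobin patches. Sparse bumps rather than smoothed noise
  because blind source separation requires non-Gaussian sources — two
  band-limited Gaussian fields would make the mixing directions
  unidentifiable in principle, and their ~(size/kernel)² effective samples
  make estimates unstable in practice.
* **Lesions** raise `q_h` by a constant boost (default 0.8) inside blobs;
  the boolean mask records exactly those pixels. Class identity is a lesion
  phenotype: filled disc / annular ring (an erythema-annulare-like shape) /
  coarsely mottled disc. The phenotypes are deliberately separable — a
  logistic regression on two oracle features (Euler number, internal
  texture variance) reaches 100 % — so classification failures indicate
  pipeline defects, not label noise.
* **Confounders**, all off by default and enabled in the experiment
  protocol: a dark non-skin background band (excluded from the mask);
  melanin-blob distractors (pigmented-nevus-like spots that mimic lesions
  in shape and darkness but not in chromophore); neutral shading
  (exposure/illumination variation, an OD offset equal across channels);
  and per-image color cast (white-balance variation, a constant per-channel
  OD offset). Casts are removed *exactly* by the decomposition's per-image
  offset subtraction, which is the mechanism behind the
  decomposition-benefit contrast below.
* **Noise** `Δ` is i.i.d. Gaussian in OD units (default sd 0.02).

Not emulated: specular highlights, hair, perspective and scale variation,
camera tone curves, lesion boundary feathering (masks are hard), and any
photometric calibration differences between devices. Passing tests
demonstrate that the pipeline machinery is correct and that its stages
compose; they do not certify clinical performance on real photographs.

## The experiment protocol

`run_experiment` reproduces the study design at a configurable scale
(defaults: 64×64 images, 3 classes × 40 images, 80/20 split by source
image, distractor background + melanin blobs + shading + cast):

* **Segmentation arms**: identical training with 9-channel
  (with-decomposition) vs 3-channel (original-only) inputs. The density
  matrix for the 9-channel arm is estimated once on pooled training-image
  skin pixels (per-image-centered, dark pixels excluded via a brightness
  threshold) and applied everywhere — the fit-once/apply-many mode —
  because per-image ICA gives each image an arbitrary component scale,
  which destabilizes cross-image training.
* **Classification arms**: whole resized images / crops from the trained
  segmenter's masks / the same crops after refinement. Refinement drops
  crops smaller than `min_area` or whose bbox is covered less than
  `min_overlap` = 0.3 by true lesion pixels — an automatic surrogate for a
  manual quality pass (available in synthetic mode where truth masks
  exist). Test crops are refined for all crop arms so the arms are scored
  on the same sample set; training crops are refined only in the refined
  arm. Crops inherit their source-image id and the split operates on
  source ids, so no photograph contributes crops to both sides.

## Numerical choices

* Binarization threshold 0.5; nearest-neighbor un-resize when mapping masks
  back to the original frame (no fractional mask values).
* Non-square images: aspect-preserving resize, then zero-pad to square
  (top-left anchored); the geometry record inverts the mapping.
* ICA: 4 seeded restarts; keep the converged solution whose sources have
  the largest total excess kurtosis (the fixed-point iteration can stall on
  near-Gaussian clouds). Components are sign-fixed (majority-positive),
  unit-normalized, and labeled by red-transparency: the component
  attenuating red least relative to green is hemoglobin. All scale lives in
  the quantity maps.
* Degenerate inputs: density estimation refuses rank-deficient pixel
  covariances (constant or two-color images) and images with fewer than 100
  usable pixels; Hausdorff distance raises on empty masks; zero-denominator
  rates return 1.0 and are flagged `vacuous` in the report.
* `fix_ratio` squares a padded bbox by centering the target window and
  shifting it back inside the image (clipping only when the image itself is
  smaller than the window), which keeps the operation idempotent at zero
  padding and always contains the original bbox.
* Ties: argmax ties in classification and Top-n ranking break toward the
  lowest class index (stable sort).

## Problem sizes

The test-suite and acceptance script run everything at the miniature
profile: 200 training images at 96×96 for segmenter trainability, 3 seeds ×
(two 15-epoch segmenters + three 12-epoch classifiers) at 64×64 for the
study contrasts, 300 truth-localized crops for the classifier, 20 images
for mixing-direction recovery, 50 masks for localization geometry. These
sizes were chosen so the full suite reproduces every claim on a single CPU
in well under half an hour.

## Known limitations

* The miniature networks are far below the capacity regime of the
  full-scale architecture; the study contrasts are demonstrated as ordered
  comparisons under fixed budgets, not as absolute performance claims.
* The decomposition assumes exactly two chromophores; shading leaks into
  the melanin map (both are near-neutral absorbers), which is tolerated
  because lesion detection reads the hemoglobin map.
* Refinement's overlap surrogate requires truth masks, so on real data the
  refined arm degenerates to the area filter unless masks are provided.
* SMOTE-style pixel interpolation is provided for completeness; the default
  balancing is augmentation-resampling, which is safer for images.
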