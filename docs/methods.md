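# Methods

`fundusdr` implements a patch-based deep-learning pipeline that detects and
segments the three cardinal signs of diabetic retinopathy — exudates,
hemorrhages and microaneurysms — in color fundus photographs, producing
mutually exclusive per-sign segmentations from per-pixel softmax
probability maps. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Pipeline overview

1. **Contrast enhancement.** Each image is transformed as
   `I_CE = α·I + β·(G_σ ∗ I) + μ` with a unit-sum Gaussian kernel
   `G_σ`. Defaults are α = 4, β = −4, σ = 10 px at the 1500×1152 reference
   resolution, μ = 128. Because α = −β, smooth regions collapse to the
   constant μ while structure at scales below σ is amplified fourfold: the
   transform is a band-pass that emphasizes lesions against the retinal
   background.
2. **Patch dataset.** Enhanced training images are tiled into
   non-overlapping S×S cells (S = 50 by default); each cell is labeled
   exudate / hemorrhage / microaneurysm / no-sign from the ground-truth
   masks; training cells are augmented with the 8 dihedral variants; the
   patch set is split 70/15/15 stratified by class.
3. **Classifier.** Four blocks of conv(16 maps, 3×3, same padding) → ReLU →
   max-pool(2×2, floor) → normalization, then FC(256) → ReLU → dropout(0.5)
   → FC(4) → softmax. Trained with mini-batch SGD using classical momentum
   and weight decay,
   `θ(p+1) = θ(p) − γ·∂L/∂θ + ϑ·Δθ(p) − a·γ·θ(p)`,
   on the mean negative log-likelihood `L_c = −(1/|C|) Σ ln p(D_i|C_i)`.
4. **Probability maps.** The trained classifier is slid over the whole
   image: the S×S window centered on each pixel of a stride grid is
   classified and the four softmax scores are written at that pixel,
   yielding maps P_E, P_H, P_M (+ background).
5. **Segmentation.** One threshold per sign is chosen on held-out images by
   maximizing Youden's J over the ROC curve of the sign's pixel scores;
   maps are binarized at `p ≥ Th`; pixels positive for several signs keep
   the most probable one; each sign's mask is cleaned by closing (5×5),
   opening (5×5) and erosion (4×4), and every 8-connected component smaller
   than S²/4 pixels (625 at S = 50) is removed.
6. **Evaluation.** One-vs-rest confusion counts at patch level (argmax
   class) and pixel level (within the field of view), reported as accuracy,
   error rate, PPV, sensitivity and specificity.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| α, β, σ, μ | 4, −4, 10 px @1500 w, 128 | enhancement gains, Gaussian scale, gray offset |
| S (patch side) | 50 px | window size, matched to the smallest signs |
| split fractions | 0.70 / 0.15 / 0.15 | stratified patch train/val/test |
| label_rule_min_overlap | 0.10 (microaneurysm 0.004) | fraction of a cell a sign mask must cover |
| learning rate γ | 0.01 | SGD step, stepped ×0.1 every 33 epochs |
| momentum ϑ | 0.9 | classical momentum on the applied step |
| weight decay a | 5e-4 | conventional companion value |
| weight init | Gaussian σ = 0.01 | all conv/FC weights; biases 0 |
| batches | 128 train / 32 eval | mini-batch sizes |
| max epochs | 43 | configurable; accuracy typically saturates earlier |
| dropout | 0.5 | after the first FC layer |
| map stride | 1 (pipeline default 4) | grid spacing of window evaluation |
| morphology | closing 5×5, opening 5×5, erosion 4×4 | in this order |
| area rule | S²/4 | minimum surviving component area |

## Design choices where the design was open

- **σ printed as a ratio.** The enhancement scale is specified as 300/30 at
  the reference width; we read it as the scalar 10 px and scale it
  proportionally with image width (σ = 2 px at the 300-px synthetic scale)
  so the band-pass covers the same retinal extent at any resolution.
- **Per-channel enhancement.** The transform is applied independently to R,
  G and B (configurable), preserving the color cues the classifier uses.
  Outputs are clipped to [0, 255] (μ = 128 implies an 8-bit convention) but
  kept in floating point.
- **Boundary handling.** Gaussian smoothing uses edge-including reflection
  (`scipy.ndimage` "reflect"); probability mapping reflect-pads by ⌊S/2⌋ so
  every pixel has a full centered window.
- **Patch labeling rule.** Manual curation of sign patches is emulated by a
  coverage rule: a cell is labeled with a sign when that sign's mask covers
  at least a cutoff fraction of it, larger overlap winning, exact ties
  resolved exudate > hemorrhage > microaneurysm. The default cutoff is 10%
  of the cell: cells that merely graze a lesion are poor class exemplars,
  and labeling them as background teaches the classifier a sharp boundary,
  which directly limits how far sliding-window detections spread beyond the
  true lesion. A microaneurysm (radius 2–4 px) can never cover 10% of a
  50×50 cell, so its cutoff is overridden to 0.4% (10 px), just below the
  area of the smallest dot — the general rule being that each sign's cutoff
  must sit below the area of its smallest instance.
- **Normalization layer.** The architecture names a normalization layer
  after each pool without fixing its type. The package defaults to batch
  normalization (with debiased running statistics) and offers across-channel
  local response normalization (`norm="lrn"`). The reason is numerical:
  with Gaussian(0, 0.01) weights each conv block multiplies the useful
  signal by roughly 0.01·√fan-in ≈ 0.1, so after four blocks the logits are
  ~1e-7 and gradient descent stalls on the class-prior plateau for longer
  than a desk-scale budget. Batch normalization restores unit scale after
  every block and training converges within ~20 epochs; LRN leaves the
  collapse untouched (its scale factor is ≈1 for small activations).
- **SGD form.** The update is implemented literally with the previous
  applied step as the momentum term (classical momentum), and the weight
  decay coefficient defaults to 5e-4, the conventional companion of this
  learning-rate/momentum pair.
- **Inputs.** Patches are scaled to [0, 1] and centered with per-channel
  means computed from the training split only.
- **Threshold criterion.** "Maximizing the ROC curve" is read as maximizing
  Youden's J = sensitivity + specificity − 1 over all distinct score
  values, ties toward the higher threshold; closest-to-(0,1) is available
  behind `criterion="closest"`. Thresholds are always fitted on the
  held-out threshold-fitting images, never on test images.
- **Morphology conventions.** Structuring elements are solid squares; the
  even-sized 4×4 erosion uses the top-left-of-center origin; connected
  components are 8-connected; the area rule runs after the morphology.
  Pixels outside the image frame count as background for all operations.
- **Stride > 1.** Per-pixel evaluation is the definition; stride > 1 is a
  computational concession, with off-grid pixels filled by bilinear
  interpolation of the grid values (values at grid pixels are exactly the
  per-pixel ones — pinned by tests).

## Synthetic fixtures

Real annotated fundus datasets are large and externally hosted, so the
test-bed is a parametric generator: a shaded reddish-orange disc (the field
of view) on black, smooth dark vessel-like curves, bright soft-edged
exudate blobs (radius 10–16 px at the 300-px scale), larger irregular dark
hemorrhages (12–20 px), tiny dark microaneurysm dots (2–4 px), Gaussian
pixel noise, all placed without overlap and recorded in pairwise-disjoint
ground-truth masks, fully determined by a seed.

What the generator emulates: the relative size, polarity (bright vs dark)
and color contrast of the three signs, vessels as dark distractors, the
circular field of view, annotation masks aligned to the modified pixels.
What it does not: photographic texture, illumination gradients, the optic
disc, drusen and laser scars, inter-grader variability, or the class
frequencies of clinical datasets. Passing the recovery tests therefore
shows that the pipeline's machinery — enhancement, training, mapping,
thresholding, cleanup — composes correctly and can recover planted signal
at realistic geometry; it does not certify clinical performance.

A second generator (`generate_separable_patches`) emits single-class
windows with the canonical appearance centred in the patch; these are
nearest-mean separable at accuracy 1.0 by construction and are used to
demonstrate that classifier training converges.

## Numerical choices

- Cross-entropy floors probabilities at 1e-12 inside the logarithm.
- `error_rate` is computed as `1 − accuracy` (algebraically equal to
  (FP+FN)/total) so the accuracy/error identity holds exactly in floating
  point; 0/0 ratios are reported as NaN and flagged, never zeroed.
- The Gaussian kernel is truncated at 4σ per side and renormalized to unit
  sum, which makes the constant-image identity exact.
- Max pooling uses floor division (50 → 25 → 12 → 6 → 3); convolutions use
  zero same-padding; training arrays are float32, metrics float64.
- Training is deterministic given the seed: one NumPy generator drives
  shuffling and dropout; batch-norm running statistics are zero-debiased
  exponential averages.

## Problem sizes used by the test suite

The full-scale recovery test trains on a 20-image fixture set (12 train /
4 threshold-fit / 4 test at 300×300), for 25 epochs, and maps held-out
images at stride 4. These sizes were chosen so the complete suite runs on
one CPU core in well under half an hour while the classifier is converged
(patch validation accuracy fluctuates in the 0.92–0.98 range over the
final epochs).

## Known limitations

- Overlapping hemorrhages and microaneurysms cannot be distinguished within
  a single region: overlap resolution assigns each pixel to exactly one
  sign.
- The sliding-window construction inflates every detection by up to ~S/2
  around the true lesion (windows that merely contain a lesion score
  positive); the ROC threshold and the erosion step counteract but do not
  eliminate this, so pixel-level specificity is the binding metric for tiny
  lesions.
- The area rule (S²/4) deletes true lesions whose detected component ends
  up smaller than 625 px; with the default fixture geometry this mainly
  disciplines noise, but for very small exudates it is the dominant failure
  mode.
- The NumPy classifier is CPU-bound and intended for patch sizes ~50 px and
  datasets of thousands of patches, not for full clinical corpora.
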