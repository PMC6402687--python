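# Methods

## Scope and conventions

`phasecell` analyses grayscale phase-contrast frames of cultured human
embryonic stem cells (hESC).  Pixels are 0-based, row-major `(row, col)`;
bounding boxes are half-open.  Images are carried as floats on the 0–255
scale; model inputs are rescaled to [−1, 1] only at the network boundary so
that image-quality metrics keep the 8-bit scale (L = 255).  The six classes
are always ordered `CC, DEB, UN, AT, DYN, APO` — every score vector and
confusion-matrix axis uses this order.

## Detection model

The substrate (background) and cell bodies (foreground) are modeled as two
Gaussians, N(μ_b, σ_b²) and N(μ_f, σ_f²).  Detection seeks the binary mask
maximizing the absolute mean-to-variance-ratio difference

    M = | μ_f/σ_f² − μ_b/σ_b² |

The implemented definition uses the *variance* in the denominator throughout
(the "mean-to-variance ratio" reading); this is the quantity the optimizer
maximizes, M_opt being its best value over the evolution.

Procedure and defaults (all exposed on `DetectionConfig`):

1. **Seed.**  Local intensity variance over a `w_var = 7` window, thresholded
   by Otsu.  Cell interiors and especially cell boundaries have high local
   variance; the substrate is comparatively flat.
2. **Spatial prior.**  Interior holes of the seed are filled (cell bodies are
   solid, while the variance seed is edge-dominated), and the mask is eroded
   by `w_var // 2` pixels with a disk footprint, because a variance window of
   width w spreads a step edge outward by w/2 pixels.  Without these two
   steps the M criterion can be gamed by edge-ring masks: corrupting the
   foreground with boundary pixels inflates σ_f², drives μ_f/σ_f² towards 0
   and *increases* M while the segmentation degrades.  On fixture frames the
   two steps raise Jaccard overlap from ≈0.3 to ≈0.93 and bring the fitted
   means within ~1 intensity unit of the generating values.
3. **Evolution.**  Up to `max_iter = 50` iterations: mean-filter the current
   mask (`w_mean = 5`), re-threshold at 0.5, re-fill holes, re-fit the two
   Gaussians, evaluate M.  The iterate attaining the maximum M wins; the loop
   stops early after `patience = 5` non-improving iterations.
4. **Cleanup.**  8-connected components smaller than `min_area = 30` px are
   discarded.  A constant frame returns an empty result rather than an error.

Overlap scoring uses SEN = TP/(TP+FN), SPC = TN/(FP+TN),
J = TP/(TP+FP+FN), DIC = 2TP/(2TP+FP+FN); undefined ratios are reported as
NaN so batch evaluation never aborts.  J ≤ DIC holds algebraically and is
asserted property-style over random masks.

## Hierarchical classifier

**CNN.**  Conv(7, 2, 3) ×64 → MaxPool(3, 2, 1) → Conv(5, 2, 2) ×128 →
MaxPool(3, 2, 1) → FC(2048 → 6); spatial chain 64→32→16→8→4, flatten length
2048.  ReLU activations (the nonlinearity is not otherwise constrained).
Training: SGD (lr 1.2e-2, momentum 0.9, weight decay 1e-3), batch 64,
cross-entropy, checkpoint on validation-accuracy improvement, stop after 3
non-improving epochs.  Augmentation samples rotation in [−180°, 180°], shear
in [0°, 30°] and zoom in [70%, 140%] uniformly; out-of-frame pixels are
filled with the crop's median intensity, resampling is bilinear.

**Triplet networks.**  The published description fixes the idea (shared
weights, a coarse early-layer branch concatenated with a fine deep branch,
skip-style reuse of early features) but not the exact layer sizes, so the
layout here is a design choice, config-exposed via `TripletLayout`:
stem Conv(5, 2, 2) ×32; coarse branch MaxPool(4, 4) → flatten (2048); fine
branch two Conv(5, 2, 2) stages (×64, ×64) → flatten (4096); concatenation →
FC → 128-d embedding, L2-normalized.  Unit embeddings make the pairwise
distance d = ‖e1 − e2‖/2 lie in [0, 1], which the complementary-distance
fusion rule (1 − d) requires.

The ranked marginal loss is implemented verbatim,
`L = max(0, −Y·(G(X1) − G(X2)) + margin)` with margin 1.  The training loop
feeds labels with the convention that makes minimization shrink the
same-class distance: with X1 the same-class anchor, Y = −1, so the active
constraint is d_same + margin ≤ d_other.  Triplet network A separates AT from
DYN, B separates CC from APO.  The full protocol samples 100,000 training and
5,000 validation triplets in batches of 256 (SGD; A: lr 1.2e-2, momentum 0.8,
wd 1e-3; B: lr 2e-2, momentum 0.8, wd 1e-3); the counts are override-able for
reduced-scale runs.

**Anchors.**  At inference each pair class is represented by the 5 training
images whose embeddings are nearest the class embedding centroid; query
distances are averaged over the anchors.  Averaging several anchors reduces
the variance a single hand-picked exemplar would introduce.

**Fusion (product rule).**  If the CNN argmax is DEB or UN, the CNN decision
is final.  Otherwise the relevant triplet network scores the two candidate
classes as `cnn_prob × (1 − mean anchor distance)`; the larger product wins
and exact ties fall back to the CNN argmax.  Fusion therefore never changes a
DEB or UN decision.

**Protocol helpers.**  `kfold_split` removes 10 images per class as a fixed
validation set, then stratifies the remainder into k = 5 folds balanced to
within one image (724 images split as 144 + 4×145).  `random_hp_search` draws
learning rate log-uniformly from [1e-4, 1e-1], momentum from {0.8, 0.9,
0.95}, weight decay log-uniformly from [1e-5, 1e-2], trains each candidate
3 epochs and keeps the best validation accuracy.  The occlusion map slides a
5×5 window of intensity 85 (stride 1) over a 64×64 crop and records the
classifier's target-class probability at each of the 60×60 valid centers.

**Statistics.**  Overall accuracy = 100·trace/total; per-class accuracy =
100·diagonal/row-sum; pairwise misclassification between A and B =
100·(count(A→B) + count(B→A)) / (rowsum(A) + rowsum(B)).

## GMAN

Generator: FC 100→8192 → reshape 512×4×4 → four ConvTranspose(6, 2, 2)
stages (256, 128, 64, 1 maps), tanh output; transposed-conv arithmetic
out = (in−1)·2 − 4 + 6 doubles the side each stage (4→8→16→32→64).
Discriminators (kernel 5, stride 2, pad 2, LeakyReLU 0.2):
D1 32/64/128/256 maps (flatten 4096), D2 16/32/64/128 (flatten 2048),
D3 32/64/128/256/512 ending at 2×2 (flatten 2048), each closing with a single
logistic unit.  Batch normalization follows every hidden layer except the
input layer of each discriminator and both output layers; it can be toggled
off in `GMANConfig`.

Training (Adam; generator lr 1e-4, discriminators lr 1e-5, batch 32 by
default): each discriminator is updated on a real batch (label 1) and a
generated batch (label 0) with BCE plus the embedding penalty
α·mean‖X_i − X‖² (α = 0.05, X a randomly drawn same-class real image; the
term is constant with respect to discriminator parameters and is included in
the reported loss).  The generator minimizes the weighted geometric mean of
the per-discriminator objectives V_i = E[log(1 − D_i(G(z)))], which are
negative by construction — the only reading under which GM(V, λ) is
well-defined.  λ defaults to 1 (λ = 0 gives the plain geometric mean).
During the generator update the aggregation weights w_i are treated as
constants, as is standard in multi-discriminator implementations; the
gradient through w only re-scales the per-discriminator terms and does not
change the fixed points.  Six independent models are trained, one per class.

## Evaluation metrics

SSIM is the single global-statistics form — one mean, variance and covariance
per image, no sliding window — with C1 = (0.01·255)² = 6.5025 and
C2 = (0.03·255)² = 58.5225.  Sample (n−1) statistics are the default; a
config flag selects the population form since the choice is not otherwise
pinned down.  PSNR is 10·log10(255²/MSE) with an infinity sentinel
(serialized as the string `"inf"`) when MSE = 0.  Quality reports average
each synthetic image against *all* real images of its class, then average
over the synthetic set.  The one-way ANOVA delegates to
`scipy.stats.f_oneway` with a degenerate-input guard (all values identical →
F = 0, p = 1); its correctness is checked against a hand-worked
decomposition ((1,2,3) vs (4,5,6) → F = 13.5).

## Synthetic fixtures: what they emulate and what they do not

The fixture generator reproduces the *statistical* structure the pipeline
assumes: background N(90, 64) and foreground N(180, 225) by default (a
well-separated regime; `hard_preset()` narrows the gap to N(90, 225) vs
N(130, 400) for stress tests), plus six distinguishable 64×64 morphologies —
halo-ringed round blob (UN), homogeneous ellipse (AT), blob with boundary
protrusions (DYN), blob with exaggerated internal texture (APO), central blob
with small adjacent sub-cells (CC), scattered fragments (DEB).  Frames place
disk-shaped cells with enforced separation and return the exact mask and
generating parameters, giving detection tests a ground-truth oracle.

The fixtures do **not** simulate phase-contrast optics (halo physics, shade-off),
focus drift, uneven illumination, cell motion blur or biological shape
variability.  Tests passing on fixtures therefore demonstrate that the
algorithms are implemented correctly under their stated model assumptions,
not that real-microscopy accuracy figures carry over.

All fixture randomness derives from one master seed through per-image
`SeedSequence` spawn keys, so datasets are reproducible file by file.

## Problem sizes used by the tests and the acceptance script

The test suite and `scripts/acceptance.py` run reduced-scale versions of the
training protocols, chosen once as representative of the study conditions:
classifier runs use 40 fixture crops per class (30 train / 10 validation) for
6 epochs; triplet runs sample ~1,000 training triplets in batches of 128;
the adversarial run uses 200 crops of one class, 200 generator steps and
batch 8 (the full-protocol defaults — 100,000 triplets, batch 32 — remain the
config defaults).  At these sizes the classifier reaches well above the 1/6
chance level and the generator objective visibly decreases, which is what the
checks assert.

## Numerical choices and known limitations

* All network arithmetic is float32 on a hand-written numpy engine (im2col
  convolutions, scatter-add col2im, BLAS matmuls); float64 is supported and
  used for finite-difference gradient checks.  Runs are bit-reproducible
  under a fixed master seed on a fixed BLAS build.
* Softmax/BCE use the standard max-shift / log1p stabilizations; embedding
  normalization floors the norm at 1e-8; distance gradients add 1e-8 to the
  denominator to avoid the d → 0 singularity.
* Otsu thresholding fails on constant maps; detection returns an empty result
  for constant frames instead.
* The margin of 1 with distances confined to [0, 1] means the triplet loss is
  active almost everywhere (zero only at d_same = 0, d_other = 1); training
  still orders the distances correctly, which is what fusion needs.
* `fit_two_gaussians` uses population (n) moments; at the region sizes
  involved the difference from sample moments is negligible.
* No test-time augmentation; a single forward pass per crop.
* Video decoding from microscope-native formats is out of scope; frames are
  supplied as PNG/TIFF files, with no frame-level preprocessing (no
  flat-field correction, bit depth assumed 8-bit).
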