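# Methods

## Problem and model

`sonovid` classifies grayscale breast-ultrasound cine sequences as benign or
malignant at the *video* level. A clip is an ordered set of frames
V = {v_t | t = 1..T} of arbitrary length. The model has three stages:

1. **Frame encoder Θ(·).** A ResNet-18-topology convolutional network
   (7×7/2 stem + 3×3/2 max-pool, four stages of two basic residual blocks at
   widths w, 2w, 4w, 8w, global average pooling) maps each frame to an
   m-dimensional feature f_t = Θ(v_t), m = 8w. Two departures from the stock
   backbone:
   * every batch-normalization layer is replaced by **group normalization**
     (per-sample statistics over channel groups). Video batches are small and
     frames within one clip are strongly correlated, which makes batch
     statistics unstable; group statistics are batch-size independent. The
     group count is gcd(32, C) so it always divides the channel count.
   * one **non-local self-attention block** is appended to stage 3 and to
     stage 4. In the embedded-Gaussian form used here, the response at every
     spatial position is a softmax-normalized weighted sum of the features at
     all positions (channel bottleneck C/2), added residually:
     out = x + W_z·y(x). W_z is zero-initialized, so a freshly inserted block
     is exactly the identity and cannot disturb a pretrained backbone.
   * the stem takes one channel (ultrasound is grayscale); no ImageNet
     weights are used anywhere.

2. **Multi-meta attention aggregation.** A cascade of L=2 shared
   fully-connected layers with Tanh activations scores each frame feature,
   E_l^t = tanh(W_l E_{l-1}^t + b_l) with E_0^t = F^t. A softmax across the
   *frame* axis, taken per feature dimension i, produces a T×m attention
   matrix A with Σ_t A_i^t = 1, and the video feature is the per-dimension
   convex combination F̄_i = Σ_t A_i^t F_i^t. Consequences, all tested:
   uniform weights reduce the operator exactly to average pooling over
   frames; the operator accepts any T without reconfiguration; it is
   invariant to frame order; sharply peaked weights approach per-dimension
   max pooling. Because the literal cascade ends in Tanh, logits live in
   (−1, 1) and per-pair weight ratios are bounded by e²; the exact
   max-pooling limit therefore requires the configurable
   `final_activation="none"` variant, which is provided while Tanh remains
   the default.

3. **Linear classifier.** One linear layer m → 2 with softmax; malignant is
   the positive class and the decision threshold on the malignant
   probability is 0.5. Inference uses every frame of a clip (the aggregator
   is length-agnostic); training subsamples T frames per clip.

## Contrastive pretraining

The encoder can be initialized by SimCLR-style instance discrimination on
frames: from N clips, M frames each are sampled, each frame is augmented
twice by τ (random horizontal flip, crop-then-resize, zoom, brightness
offset, contrast scaling, elastic deformation), embedded as
f̄ = MLP(Θ(τ(v))) and L2-normalized. The NT-Xent loss with temperature 0.5
treats the two views of one frame as positives and every other view in the
batch as a negative; optimization uses LARS (per-tensor trust ratio
||w||/(||g|| + wd·||w||), coefficient 0.001, momentum 0.9; 1-D parameters
excluded from adaptation and decay) under a cosine-annealed learning rate.
An alternative positive-pair definition treating two *different* frames of
the same clip as one instance (`positive_mode="same_video"`) is provided,
motivated by the cross-section variability of one lesion within a sweep;
the strict same-frame definition is the default.

The projection head is m → m → 128 with a batch-standardization step after
each linear layer (no affine, running moments for inference), ReLU between,
and ε-guarded L2 normalization (ε = 1e-12) at the output. The
batch-standardization follows reference SimCLR heads and is load-bearing
here: with group normalization in the backbone nothing else centers
features across samples, and without it NT-Xent training sits at the
collapsed fixed point loss = ln(2K−1) with vanishing gradients (all
pairwise cosines → 1). With it the loss optimizes normally.

## Synthetic data generator

No public dataset of labeled breast-ultrasound videos accompanies this
package, so `synthio` generates clips that emulate the properties the
method depends on:

* **speckle**: multiplicative noise, frame = clean·(1 + s·G) with s = 0.15
  and G a standard-normal field, then a σ = 1 px Gaussian blur to mimic the
  spatial correlation of real speckle; drawn independently per frame;
* **lesion**: a darker (0.4× background) star-convex region. The boundary
  radius over angle is an ellipse profile modulated by a piecewise-linear
  16-vertex perturbation of relative amplitude `irregularity` — 0.05 for
  benign (smooth, near-elliptic margins) and 0.35 for malignant (irregular,
  spiculated margins), the standard sonographic cue. Edges are anti-aliased
  with a 1.5 px smoothstep;
* **probe operation**: a bounded random-walk translation (1 px/frame
  default), slow zoom within [0.97, 1.03] and per-frame brightness offsets
  within ±0.05, mimicking free-hand scanning with brightness/scale
  adjustments; clip lengths vary by ±25 % around the template length;
* **defaults**: 64×64 px frames, T = 16 frames, lesion radius 0.25·min(H,W).
  Resolution and frame count of the clinical acquisition are not public;
  these values keep the lesion-boundary cue resolvable at CPU scale.

Class separability is verified at the population level: an independent
mask-based oracle (Otsu threshold → largest connected component →
isoperimetric ratio perimeter²/4πA) separates the classes with a one-sided
Mann–Whitney p ≪ 0.01 over 100+100 clips, so the end-to-end classification
task is learnable by construction. What the generator does **not** emulate:
acoustic shadowing and posterior enhancement, anatomical context (ducts,
fascia, ribs), vendor post-processing, BI-RADS heterogeneity, operator
re-centering. Passing tests on this data therefore demonstrates the
correctness and trainability of the pipeline, not clinical performance.

## Numerical substrate

All network computation runs on a small reverse-mode autograd engine over
float32 NumPy arrays (`sonovid.nn`): convolution by im2col + BLAS matmul
with a hand-written adjoint, max-pooling with argmax routing, broadcasting
ops with sum-to-shape backward. Gradients of every op are tested against
central differences; NT-Xent is tested against a double-loop oracle; the
softmax is computed with max subtraction; cross-entropy goes through
log-softmax.

## Training protocols

* `paper_default` preset: supervised SGD, 320 epochs, lr 1e-4, momentum 0.9,
  weight decay 5e-4, sample length T = 16, batch 8 clips, cross-entropy;
  pretext LARS, 8192 epochs, lr 9e-3, weight decay 1e-6, 64 frames
  (128 views) per batch, cosine annealing. These defaults encode the
  reference protocol and are far beyond CPU scale; they are configuration
  defaults, not exercised in tests.
* `tiny` preset (used by tests, the worked example and the acceptance
  script): encoder width 16 (m = 128), supervised 20 epochs at lr 0.02,
  T = 8, batch 8; pretext 40 epochs of LARS at lr 2.0 with N = 16 clips ×
  M = 1 frame per batch. Chosen so a full supervised run on 120 training
  clips takes about two minutes on one CPU core while reliably reaching
  ≥ 0.9 test accuracy on the synthetic task: ranking quality (AUC)
  saturates after ~10 epochs, but the 0.5-threshold calibration needs the
  train loss to converge, which the longer schedule guarantees.

Class weighting (inverse frequency) is available but off by default,
mirroring the unweighted protocol; the synthetic datasets are balanced.

## Evaluation

Six metrics with malignant positive: accuracy, average precision (step-wise
area under the precision–recall curve), sensitivity TP/(TP+FN), specificity
TN/(TN+FP), F1, and AUC via the Mann–Whitney rank formulation with ties
counting ½. The ROC curve groups tied scores, so its trapezoidal area equals
the rank AUC to 1e-9 (asserted). With a single class present AUC and AP are
reported as NaN with explicit `*_defined` flags rather than silently 0.

## Known limitations

* The contrastive stage, run at CPU scale (hundreds of optimizer steps
  rather than the 8192-epoch reference schedule), does **not** improve a
  frozen-encoder linear probe over random initialization on the synthetic
  data; in our experiments it consistently degrades it. Two views of a
  synthetic frame share clip-unique nuisance signals (the identical speckle
  realization in the strict mode, a static per-clip background field in
  both modes), so short instance-discrimination runs are solved by nuisance
  hashing instead of morphology. The corresponding directional acceptance
  test documents this by failing; the pipeline (loss, sampling, optimizer,
  checkpointing) is exercised and correct regardless.
* The exact max-pooling limit of the aggregator is unreachable with the
  literal Tanh-terminated cascade (logits bounded); `final_activation:
  "none"` exposes the limit.
* Checkpoints store parameters only; projection-head running moments are
  not persisted (the head is discarded after pretraining).
* Single-threaded CPU only; determinism is guaranteed under single-threaded
  BLAS.
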