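# Methods

`ndnseg` implements a three-dimensional multimodal segmentation pipeline for
gliomas: an encoder–decoder convolutional network augmented with channel
attention and nested dilated convolutions, trained per cascade stage as a
binary segmentation problem, with connected-component post-processing.  This
note records the model, its assumptions, the parameters that matter, and the
design decisions taken where more than one reasonable choice existed.

## Problem and data model

A case consists of four co-registered MRI modalities (T1, T2, post-contrast
T1, FLAIR) and an integer label map over four classes: 0 background, 1 edema,
2 non-enhancing tumor, 3 enhancing tumor.  Clinical volumes are typically
240×240×155 voxels at 1 mm isotropic spacing.  Tumor sub-regions are nested:
enhancing ⊆ tumor core (non-enhancing + enhancing) ⊆ whole tumor (+ edema),
and the whole tumor forms a single connected domain.  Volumes are stored
channel-last `(X, Y, Z, C)`; voxel boxes are half-open, 0-based.

External label codings (e.g. the BraTS convention 1/2/4) are mapped to the
internal scheme through explicit, validated tables; the file coding is never
assumed.

## Preprocessing

Each modality is z-scored per patient over the whole volume (population
standard deviation; zero-variance channels map to zeros).  Black x/y borders
are cropped to the tight bounding box of nonzero voxels; the central 70% of
z-slices is kept (`k = round(0.7·Z)`, lower start on ties).  Border
detection must run on the raw volume — z-scoring shifts the exact-zero
exterior — so pipelines crop first (or compute the box on the raw data)
and normalize after; whether published pipelines normalize before or after
border removal is generally unstated, and this package fixes the order for
determinism.
Training patches (default 96×96×48) are centered on uniformly drawn tumor
voxels, clamped to bounds and zero-padded when the source is smaller.

## Augmentation

Applied in the fixed order flip → rotate → gamma → elastic, each seeded:

| operation | default | notes |
|---|---|---|
| axis flips | p = 0.5 per axis | intensities and labels flipped together |
| rotation | uniform in [−15°, +15°] | axial plane only: the z-extent of clinical stacks (155 vs 240) makes through-plane rotation destructive |
| gamma | γ uniform in [0.4, 1.6] | applied in per-channel min-max space because z-scored inputs are negative; channel extrema preserved |
| elastic | α = 10 voxels, σ = 4 voxels | Gaussian-smoothed iid noise field; α and σ are package defaults, not literature values |

Intensities interpolate linearly, labels nearest-neighbor, so the label
alphabet never grows and patch shape is invariant.

## Network

The network is a depth-3 encoder–decoder (three 2×2×2 max-poolings, three
nearest-neighbor upsamplings) over 4-channel input.  Filter widths double
per encoder level and halve per decoder level (base width 16; a desk-scale
profile uses 4).

* **Residual blocks**: two 3×3×3 conv–BN–ReLU layers plus an additive
  shortcut (identity, or a 1×1×1 projection on channel mismatch).
* **SE blocks** after every level: global-average squeeze to one value per
  channel, excitation through C → ⌈C/r⌉ (ReLU) → C (sigmoid) dense layers
  (r = 16, floored at one hidden unit), channel-wise multiplication.
* **RnD blocks** in the first two encoder levels: three serial dilated
  3×3×3 convolutions (rates 1, 2, 5), each BN + ReLU, wrapped in a residual
  connection.  They raise the shallow-layer receptive field to 17 voxels
  per axis (1 + 2·(1+2+5)) without pooling.
* Decoder levels: upsample + 1×1×1 channel-halving conv, concatenation with
  the encoder skip, residual block, SE block; a final 1×1×1 conv emits class
  logits.  One residual block per decoder level (the stack depth is
  configurable).

The third encoder level uses plain residual blocks: nesting dilations is a
shallow-layer device and the deep levels already see large receptive fields.
Skip fusion by concatenation and nearest-neighbor-plus-conv upsampling are
conventional choices; all four (base width, SE ratio, fusion, upsampling)
are configurable.

### Hybrid dilated convolution (HDC) validation

Stacked dilated convolutions with a shared factor produce gridding: the taps
cover only a lattice, and small structures fall through the holes.  The rate
check enforces two conditions: pairwise coprimality of the rates, and the
max-distance recurrence

    M_i = max(M_{i+1} − 2 r_i,  2 r_i − M_{i+1},  r_i),   M_n = r_n,

requiring `M_i < K` for i < n (checking `M_n` would reject the canonical
(1, 2, 5) scheme, since `M_n = r_n` by definition).  The middle term is the
algebraic simplification of `M_{i+1} − 2(M_{i+1} − r_i)`.

A brute-force oracle (`gridding_coverage`) composes the 1-D tap sets by
Minkowski sum; a scheme is hole-free iff coverage is a contiguous interval.
Enumerating all rate triples in [1, 6]³ at K = 3 shows the conditions are
**sound but conservative**: no scheme passing both conditions has holes
(0 of 216), while 55 orderings — 8 among ascending triples, e.g. (1, 2, 2),
(1, 3, 3), (1, 3, 4) — are hole-free yet rejected.  Two sources of
conservatism: the strict `<` (the inequality is `≤` in part of the HDC
literature; `≤` would admit (1, 3, 3) but also wrongly admit the holey
(2, 3, 5), so neither variant is exact) and pairwise coprimality, which
rejects e.g. (1, 2, 2) although the unit rate fills the lattice.  The strict
`<` and the pairwise rule are implemented as printed; the survey is part of
the test suite.  One degenerate case is handled explicitly: for a
single-layer scheme the recurrence checks nothing, yet a lone dilated
convolution with r > 1 always grids, so `distance_ok` is `r == 1` when only
one rate is given.

## Losses

All losses act on per-voxel softmax probabilities `q` against one-hot truth
`p`; probabilities are clipped to [1e-7, 1] before logarithms.

* cross-entropy: `−(1/N) Σ_v Σ_k p log q`
* weighted cross-entropy: per-class factors, default (1, 1, 2, 1) —
  non-enhancing tumor, the rarest class, weighted double
* focal loss: `−Σ p (1−q)^γ log q / Σ p`, γ = 2; the exponent is read as
  binding to `(1−q)` only
* soft Dice: `1 − 2 Σ p q / (Σ p + Σ q + ε)`, ε = 1e-5

The printed form of the Dice loss carries a leading 1/N (N = voxel count);
taken literally it pins the loss at ≈ 1 with vanishing gradient scale for
any realistic N, so the canonical form is the default and the scaled form is
retained as `mode="as_printed"`.  The evaluation-side `dice_loss` sums over
all classes including background (configurable).  The **training** gradient
path excludes background from the Dice by default: with background included,
predicting background everywhere already achieves a loss equal to the
foreground volume fraction — about 0.003 for the enhancing stage — and the
optimizer demonstrably settles in that trap.  Foreground-only soft Dice
removes the degenerate optimum.

Metrics: Dice similarity coefficient `DSC = 2TP / (FP + 2TP + FN)` per class
one-vs-rest; two empty masks score 1.0 so benign cases (no enhancing tissue)
are well-defined.

## Cascade

Stage targets: 1 → whole tumor {1,2,3}, 2 → tumor core {2,3}, 3 → enhancing
{3}; each stage is a binary problem with a 2-class softmax head so the same
losses apply.  At test time the binarized stage mask's bounding box,
extended by (32, 32, 8) voxels in (x, y, z) and clamped to the volume, is
the next stage's crop; masks are re-embedded into the full frame and fused
with later-stage precedence (3 over 2 over 1).  Probabilities binarize at
0.5.  An empty stage-1 mask short-circuits to an all-background prediction.
During training, crops derive from ground-truth regions instead of predicted
masks.

## Post-processing

Two rules, in order: (1) keep only the largest 26-connected component of the
whole-tumor mask (ties to the first-discovered component); (2) relabel
enhancing components smaller than a volume threshold to non-enhancing —
relabeling rather than deleting preserves the single-connected-domain
property; deletion is available.  The default threshold of 200 voxels
targets 1 mm³ clinical voxels and is a package default, not a literature
value; runs on 64×64×32 phantoms use 20 voxels (the phantom enhancing core
holds ≈ 75).

## Training

Adam with first-moment decay 0.9 (reading the published "momentum" for this
optimizer as its first-moment coefficient) and L2 weight decay 1e-5 on
convolution and dense weights.  Paper-scale profile: base filters 16,
96×96×48 patches, batch 4, learning rate 1e-4, 300 epochs — far beyond CPU
budgets.  Desk-scale profile: base filters 4, 32×32×16 patches, batch 2,
learning rate 1e-3 (a small network trained for a few hundred steps wants
the larger step size), 240 steps per stage, flips-only augmentation.  Cases
split 80/20 into train/validation by case; the checkpoint with the best
end-of-epoch validation Dice is kept.  All randomness flows from a single
seed.

Two thirds of training patches are centered on stage-target voxels and one
third placed uniformly inside the stage crop.  Without the uniform share the
network never sees empty context and misfires on background-only windows at
inference (foreground oversampling with a background share is standard
practice in patch-based volumetric segmentation).

Inference is sliding-window with the training patch size, 50% overlap and
Gaussian importance weighting (probabilities blended with weights that
fall from 1 at the window center to ≈ 0.05 at its faces).  Two effects
motivate this.  The SE squeeze pools over the entire input, so a single
full-volume pass feeds the excitation layers context statistics far from
anything seen in training; tiling keeps the two distributions aligned (a
full-volume single-pass mode exists and is used for shape contracts).  And
windows that clip a small structure at their border predict it weakly;
under unweighted averaging those windows drag well-centered predictions
below the 0.5 threshold, which measurably erased most of the enhancing
class — center weighting lets each voxel be decided by the windows that
see it with the most context.

### The network engine

No deep-learning framework is part of the dependency set; `ndnseg.nn`
implements the required layers (dilated 3-D convolution as one matrix
product per kernel tap, batch normalization with running statistics,
ReLU/sigmoid, 2×2×2 max pooling, nearest-neighbor upsampling, dense layers,
global average pooling), their analytic backward passes, and Adam, all in
numpy/BLAS.  Every layer's gradient is verified against central finite
differences in the test suite, and the four loss gradients with respect to
logits likewise.  Arithmetic is float64.

## Synthetic phantoms

The generator emulates the *statistical structure* of multimodal glioma MRI,
not MR physics: nested ellipsoids (enhancing ⊂ core ⊂ whole tumor) at a
jittered center inside an elliptical brain mask, exact zeros outside the
mask (so border cropping is exercised), per-class per-channel mean
intensities plus Gaussian noise (σ = 0.1).  The class-mean table gives each
tissue its expected contrast pattern — enhancing tissue bright in
post-contrast T1, edema bright in FLAIR.  Default shape 64×64×32 so a
depth-3 network trains in minutes on one CPU; a benign flag merges the
enhancing region into the core.  `inject_artifacts` adds the two defect
types post-processing removes: disconnected small tumor blobs and a
sub-threshold enhancing speck inside the core, both guaranteed non-adjacent
(full 26-neighborhood) to the structures they must not merge with.

What passing tests on phantoms do **not** show: robustness to real tissue
texture, intensity inhomogeneity, partial-volume effects, registration
error, or tumors whose classes overlap in intensity.  Phantom classes are
separable by per-channel means, so learned Dice scores here are upper bounds
of a sanity check, not performance claims about clinical data.

## Numerical and degenerate-input choices

* Probability clipping floor 1e-7; Dice ε = 1e-5 (denominator only).
* Zero-variance channels normalize to zeros; constant channels pass through
  gamma correction unchanged.
* Both-empty masks score Dice 1.0.
* Empty stage masks stop cascade refinement with a logged warning; benign
  cases skip stage-3 training examples.
* Slab centering ties break toward the lower start index; equal-size
  component ties keep the lowest id.
* He-normal weight initialization; BN momentum 0.9, eps 1e-5.

## Known limitations

* CPU-only: paper-scale training (base 16, 96×96×48 patches, 300 epochs) is
  impractical in this engine; the desk profile is the supported scale.
* Single connected tumor assumed by post-processing; multifocal disease
  would be harmed by the largest-component rule.
* No Hausdorff or surface metrics; evaluation is Dice only.
* The HDC check is conservative (see above); schemes it rejects can be
  forced with `allow_invalid_scheme`.
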