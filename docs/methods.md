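# Methods

This note documents the models, numerical choices, and open design
decisions behind `gbsd`, and what the synthetic study does and does not
demonstrate.

## Problem setting

The package classifies 2-D dermoscopy-style lesion images as benign or
malignant and produces pixel-level visual explanations of each decision.
The discriminative cues it is built around are the two classic clinical
ones: border irregularity and intra-lesion texture heterogeneity.  All
stages run on a single CPU with no pretrained weights and no external data.

## Synthetic data generator

The generator is the package's study population, not a test fixture.  A
lesion is a filled star-convex region with radius
`r(θ) = r0 (1 + Σ_k a_k sin(kθ + φ_k))`, harmonics k = 2…7, where the total
harmonic amplitude `Σ|a_k|` is the *border irregularity* knob (benign 0.05,
malignant 0.35).  The lesion (base intensity ≈ 0.35–0.45) sits on a lighter
skin-tone gradient (≈ 0.70–0.88) so it is always darker than its
surroundings.  Intra-lesion texture is spatially correlated Gaussian
blotching (correlation length 2 px) rescaled to an exact standard deviation
(*texture sigma*: benign 0.03, malignant 0.15 on the [0,1] intensity
scale).  Per-image additive sensor noise has σ = 0.01, and 0–8 dark
curvilinear hair strokes (quadratic Bézier curves, width 1–3 px,
attenuation 35–55 %) are overlaid per image.

Seeding is counter-based: image *i* draws from
`SeedSequence((master_seed, i))`, so generating a larger dataset never
changes earlier images, and fixed seeds give byte-identical PNGs.

What the generator does *not* emulate: real pigment-network structure,
color information relevant to dermoscopy (the default is single-channel),
vignetting, rulers/gel artifacts, multi-lesion frames, and class overlap —
the two synthetic classes are separable by construction.  Passing the
end-to-end tests therefore shows the pipeline's machinery is correct and
learnable-from, not that it would reach comparable accuracy on clinical
data.

## Preprocessing

*Hair removal.* Grayscale black-hat responses (closing minus image) are
computed with linear structuring elements (length 15 px) at 8 orientations
and thresholded at 0.08.  A pixel is declared hair only if (a) at least half
the orientations respond — a hair is thin in almost every direction, while
a lesion boundary responds only tangentially; (b) it does not belong to a
region surviving a 5×5 erosion — hairs are ≤ 3 px wide, pigment blotches are
wider; and (c) its connected component spans at least the kernel length.
Hair pixels are replaced by the median of non-hair pixels in a growing
window (NaN-masked median, starting at 5×5).  On hairless synthetic images
the filter alters < 1 % of pixels; on hairy ones it reduces the mean
absolute error against the pre-stroke ground truth by roughly an order of
magnitude.

*Smoothing.* Gaussian blur, σ = 1 px; σ = 0 is the identity.

*Lesion localization.* Per-pixel adaptive thresholding: foreground where
`I < mean_{w×w}(I) − offset`, with window w = 31 px and offset 0.03,
reflective padding.  The darker-than-mean direction is fixed because
lesions are darker than skin; a flag inverts it for other modalities.  For
lesions larger than the window, only the boundary band responds; a 5×5
binary closing bridges gaps, the largest connected component is kept,
holes are filled, and the bounding box plus a 10 % margin is cropped and
resized to 128×128.  The window/offset defaults were calibrated once on the
generator's defaults and recorded here; at those settings the lesion-mask
IoU against the synthetic ground truth has median ≈ 0.95 across both
classes (the acceptance script reports the measured value).

Degenerate input: an empty threshold mask falls back to the full-frame ROI
with a logged warning rather than an error, so batch runs survive a failed
segmentation.

## Feature maps

All descriptors use reflective (edge-repeating) padding and produce
128×128 maps; the channels are min-max normalized to [0,1] independently
(a constant channel maps to zero) and concatenated in a fixed order:
`lbp, ldp, stat_mean, stat_median, stat_mode, deep_0 … deep_{k−1}`.

*Grid structural pattern (LBP variant).* The plain 3×3 LBP code of pixel p
is `Σ_d U(I_d − I_p)·2^d` over its 8 neighbours, with U(t)=1 for t ≥ 0
(equality counts as 1) and bit order fixed as top-left then clockwise —
codes are order-dependent, so the order is part of the contract.  The grid
variant assigns to each pixel the *mean of the nine codes* in its 3×3
cell, each cell member acting as its own LBP center.  Averaging over the
cell damps single-pixel intensity flips, which is the variant's point.
Implementation note: the cell mean is a 3×3 box filter over the per-pixel
code map; a brute-force double-loop oracle in the tests pins the
equivalence exactly, including the border convention.

*Grid directional pattern (LDP).* The 8 Kirsch compass masks (coefficients
summing to zero) are correlated with the image; per pixel the bits of the
m = 3 strongest responses are set, ties resolved toward the lower
orientation index, so every code has popcount m.  m = 3 is the standard
LDP choice.  Both LBP and LDP depend only on intensity differences and are
invariant to adding a constant to the image (property-tested).

*Statistical maps.* Windowed mean, median and mode with a 3×3 window.  The
mode is computed on 8-bit quantized intensities, ties toward the smallest
value — the mode is ill-defined on continuous data, so quantization is part
of the definition.  The window is odd, making the median the exact middle
order statistic; with an even sample count it would be the mean of the two
middle values.

*Deep maps.* A deterministic, fixed-seed random-projection conv stack
(two conv→ReLU→pool blocks, 8 then 16 channels) whose final activations are
reduced to k = 8 channels by a 1×1 projection and resized to 128×128.
Random convolutional features are a standard cheap filter bank; the
classifier trained on top is what carries the discriminative burden.  A
VGG-16 layout is available behind the same interface but only from a
locally supplied `.npz` weights file; nothing is downloaded.

## The classifier and its explanations

The network the package trains is a compact NumPy implementation: same-pad
stride-1 convolutions (im2col + BLAS matmul, float32), ReLU,
non-overlapping max pooling with deterministic first-winner tie-breaking,
inverted dropout, dense layers, and a softmax/cross-entropy head.  Every
layer has an explicit backward pass; finite-difference tests pin the
gradients to ~1e-7.

Architecture: a 1×1 adapter convolution maps the input to an 8-channel
stem, followed by three conv(3×3)→ReLU→maxpool(2) blocks with (8, 16, 32)
filters, dropout (rate 0.25), a 32-unit dense layer and a 2-class softmax.
There are *two* adapters sharing one trunk: one consumes the 13-channel
feature stack (pass 1), the other the single-channel fused saliency map
(pass 2).

*Saliency.* With Y the pre-softmax logit of class q and A the last conv
block's rectified activations:

- Grad-CAM++: `H = relu(Σ_l w_l A^l)` with
  `w_l = Σ_ij α_ij · relu(∂Y/∂A_ij)` and
  `α = g² / (2g² + Σ_ij A·g³)` built from elementwise powers of the
  first-order gradient g; zero denominators yield α = 0.
- FullGrad: `P = |x ⊙ ∂Y/∂x|` (summed over channels) plus each conv
  layer's spatial bias-gradient contribution `|b_c · ∂Y/∂z_c|`, each term
  min-max normalized before aggregation.  Dense-layer bias terms are
  spatially uniform and vanish under min-max normalization, so they appear
  only in the completeness identity
  `Y = x·∂Y/∂x + Σ b·∂Y/∂b`, which holds exactly for this ReLU network and
  is asserted to 1e-4 in the tests.
- Guided backprop: the input gradient with negative upstream gradients
  zeroed at every ReLU.

H and P are upsampled to the input size and min-max normalized to [0,1]
before fusion — without a common scale one map dominates — and fused
elementwise: `OH = (H + P)/2`.

*Two-pass training.* The data flow is intentionally circular: features →
prediction → saliency → classifier input.  It is made well-posed by a
warm-up: the first 20 % of epochs train pass 1 on raw stacks only (the
saliency of an untrained network is noise).  Afterwards the fused maps of
the training and validation sets are generated with the current weights,
cached, refreshed every 2 epochs, and pass 2 trains on them alongside
pass 1; the optimizer is mini-batch SGD (momentum 0.9, learning rate
0.005, batch 16) with the global gradient norm clipped at 5 — without
clipping the conv stack occasionally diverges mid-run at the 200-image
scale.  After the last epoch the validation metrics are recomputed with
freshly generated saliency, so the report matches inference exactly.
Inference always reports pass-2 probabilities; an exact probability tie
resolves to benign with a warning.

## The AICO optimizer

A bounded population metaheuristic (population N ≥ 4, box constraints,
`tmax` iterations).  Per iteration and individual:

1. *Predation*: `R ← R + r1(R_best − R) + r2(R_mean − R)` with
   `r1 = b1 (t/tmax)² |sin(π t/tmax)|`,
   `r2 = b1 (1 − t/tmax)² |sin(π t/tmax)|` (b1 = 2 by default): the pull
   shifts from the population mean toward the global best as the run ages.
2. A phase switch `ρ_s = a^y`, y ~ U[0,1]: if ρ_s > 0.5, *deviated search* —
   a running-length factor `L = clip(|(e − e^{((t−1)/tmax)²}) sin(2π r4)|, 0, 1)`
   applied along `⌈r5·d⌉` randomly chosen dimensions of the offset from the
   population mean, a unit Gaussian kick with probability 0.05
   (`round(0.5(0.05 + r3))`), plus a velocity memory; otherwise *stashing* —
   a single-dimension burrow move scaled by the iteration-decreasing hiding
   parameter `M = ((tmax − t + 1)/tmax)·r6`, with `r6 = 1{ρ_p > 0.5}` and
   ρ_p the individual's mean normalized position.
3. Clip to bounds, then greedy improve-or-retain selection.

With the default a = 2, ρ_s ≥ 1 and the search always takes the deviated
branch; a < 0.5 activates stashing (the branch is fully implemented and
exercised in tests).  Velocity is committed only when the move is
accepted; updating it on rejected moves lets the memory grow unboundedly
and stalls late-stage refinement.

After the population sweep the global best is refined by a Taylor-series
memory update: `core = (1.359·h1 − h2 + 0.6795·h3)/D` over the best's last
three positions, `D = 0.5 + P·r6 + M·x_k·r6 − 1` per dimension (entries of
D with |D| < 1e-9 pass the current best through unchanged), blended as
`core·(1 − r1 − r2) + (r1 + r2)·R_best`, accepted greedily and written over
the worst individual when it improves.

Greedy selection gives two exact guarantees used throughout the tests:
best-so-far monotonicity and bound feasibility after every step.  On the
5-d sphere (bounds ±5, N = 20, 300 iterations) the median best over 5 seeds
lands far below 1e-2.

*Hyperparameter tuning.* A 4-d unit-cube encoding maps to the classifier's
learning rate (log-uniform 1e-4…1e-1), dropout (0…0.5), a conv-filter
ladder ((4,8,16)/(8,16,32)/(16,32,64)) and a batch-size ladder
(8/16/32/64); decoding is deterministic and round-trips ladder points.  The
fitness is held-out accuracy (maximized).  An optional desk-scale mode
would let AICO drive network weights directly; the package tunes
hyperparameters, which is the variant that scales.

## Evaluation protocols

Malignant is the positive class.  Accuracy, CSI (threat score
tp/(tp+fp+fn)), FPR and FNR are computed from exact confusion counts; any
zero denominator yields an explicit `None` rather than 0, so degenerate
tables cannot silently inflate a metric.  "TP n" means an n % *training
percentage* stratified hold-out (TP 80 = 80/20); k-fold is stratified with
folds balanced within one sample.  Both protocols are seeded, disjoint and
exhaustive.  Reports contain per-epoch metric rows (checkpoints of a
single run), final confusion matrices, and the saved per-sample
predictions from which the metrics can be regenerated bit-identically.

## Problem sizes and defaults

The study configuration used by the acceptance script and the end-to-end
tests: 100 images per class at 128×128, TP-80 split, 13-channel feature
stacks, 20 training epochs.  Unit and property tests run on 8×8–32×32
inputs with reduced channel counts; the optimizer benchmark uses the
5-dimensional sphere.  All defaults above are recorded in the dataclass
configs (`SyntheticConfig`, `ECNNConfig`, `AICOConfig`, `SplitSpec`) and in
this note.

## Known limitations

- The synthetic classes are cleanly separable; real dermoscopy is not.
  Accuracy numbers from the synthetic study characterize the pipeline, not
  clinical performance.
- The deep-feature backbone is untrained by default; with a local VGG-16
  weights file the same interface yields pretrained features, but that path
  is exercised only for its error handling in the test suite.
- Saliency-map classification (pass 2) discards the raw feature stack at
  inference; on data where the saliency geometry is less class-informative
  than the texture itself, pass-2 accuracy may trail pass-1.
- Single-device determinism only: results are bit-reproducible on one
  machine/BLAS, not across different BLAS builds.
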