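# Methods

This note records the modelling choices behind `pflyolo`: what each
component computes, the conventions the numbers depend on, which design
points were genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## The architecture family

The baseline is a 23-layer anchor-free single-stage detector of the
YOLOv8n family: a backbone of stride-2 convolutions and C2f
(split-bottleneck fusion) stages with channels 16/32/64/128/256 and C2f
repeat counts 1/2/2/1, an SPPF pyramid at layer 9, an FPN/PAN neck
(layers 10–21), and a decoupled detection head (layer 22) fed from strides
8/16/32. Box edges are regressed as distributions over `reg_max = 16` bins
and decoded by expectation (distribution-focal convention).

PFL-YOLO substitutes four lightweight modules layer-for-layer, so layer
indices stay comparable across variants:

* **EHConv** (layers 0, 1, 3, 5, 7, 16, 19) — grouped 3×3 stride-2
  convolution → efficient channel attention (ECA) → batch norm → Hardswish,
  in that order. ECA's 1-D kernel width follows the adaptive rule
  k = nearest-odd((log2 C + 1)/2), floored at 3.
* **RC2f** (every C2f site: 2, 4, 6, 8, 12, 15, 18, 21) — a Res2Net-style
  ladder: two 1×1 stems to a hidden width m, split into four groups
  x1..x4; y1 = x1 and yi = Ti(xi + y(i−1)) for i ≥ 2 with Ti a grouped 3×3
  convolution; concat → grouped 1×1 fuse → ECA.
* **ESPPF** (layer 9) — SPPF with both 1×1 convolutions grouped and ECA on
  the output; the three chained 5×5 stride-1 max-pools are unchanged.
* **PFDetect** (layer 22) — a merged head: each scale is projected by its
  own grouped 3×3 convolution to a common width, then refined by two 3×3
  grouped convolutions whose weights are **shared across the three
  scales**, with ECA between them and a channel shuffle after the second
  (grouped) stem; shared grouped 1×1 convolutions emit the 64 box-bin and
  nc class channels.

Hardswish (0 for x ≤ −3, x for x ≥ 3, x(x+3)/6 between) is used only inside
the improved modules; baseline blocks keep SiLU. Note hardswish is *not*
monotone on all of (−3, ∞): its minimum is −0.375 at x = −1.5. The test
suite asserts the three branches, continuity at ±3, and monotonicity from
the minimum onward.

## Calibration of group counts and widths

The published description specifies *that* convolutions are grouped but not
the group counts, hidden widths, or the head's internal width. These are
configuration here, fixed once by calibrating against the published budget
table (nine variant rows of parameters-in-millions and FLOPs-in-G, plus the
exact layer-22 anchors 762,244/59,861 parameters and 3.025/0.405 GFLOPs).
The calibrated configuration — the shipped default — reproduces **all
nine** rows at their printed precision simultaneously:

* ESPPF: groups c_in/8 → (32, 64) at layer 9.
* EHConv: per layer, the largest divisor of gcd(c_in, c_out) not exceeding
  c_out/4 → groups (1, 8, 16, 32, 64, 16, 32).
* RC2f: hidden width m = 0.75·c_in; 1×1 stems ungrouped; ladder and fuse
  convolutions with 2 groups. Calibration also settles an ambiguity in the
  source description (neck-only vs everywhere): only the *every-C2f*
  substitution matches both the parameter and FLOP rows of the RC2f
  ablation.
* PFDetect: width 48; per-scale projector groups (2, 8, 4); shared stem
  groups (3, 8); head groups 4 (class head falls back to the largest
  divisor of gcd(48, nc) ≤ 4 when nc is not divisible by 4). Sharing the
  stem weights across scales is forced by the anchors: with per-scale stem
  weights, no configuration reaches 0.405 G at 59,861 parameters
  (parameter-exact candidates cap near 0.33 G).

Residuals: the baseline head counts 763,012 here vs the published 762,244
(+0.10%) and PFDetect 59,999 vs 59,861 (+0.23%); totals agree at the
printed two-decimal precision. The residual is a counting-convention
artifact of the exact framework build behind the published figures and is
within the ±0.3% band the budgets are checked against.

## Counting conventions

* **Parameters**: convolution weights k²·C_in·C_out/g, biases where
  present, batch-norm affine pairs (2C, running statistics excluded), ECA
  1-D kernels, and the fixed 16-weight distribution-focal kernel (counted,
  never updated).
* **FLOPs**: 2 per multiply-accumulate, convolutions only (2-D convolutions
  at their output resolution and the 1-D ECA kernel, k·C MACs once per
  forward); pooling, upsampling, concatenation, activations and
  normalisation count zero. This convention reproduces the published
  layer-22 value of 3.025 G for the baseline head.
* **Model size**: parameters × bytes-per-value / 10⁶ plus a fixed 0.1 MB
  container overhead. Published size figures scatter ±0.1 MB around this
  line; size is reported but not used as a calibration anchor.

Counts are produced two independent ways — closed-form from the layer
specifications, and by introspecting the weight arrays of the instantiated
network — and the test suite requires exact agreement across the whole
2⁴ ablation lattice.

## Numerical core

The forward pass, gradients, smoke training and Grad-CAM run on a small
reverse-mode autodiff engine over NumPy float32 arrays (grouped im2col
convolutions lowered to BLAS, exact col2im backward, argmax-routed
max-pool gradients, training-mode batch-norm backward). Every operator's
gradient is verified against float64 central differences at tolerance 1e−4.
Weights initialise Kaiming-style from an explicit seed; batch-norm starts
at γ=1, β=0 with momentum 0.03 running statistics.

## Dataset curation

* **SSIM** is the *global-statistics* form printed in the source
  formulation — one mean/variance/covariance per image pair on the
  luma-weighted grayscale, constants k1=0.01, k2=0.03, L=255 — not the
  sliding-window variant (available behind `windowed=True`). A test pins
  the global form to the windowed implementation evaluated with a single
  whole-image window.
* **Duplicate filtering** scans each identity class in input order and
  rejects an image whose SSIM against *any already-retained* image exceeds
  0.75 (the comparison policy is unstated in the source; greedy
  sequential-reference is the documented choice, and it is idempotent).
* **Augmentation** draws exactly one of six transforms per item: h-flip,
  v-flip, rot90 (k ∈ {1,2,3}), shift-scale-rotate (±6.25% shift, ±10%
  scale, ±15° — ranges unstated in the source, library-typical defaults),
  brightness-contrast (±20%), and HSV jitter (hue ±0.05, sat/val ±30%).
  Geometric transforms map the four box corners and re-fit the axis-aligned
  box, clipped to the frame; degenerate results are redrawn.
* **Split-then-augment**: a *global* seeded permutation with
  val = test = floor(N/10) and train the remainder, then one augmented copy
  per item inside its own split. This is the only order/rule consistent
  with the published 6418 → 5136/641/641 → 10,272/1282/1282 arithmetic
  (augment-then-split would give a 1283-item holdout).

Frame extraction operates on frame sequences (arrays, iterables,
multi-frame image files, or directories); containerised video decoding is
out of scope for this package.

## Evaluation

Matching is greedy in descending confidence with one-to-one assignment at
the IoU threshold; P/R/F1 follow the printed formulas with 0/0 → 0.
Average precision applies the monotone precision envelope to the enumerated
PR points and integrates exactly (rectangle sum); mAP@50:95 averages IoU
thresholds 0.50:0.05:0.95. A 101-point sampled variant exists behind
`sampled=True`. The exact method is pinned to a brute-force
enumerate-envelope-sum oracle in the tests. Point metrics default to
confidence 0.25 / IoU 0.5 (not stated in the source; configurable).

Grad-CAM weights a chosen layer's activation channels by spatially averaged
gradients of the top class logit, rectifies, and normalises to [0, 255].
The area of interest binarises the map (Otsu by default; fixed threshold
for reproducible tests), extracts boundary contours at level 0.5 and sums
the shoelace (Green's theorem) areas of outer contours — hence half-pixel
values. Convention note: the level-0.5 contour cuts each convex corner, so
a solid n-pixel rectangle measures n − 0.5.

## Smoke training

Smoke training exists to demonstrate end-to-end trainability, not accuracy
claims: centre-cell assignment at all three scales, weighted BCE on the
class map, distribution-focal cross-entropy on the centre-to-edge
distances, SGD (momentum 0.937, weight decay 5e-4, lr 0.01 — the
study-scale hyperparameters; only the schedule length and image size are
smoke-scale: 40 epochs at 64×64 on 2 classes × 20 images in the acceptance
test). Under those conditions the model overfits its training items to
mAP@50 > 0.9 and its Grad-CAM hot region overlaps the annotated face box.

## What the synthetic data does and does not show

The generator produces procedural faces — an ellipse with a class-specific
hue and stripe signature, eye/nose dots, on a textured background — with
exactly one box per image, optionally with jittered near-duplicate frames
(SSIM > 0.75 against their source). It reproduces the *structural*
properties the pipeline relies on (label format, class structure, duplicate
statistics, separable identities) but none of the photometric difficulty of
real barn footage: occlusion, motion blur, exposure extremes, ear-tag
confusion. Passing tests therefore validate the machinery — arithmetic,
wiring, gradients, bookkeeping — not recognition performance on real
animals.

## Known limitations

* CPU-bound NumPy execution: full-resolution training is out of reach;
  training claims are limited to the smoke scale above.
* The calibrated group configuration is one member of the family consistent
  with the published budgets; other divisor choices reproduce the same
  table.
* Global SSIM is insensitive to local structure by construction; the
  windowed option exists for robustness studies but is not the documented
  filtering rule.
* The 0.1 MB size overhead is a fixed proxy for serialization framing, not
  a measured container cost.
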