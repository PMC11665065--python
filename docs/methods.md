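# Methods

## Problem and model

`dmfnet` segments individual cell nuclei in H&E-stained histopathology
patches as *instances*: each nucleus gets its own binary pixel mask rather
than a shared foreground class. The network is one-stage — no region
proposals, no pixel clustering — and combines three ideas:

1. **Deformable convolution.** A standard convolution samples a fixed grid
   R around each output position p0, `y(p0) = Σ_n w(p_n) x(p0 + p_n)`. The
   deformable variant adds a learned fractional displacement per sampling
   point, `y(p0) = Σ_n w(p_n) x(p0 + p_n + δp_n)`, evaluated through the
   separable bilinear kernel `G(p,q) = g(q_x,p_x) g(q_y,p_y)` with
   `g(a,b) = max(0, 1−|a−b|)`. Gradients flow to inputs, weights and
   offsets through the same kernel. The offsets come from a zero-initialised
   convolution over the same input, so training starts exactly at the
   standard-convolution behaviour. Nuclei are irregular ellipses; the
   adaptive sampling grid lets the receptive field follow their outlines.
2. **Balanced feature pyramid.** FPN levels {Q2..Q5} (strides 4..32) are
   rescaled to the stride-16 level (max-pooling downward, bilinear
   interpolation upward), averaged (`Q_int = (1/L) Σ_l Q_l`), refined with
   an embedded-Gaussian non-local block
   (`U_i = (1/C(v)) Σ_j f(v_i,v_j) g(v_j)` with softmax normalisation and a
   residual add), and redistributed additively to every level. Each level
   then carries the same aggregated semantic information.
3. **Location-based mask generation.** The image is divided into an S×S
   grid. A category branch scores each cell (S×S×C, sigmoid); a mask branch
   carries one channel per cell (H×W×S²), and cell (i,j) owns channel
   k = i·S + j. An instance whose mask centre of mass falls in a cell is
   predicted by that cell. The loss is `L = L_focal + γ·L_m` with
   `L_m = (1/N) Σ_k 1{cell k positive} L_dice`, N the number of positive
   cells. Decoding thresholds category scores, binarises the owned mask
   channels, rescales scores by mean foreground confidence (maskness), and
   finishes with greedy mask-IoU NMS.

## Numerical stack

No GPU framework is used: the package ships a compact float64 reverse-mode
autodiff engine over numpy (`dmfnet.nn`) providing exactly the primitives
the model needs (im2col convolution, max-pooling, bilinear resize, the
fractional-coordinate gather used by deformable sampling, batch norm
composition, SGD with momentum and L2 weight decay). Every non-trivial
primitive is verified against central finite differences in the test
suite, and the deformable convolution, the non-local operator and the mean
integration are additionally checked against literal scalar-loop reference
implementations (`dmfnet.reference`) that share no code with the
vectorised path.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| learning rate / weight decay / momentum | 0.0025 / 1e-4 / 0.9 | SGD protocol for full-scale training |
| batch size / epochs | 2 / 200 | with 352 training patches this is exactly 35,200 iterations (partial batches dropped) |
| γ (mask-loss weight) | 3.0 | balances dice term against focal term |
| focal α / γ_f | 0.25 / 2.0 | standard focal-loss shape |
| S (grid side) | 24 (full), 8 (desk) | cells per side; S² is the maximum instance count per image |
| score / mask-bin / NMS-IoU thresholds | 0.1 / 0.5 / 0.5 | decoding; at most 100 instances kept (matches the evaluator's AR cap) |
| FPN width | 256 (full), 16 (desk) | uniform channel count across pyramid levels |
| deformable stages | stages 3–5 | the 3×3 convolutions of these residual stages deform |
| fragment threshold | 10 px | clipped mask fragments below this are dropped at tile borders |

Backbone blocks are two-convolution residual blocks (counts (3,4,6,3) by
default); the stem is a 3×3 stride-2 convolution plus 2× max-pool, chosen
for the small-patch regime this package targets. All of these are config
knobs.

## Synthetic data: what it emulates and what it does not

The generator renders rotated ellipses with low-frequency radial Fourier
boundary perturbation in hematoxylin-purple tones over eosin-pink textured
background, with per-nucleus stain intensity, optional photometric
augmentation (brightness gain, contrast reduction toward the mean,
Gaussian/impulse/Poisson noise, each applied independently with
probability 0.3 by default), 1000×1000 scenes tiled into 250×250 patches,
and whole scenes assigned to train/val/test splits (22/2/6 of 30 scenes →
352/32/96 patches) so no scene straddles a split. Overlaps are resolved by
draw order, so the per-pixel instance labelling is exclusive, and every
scene is a pure function of (parameters, seed).

It does **not** emulate chromatin texture, nucleoli, stain bleed,
out-of-focus blur, organ-specific morphology, or annotation noise. Passing
tests therefore demonstrate that the architecture, losses, decoding and
evaluation are implemented correctly and that the network can learn the
task end to end — not that it reaches any particular accuracy on real
tissue.

## Evaluation protocol

Mask IoU replaces box IoU. Per image, score-ranked predictions are greedily
matched to the unmatched ground truth of highest IoU at or above the
threshold; matched → TP, unmatched predictions → FP, unmatched ground
truths → FN. Precision = TP/(TP+FP), recall = TP/(TP+FN). AP at a
threshold is the 101-point interpolated average precision
(`p_interp(r) = max_{r̃≥r} p(r̃)` averaged over r ∈ {0, 0.01, …, 1});
thresholds run 0.50:0.05:0.95 and mAP/mAR are the ten-threshold means. AR
uses at most the top-100 predictions per image; with a single category, AR
at a threshold equals the recall of that matching. P-R curves are the
interpolated-precision envelopes per threshold, exported as CSV and PNG.
Conventions: precision is 0 with no predictions; IoU of two empty masks
is 0. A second, structurally independent evaluator implementation is kept
in `dmfnet.reference` purely as a cross-check.

## Desk-scale run

CPU-scale experiments use the `desk` profile: 128×128 patches with ~8
nuclei (semi-axes 8–14 px), a thin backbone ((1,1,1,1) blocks, width 8,
FPN 16 channels), S = 8, learning rate 0.01, no photometric augmentation,
50 epochs over 16 training scenes at batch 2 (400 iterations, a few
minutes on one CPU). Under this profile training loss falls well below
half its initial value and held-out AP50 rises above the untrained
model's; the numbers are recomputed, never stored, by
`scripts/acceptance.py` and `tests/test_acceptance.py`.

## Known limitations

- Float64 numpy training is orders of magnitude slower than a GPU stack;
  the full 35,200-iteration protocol is supported but intended for
  patience, not routine use.
- Single-category decoding is the tested path; multi-class grids are
  plumbed through but not exercised beyond shape checks.
- One grid level is the reference configuration; per-FPN-level grids with
  scale-range assignment are not implemented.
- The greedy matcher implements the standard protocol's behaviour for
  non-crowd annotations only (no "ignore" regions).
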