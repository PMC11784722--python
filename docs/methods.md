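# Methods

## Problem setting

Razor clams (*Solen strictus*) live buried in intertidal mudflats; the only
surface evidence of a clam is its burrow opening — a dark ellipse a few
millimetres to centimetres across.  Counting and localizing burrows from
photographs is a small-object detection problem: most boxes occupy well
under 1% of the frame, against a textured, variably lit mud background.
The package implements a family of single-stage anchor-free detectors for
this task: a nano-scale baseline and an improved variant (here called
`imc_yolo`) that modifies the baseline in four places, each independently
switchable so the whole ablation grid can be built and measured.

## Architecture

All variants share the CSP-style backbone at nano multipliers (width 0.25,
depth 0.33), giving the channel ladder 16/32/64/128/256 over strides 2–32.
Convolutions carry no bias when followed by batch norm (eps 1e-3,
momentum 0.03); activations are SiLU unless noted.

**IAIFI tail** (`iaifi` flag).  The baseline ends its backbone in SPPF
(three chained 5×5 max-pools).  The improved tail first compresses the
stride-32 map 256→128 with a 1×1 CBS, then applies one post-norm
transformer encoder layer — 8-head self-attention with 2-D sinusoidal
positional encoding added to queries and keys (temperature 10 000,
interleaved sin/cos, the x- and y-encodings concatenated), a feed-forward
sublayer of width 64 — and finally fuses input and encoded output with
iAFF: two rounds of MS-CAM channel attention (reduction 4, local
per-position branch plus a globally pooled branch), each round producing a
convex combination `a·X + (1−a)·Y`.  The compressed 128-channel tail
propagates into the neck, which shrinks the model below the baseline
(2.95 M vs 3.01 M parameters).  The embedding sizes follow the published
per-variant parameter budget rather than the RT-DETR defaults; with
d_model 256 and a 1024-wide feed-forward the variant would *grow* by
~1.3 M parameters, contradicting the reported ablation sizes.

**Quad-scale ASFF head** (`refactored_head` flag).  The neck is extended
one octave up: the stride-8 path is upsampled once more, concatenated with
the backbone stride-4 feature, and closed by a C2f block; a symmetric
down path rebuilds strides 8/16/32 (yolov8-p2 topology).  Output channels
are 32/64/128/256 at strides 4/8/16/32.  At each output level the four
maps are resampled into that level's geometry — every contributor
(including the native map) through a 1×1 CBS; 2× finer maps through a 3×3
stride-2 CBS; ≥4× finer maps through a max-pool chain plus 1×1 CBS;
coarser maps through 1×1 CBS plus nearest upsampling — and combined with
per-position softmax weights α+β+γ+δ=1 predicted from 8-channel
compressed copies.  A 3×3 expand CBS follows the fusion.  The exact
wiring is under-determined by the source figures; the free choices were
fixed once against the published per-variant parameter counts and then
frozen.

**FasterNet blocks** (`fasternet` flag).  Every C2f inner bottleneck is
replaced by a FasterNet block: partial 3×3 convolution over the first
quarter of the channels (the rest pass through bit-identical), then a
pointwise MLP (expansion 2, conv–BN–ReLU–conv, bias-free) and a residual
sum.  The swap removes ~0.72 M parameters across the grid.

**TBCAM / TBAFN** (`tbcam` flag, requires `fasternet`).  TBCAM is a hybrid
attention applied inside each FasterNet block just before the residual
addition.  Channel stage: two per-channel descriptors (mean over H then
max over W; max over H then mean over W) pass a shared bottleneck MLP
(reduction 16, hidden floor 1); sigmoid of their sum gates the channels.
Spatial stage: three branches over permutations HW, CH, CW — each
computes max and mean over its leading dimension, concatenates them,
applies an unshared 7×7 conv (2→1) + BN + sigmoid, gates the permuted
tensor, and permutes back; the three outputs are averaged.

**Detection head.**  Decoupled anchor-free stems per level (regression
stem width 64, classification stem width = the finest level's channels),
distribution-focal box regression with reg_max 16 decoded as the bin
expectation times the stride, greedy per-class NMS.  Evaluation decode
uses conf 0.001 / NMS IoU 0.7; rendering uses 0.25 / 0.45.

### Parameter accounting

Trainable scalars only; the fixed DFL expectation kernel (16 values) is a
buffer.  The seven-variant table produced by `variant_table()`:

| variant | flags | params (10^6) |
|---|---|---|
| yolov8n | ---- | 3.01 |
| model1 | I--- | 2.95 |
| model2 | IH-- | 4.24 |
| model3 | IHF- | 3.52 |
| model4 | -HFT | 3.59 |
| model5 | I-FT | 2.25 |
| imc_yolo | IHFT | 3.53 |

## Training objective

The improvements are architectural, so the loss is the standard
anchor-free recipe: task-aligned assignment (top-10 anchors per box by
`score^0.5 · IoU^6`, candidates restricted to anchor points inside the
box, multiply-assigned anchors resolved by IoU, target scores normalized
per box to peak at its best IoU), BCE classification against those soft
targets, CIoU box loss, and distribution-focal loss on the two bins
flanking each true side distance; gains 7.5/0.5/1.5, all normalized by the
summed target scores.  Published run defaults: Adam, lr 0.001 decaying
linearly to 1% (the stated final-factor semantics; a cosine shape is a
one-line change), batch 16, 100 epochs, 640×640 inputs.

## Synthetic scenes

The field corpus behind the original study is not deposited, so the
generator stands in for it.  Each scene is procedurally textured mud
(coarse cell noise, cell size 16 px, plus per-pixel speckle over a
wet-sediment brown, with a global illumination multiplier) holding 5–15
dark soft-edged ellipses of 6–20 px semi-major axis at 640×640 — box
sizes chosen so that ≥70% of boxes fall below 1% of image area, matching
the reported small-object size profile.  Ellipses carry a faint rim
highlight; exact axis-aligned extents become the labels.  Everything is
deterministic under the scene seed.

What the generator does *not* emulate: tide-water reflections, partial
occlusion by debris, motion blur, perspective foreshortening, or the
label noise of manual annotation.  Tests passing on these scenes
demonstrate that the architecture, loss, and metric stack are wired
correctly and can fit real structure; they say nothing about accuracy on
real mudflats.

The augmentation protocol mirrors the described field pipeline: per
original, ±40% per-channel brightness (round half away from zero, clip),
whole-pixel salt-and-pepper corruption with probability 0.5 (the stated
"intensity 50%" is read as corruption probability and exposed as config),
and horizontal flip — a 5× expansion in which every derivative inherits
its source's train/val/test split (7:1.5:1.5 by largest-remainder
rounding), so augmentation can never leak across splits.

## Evaluation stack

Greedy score-descending one-to-one matching (ties by insertion order);
P = TP/(TP+FP), R = TP/(TP+FN) with P=1 under zero detections; AP as the
area under the monotone-envelope P-R curve, reported via 101-point
interpolation (the ecosystem convention) with an exact staircase integral
kept alongside as the test oracle; mAP50:95 over IoU 0.50:0.05:0.95;
F1best as the maximum of 2TP/(2TP+FP+FN) over the detection-score sweep
(ties to the lowest threshold).  Size strata read the 32/96 cut-offs as
side lengths (areas 32² and 96²) — the literal-area reading would label
nearly every burrow "large" — with a `px2` option preserving the literal
reading; detections overlapping out-of-stratum truth are ignored, and
empty strata report as missing rather than zero.

## Numerical engine

No GPU framework is used: `imcyolo.nn` is a reverse-mode autodiff engine
over float32 numpy arrays (im2col convolution, index-tracked max-pooling,
composed batch/layer norm, batched matmul attention, Adam).  Gradients
are verified against central differences in the test suite.  Numerical
guards: logits clipped to ±60 before sigmoid, stable log-sum-exp in the
focal decode, epsilon-guarded square roots and divisions; max-reduction
gradients split ties evenly.

## Desk-scale choices

Everything in the tests runs on one CPU core: forward checks and
trainability use 64×64 inputs (the architecture only requires
divisibility by 32), the smoke test takes 200 Adam steps (lr 0.008) on a
fixed batch of 8 scenes, and the overfit check continues on 16 scenes
(2–4 burrows of 5–10 px radius) until train-set mAP50 ≥ 0.8, reached in
well under 200 further steps.  Because class scores start at the
low-confidence prior bias, the loss briefly rises while confidence grows
before optimization pulls it down — short-horizon tests therefore compare
against the early peak, not step 0.

## Known limitations

- Eval-mode batch-norm statistics come from whatever batches were seen
  during the short runs; no EMA of weights is kept.
- The assigner is re-derived per step on detached values; no gradient
  flows through assignment (as in the reference recipe).
- The per-variant parameter table matches the published figures to
  ±0.01×10^6 on the two loosest rows (`model4`, `model5`) and exactly
  elsewhere; the composite model's published size is itself printed as
  3.50 in one table and 3.55 in another, so a ±0.05 band applies to it.
- Checkpoints are npz + JSON config, readable without any DL framework.
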