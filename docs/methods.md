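# Methods

## Problem and model

`kneemamba` segments five classes in knee MRI slices — background, femoral
bone (FB), tibial bone (TB), femoral cartilage (FC) and tibial cartilage
(TC) — with an encoder–decoder network whose encoder runs two parallel
branches over a shared stride-4 patch embedding:

* a **global branch** of visual state-space (VSS) stages.  Its core is the
  discrete linear state-space recurrence

      h_t = A h_{t-1} + B x_t,      y_t = C h_t + D x_t,      h_0 = 0,

  applied to the feature map flattened into token sequences.  Because a 1D
  scan sees only one traversal order, the 2D operator (SS2D) scans along
  four orders — row-major, reversed row-major, column-major, reversed
  column-major — with independent parameters per direction and merges the
  restored 2D maps by summation.  Each VSS block is pre-norm residual:
  LayerNorm → gated scan mixer (input projection to an expanded width, SiLU
  gate, output projection) → residual add → LayerNorm → feed-forward →
  residual add.  Patch merging (2×2 neighbourhood concat + linear
  reduction) halves resolution and doubles channels between the four
  stages, giving features at strides 4/8/16/32.

* a **local branch** (MPSK) of residual multi-scale blocks.  Each block
  reduces to a bottleneck width, runs parallel 1×1/3×3/5×5 convolutions,
  fuses them with selective-kernel (SK) attention — a per-channel softmax
  over the three branches computed from a global average-pooled descriptor
  passed through a squeeze/expand FC pair — enriches the result with a
  PSP-style pyramid pooling module (adaptive average pooling at levels
  1/2/3/6, per-level 1×1 convs, nearest upsampling, concatenation with the
  un-pooled map, 1×1 restoration), and expands back to the stage width.
  The block output is added to its input, so a zeroed expansion conv makes
  the block an exact identity.  Stride-2 1×1 projections double channels
  between stages so the four local maps mirror the global stages.

Per stage, the two branches are fused by channel concatenation (2C) and a
1×1 convolution back to C (BatchNorm + ReLU), forming the encoder pyramid
F1..F4.  The decoder mirrors the encoder (VSS blocks + patch expanding);
each skip passes the encoder map through **efficient channel attention**
(ECA: global average pool → 1D convolution across channels with an
adaptive odd kernel size k(C) = nearest odd integer to (log2 C + 1)/2, ties
downward → sigmoid weights in (0,1)) and fuses it with the decoder map by
element-wise **addition**, which forces decoder stage widths to equal
encoder widths.  A final 4× patch expansion and a linear head produce
5-class logits at input resolution; prediction is per-pixel argmax with
ties broken toward the lower class index.

### Numerical core

No GPU tensor framework is used: the package ships its own reverse-mode
autodiff engine on NumPy (`kneemamba.nn`), with analytic backward passes
for convolution (im2col), adaptive pooling, nearest upsampling, fused
normalisation and the state-space scan (the adjoint recurrence
λ_t = Cᵀ g_t + Aᵀ λ_{t+1}).  All backward passes are verified against
central finite differences, and the grouped (four-direction) scan against a
naive per-time-step loop.  Parameters are float32; the scan transition is
initialised near 0.5·I to keep long recurrences stable.

## Training protocol

The reference protocol is AdamW with β1 = 0.9 (the conventional reading of
"momentum" for Adam-family optimizers), β2 = 0.999, weight decay 0.01,
initial learning rate 1e-4, batch size 24, 100 epochs, on 2D slices, with
a compound loss: cross-entropy plus soft-Dice averaged over classes with
equal weight (λ = 1, configurable).  The Dice term counters the heavy
class imbalance (cartilage ≪ bone ≪ background).  Checkpoints keep the
best validation mean-DSC weights.

The CPU-scale **smoke protocol** used by the tests and the acceptance
script trains a reduced full model — embed width 32, one VSS block per
stage (encoder and decoder), state dim 8, expansion 1, MPSK widths
32/64/128/256 with one block per stage — for 200 steps at batch 8 and
learning rate 1e-3 on 32 single-slice 64×64 phantoms, evaluating on 8
held-out phantoms.  The higher learning rate is the standard choice for a
short schedule on a small model; 1e-4 is the full-scale default.  One such
run takes a few minutes on one CPU core and reaches mean foreground DSC
around 0.85–0.91 depending on the seed; the training loss falls to well
under half its first-step value.

## Synthetic phantoms

The generator emulates the structure of a sagittal knee MRI dataset: two
ellipse-like bone regions facing each other across a joint gap, thin
cartilage rims (default 2–3 px, configurable) grown from each bone's
boundary toward the gap, pose jitter between slices, per-class base
intensity levels (0.10 / 0.85 / 0.65 / 0.45 / 0.30 for background, FB, TB,
FC, TC), a smooth multiplicative bias field (±10%) and additive Gaussian
noise (sd 0.05), with declared voxel spacing (1.5 × 0.5 × 0.5 mm).  Every
cartilage voxel lies within a Chebyshev distance of the drawn rim
thickness from its parent bone, and each cartilage class stays below 5% of
voxels.  All randomness derives from the spec seed, so phantoms are
bit-reproducible, and a threshold segmenter at the level midpoints is
exact on noise-free phantoms — the sanity anchor for the metric stack.

What the phantoms do **not** emulate: real MR texture and partial-volume
effects, anatomy-dependent cartilage thinning, osteophytes, field
inhomogeneity beyond a smooth low-order field, and inter-scanner intensity
distribution shifts.  Passing the smoke criterion therefore demonstrates
that the architecture, loss, optimizer and evaluation stack are wired
correctly and can fit a strongly imbalanced 5-class problem — not that the
model reaches clinical-grade accuracy on real MRI.

## Evaluation and statistics

Per class, DSC = 2TP/(2TP+FP+FN); a class absent from both prediction and
reference scores 1.0 so that cohort aggregation stays total.  The
Hausdorff distance is the exact symmetric maximum (not the 95th
percentile), computed in physical mm between boundary voxel sets — a
labelled voxel is boundary if any face-adjacent voxel (or the image
border) has a different label — of 3D volumes assembled from slice
predictions; per-volume 3D was chosen over per-slice 2D so that mm values
are meaningful under anisotropic spacing.  An empty prediction for a
present structure is flagged and scored with the image bounding-box
diagonal (worst case), DSC 0.  Cohort summaries are mean ± sample SD per
tissue; model comparisons use the classic paired t-test on per-volume
scores with a 95% CI on the mean difference; zero-variance differences
raise an explicit degenerate-case error rather than fabricating a p-value.

## Preprocessing and splitting

CLAHE is applied per slice on intensities rescaled to [0,1] (scikit-image
convention, default clip limit 0.02, 8×8 tile grid), followed by per-volume
Z-score standardisation (population SD; constant volumes map to zeros).
Cohorts are split 7:2:1 into train/validation/test, stratified by
Kellgren–Lawrence grade with largest-remainder rounding per stratum
(deterministic given the seed; stable tie-break), and five stratified
cross-validation folds partition the training set via a rolling
round-robin.  Strata smaller than the fold count trigger a warning and a
best-effort assignment.

## Complexity calibration

The full-scale reference configurations target published complexity
budgets of 15.65 M trainable parameters for the plain state-space U-Net
and 22.67 M for the full model.  Two width knobs were calibrated once
against those budgets: the feed-forward ratio of the VSS blocks (1.7334,
with embed width 64, depths 2/2/2/2, state dim 16, expansion 2, decoder
depths 2/2/2/1) and the per-stage MPSK bottleneck widths (30/66/119/227).
The shipped configs land on 15,652,250 and 22,669,996 parameters —
15.65 M and 22.67 M at two decimals.  ECA contributes 14 parameters
(three 1D kernels plus biases), under 10⁻⁴ of the total.  FLOPs are a
best-effort analytic count (2 FLOPs per multiply-add over convolutions,
linear maps and scan recurrences; normalisations, activations and pooling
omitted) reported together with the input size used, 256×256 by default.

## Design choices made where the design was open

* The SK stage fuses **three** branch maps (sum of all three, 3-way
  softmax selection); the reduction hidden width is max(C/8, 32).
* "⊕" in the stage-fusion is concatenation followed by a learned 1×1
  mixing conv, not addition — the outer convolution makes concatenation
  the natural reading.
* The scan is the literal time-invariant recurrence above; an
  input-dependent ("selective") parameterisation is a known extension but
  is out of scope here — the time-invariant core is what all oracles and
  tests pin down.
* Inside MPSK blocks a pyramid level larger than the current spatial size
  is clamped to it (so deep stages keep all level convolutions active);
  the standalone pyramid-pooling operator raises instead, per its
  contract.
* Convolutions feeding BatchNorm carry no bias (a bias before BN is
  exactly zero-gradient); this keeps the "every parameter receives
  gradient" invariant meaningful.
* Skip fusion is addition as specified by the channel-attention design,
  applied on the three finer pyramid levels; the coarsest map starts the
  decoder.

## Known limitations

* CPU NumPy training limits practical problem sizes; the full 256×256
  reference configuration is exercised for construction, complexity
  accounting and single forward passes, not full training.
* Exact (maximum) Hausdorff is sensitive to single outlier voxels by
  construction; that is the printed definition, not HD95.
* The training-plane question (sagittal only vs all three) is left to the
  data layout: the pipeline trains on whatever slice axis the volumes
  provide, axis 0 by convention.
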