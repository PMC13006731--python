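# Methods

## Data model and residual computation

A study is a set of co-registered `(slice, row, col)` volumes: one
pre-contrast phase, 1–5 post-contrast phases, and a binary tumour mask.
Loaders refuse anything not already co-registered (shape or spacing
mismatch) instead of resampling silently; registration, bias-field
correction and DICOM parsing are out of scope, and NIfTI is the only
on-disk dialect.

Two conventions are deliberate choices rather than facts of the imaging
protocol:

- **Phase selection.** When several post-contrast phases exist, the residual
  is built from the *first* (earliest-enhancement) phase by default; washout
  dynamics differ across protocols and the early phase is where malignant
  enhancement is strongest. The index is configurable
  (`phase_index`/`phase_index_used`).
- **Normalisation.** Each phase is min–max scaled to [0, 1] per volume
  *before* subtraction, bounding the residual in [−1, 1] regardless of
  scanner intensity scale. A constant volume maps to zeros, making the
  residual of a degenerate study zero rather than undefined.

Slice batching cuts a volume into consecutive, non-overlapping windows of
B slices (default B = 4); a short final window is padded by replicating the
edge slice and the pad count is recorded so stitching drops exactly those
slices. A batch never mixes patients, because the inter-slice attention
interprets the batch axis as spatial adjacency.

## Synthetic phantom cohorts

The generator emulates the structure of a breast DCE study at a scale where
ground truth is exact and training takes minutes on one CPU:

- anatomy = `background_level` (default 0.4) + low-pass-filtered Gaussian
  texture (kernel width 3 voxels, amplitude 0.08) — a stand-in for
  parenchymal heterogeneity;
- a single ellipsoidal lesion; post-contrast = `pre · (1 + f)` inside it
  (enhancement factor f, default range 1.0–2.0 across a cohort) and
  `pre · (1 + f_bg)` elsewhere (mild background/parenchymal enhancement,
  0.05–0.15);
- independent additive Gaussian noise on pre and post (sd 0.01–0.03, so the
  residual noise variance is 2σ² — the simplest model consistent with
  independent acquisitions).

Cohorts draw per-patient geometry from stated ranges so tumour volume
varies; that volume is the stratification covariate for splitting.
Defaults for tests and the acceptance run use 10 patients of shape
(16, 32, 32): large enough that held-out evaluation is meaningful, small
enough to train in about a minute.

What the phantom does *not* model — pharmacokinetic (Tofts-type) uptake
curves, multifocal disease, coil/bias artifacts, motion, anatomy-dependent
enhancement — bounds what passing tests show: they validate the
implementation (shapes, gradients, attention algebra, training dynamics,
split hygiene), not clinical segmentation accuracy on real MRI. The
contrast step in the phantom is far cleaner than real enhancement, which is
why a small model reaches DSC > 0.9 here while real cohorts sit far lower.

## Architecture decisions

The architecture follows the module flow pre/post/residual → shared hybrid
encoder → per-stage multi-scale refinement → spatiotemporal graph
enhancement → decoder. Where the design was genuinely open, the choices
were:

- **Stage count and widths.** 4 stages at (32, 64, 128, 256) channels by
  default, stem at half the first width; the test configuration uses
  2 stages at (16, 32) on 32×32 slices so the suite runs on CPU. Width and
  depth are config fields, not constants.
- **Transformer placement.** Attention blocks sit only at the bottleneck,
  where the token count N = H′·W′ stays ≤ 256 and dense attention is
  tractable. Pre-norm layout, GELU MLP of ratio 4, learned additive
  positional embedding (toggleable) — standard vision-transformer
  conventions where the block diagram is silent.
- **Branch stacking.** The three branches are encoded as one stacked batch.
  With shared weights this is the identical computation for every spatial
  operator; for batch norm it makes training statistics *joint* across
  modalities, so the running estimates used in eval mode match what
  training normalised with. Encoding branches separately leaves the
  running statistics a modality average that matches none of the branches
  (the residual's distribution differs sharply from the phases'), which
  measurably degrades eval-mode segmentation.
- **MSR routing.** One refinement block per stage. Shallow-stage outputs
  become the decoder skips; the bottleneck output combines additively with
  the graph-enhancement output before decoding. The graph branch reads the
  *encoder* bottleneck features per modality (refinement fuses modalities,
  so its output cannot feed a per-modality graph).
- **Graph attention.** Fully connected graph over bottleneck positions,
  single layer, single head, C′ = C, LeakyReLU slope 0.2 and ELU output
  nonlinearity (graph-attention-literature conventions). The pairwise logit
  `aᵀ[Wh_i ‖ Wh_j]` is computed as an outer sum of two length-N
  projections — algebraically identical, O(N²) memory instead of O(N²·2C′).
- **Batch-slice recalibration layout.** The tensor is reshaped to
  (B·H, C, 1, W) rows — batch and height aggregated — gated by a 1×1
  convolution + sigmoid over the C channels, and restored. The layout is
  isolated in one function (`batch_slice_attention`) so it can be swapped.
- **Decoder.** Mirror-image U-Net: bilinear 2× upsampling (half-pixel
  alignment), skip concatenation, two conv blocks per stage, 1×1 logit
  head. Mask threshold 0.5 with ties to foreground.
- **Ablation variants.** `w/o CFE-L` replaces every 3×3 convolution with a
  1×1 channel projection but keeps pooling (the resolution schedule must
  survive); `w/o CFE-G` removes the transformer stack; `w/o MSR` replaces
  refinement with concat + 1×1 projection; `w/o STGE` bypasses the graph
  module entirely. Each variant has strictly fewer parameters than the full
  model and trains end-to-end.

## Objective and metrics

`L = L_Dice + λ·L_BCE + β·L_Boundary`, λ = 0.5, β = 0.2 (the optimum of a
{0.1, 0.2, 0.5, 1.0} grid; a grid runner is available through the config).
Numerical guards: Dice stabiliser ε = 10⁻⁶; BCE probabilities clamped to
[10⁻⁷, 1−10⁻⁷]. The boundary term compares Sobel responses of prediction
and target under L1, summed over both directional kernels (the kernels are
directional, so comparing per direction preserves orientation information
that a gradient-magnitude formulation would discard); images are
replicate-padded so the response keeps the input shape.

Metrics are DSC, Jaccard and RVD on binary masks. The empty-vs-empty pair
is defined as DSC = JI = 1 (perfect agreement; the ratio is otherwise 0/0),
and RVD requires a nonempty ground truth — studies with empty masks are
skipped with a warning during evaluation. RVD is the dimensionless ratio
(|P|−|G|)/|G|.

## Training protocol

Adam with lr 10⁻³, weight decay 10⁻⁴ (L2 folded into the gradient), batch
size 4, no data augmentation. The cohort protocol holds out 30% of patients
(stratified by tumour-volume half), then partitions the rest into k = 5
stratified folds; early stopping on fold-validation DSC with patience 10
selects the reported weights when validation studies are supplied. Epoch
count is a config field; the library default (20) and the sizes used by the
test suite and acceptance run (8 epochs on 10 phantoms; 300 steps for the
single-batch overfit) were chosen as the smallest runs whose outcomes are
stable across seeds.

Determinism: all randomness flows through explicit `numpy` generators
seeded from config fields; eval-mode forward is pure (no state mutation)
and repeatable bit-exactly on fixed hardware; identical seeds reproduce
phantom cohorts bit-identically and training histories exactly.

## Grad-CAM

The interpretability map targets the shared encoder's bottleneck activation
of the residual branch by default (the residual carries the enhancement
signal; any branch or residual-skip stage can be named). The scalar target
is the sum of logits inside the predicted mask — a segmentation adaptation
of the usual class score — with a fallback to all logits when the predicted
mask is empty. Channel weights are spatially averaged gradients; the
weighted activation sum is ReLU-rectified, bilinearly upsampled to input
size and min–max normalised per item (all-zero maps stay zero).

## Known limitations

- At phantom scale the structural ablation study does not reproduce the
  ordering expected on real cohorts: the synthetic task is easy enough that
  smaller variants (fewer parameters, no transformer) converge faster and
  can out-score the full model within a few epochs. The ablation runner is
  therefore validated for its contract (identical seeds and data across
  variants, parameter accounting, reproducibility), not for variant
  ranking.
- The phantom's contrast model is multiplicative and instantaneous; no
  kinetic curves, so nothing here validates temporal-sampling robustness.
- Attention and graph modules run dense; inputs whose bottleneck exceeds a
  few hundred positions will be slow on CPU.
- The compute backend implements exactly the operators this model needs;
  it is not a general-purpose training framework (no GPU, no mixed
  precision, no 3D convolution).
- A fixed input size is baked into a built model (the positional embedding
  length and batch-norm shapes); predicting a different geometry requires
  rebuilding with a matching config.
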