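# Methods

## Problem

Abdominal MRI examinations acquire many series: unenhanced sequences (T1, T2,
DWI, MRCP) and dynamic contrast-enhanced (DCE) phases (pre-contrast, early and
late arterial, portal-venous, delayed). Downstream tooling — automated
reporting, multi-sequence diagnosis models, dataset curation — needs reliable
series labels, and DICOM headers are often wrong or missing for DCE timing.
Recognizing the sequence from the voxels is a fine-grained problem: adjacent
DCE phases differ only in subtle, localized vascular enhancement, while
volumes of the same phase differ enormously across patients (body habitus,
base signal level, pose, scanner settings).

## Model

The classifier has three parts.

**Frozen 3D CNN backbone.** A residual 3D CNN (ResNet18-style basic blocks)
maps a volume to a coarse feature grid. Its weights are He-initialized and
frozen: the backbone is a fixed feature extractor, never updated by training.
Because no gradient ever flows through it, it is implemented as plain forward
numpy computation (im2col + GEMM, float32). The default reduced
configuration (stem stride 2, three stages with strides 2/2/1, channels
16/32/64) maps a 16 x 32 x 32 crop to a 64-channel 2 x 4 x 4 grid; the full
four-stage ResNet18 layout is available in config for larger inputs.

**Transformer encoder with token selection.** Each grid position becomes a
token (linear projection to width d, learned positional embedding, learned
CLS token prepended). N pre-norm encoder layers (multi-head self-attention
and MLP, both in residual branches) process the full sequence while the
row-stochastic attention matrices of every head are recorded. Deep-layer
attention no longer tells which *input* token the CLS embedding depends on,
because every layer re-mixes tokens; the feature-selection step therefore
fuses attention across depth by per-head cumulative matrix multiplication,

    A_final^i = A_N^i · A_{N-1}^i · ... · A_1^i ,

and reads row 0 (the CLS query row) of each fused matrix as the effective
CLS-to-token weights. For each of the K heads, the single most-attended token
(CLS excluded; ties to the smallest index; duplicates across heads allowed)
is selected from the layer-N hidden states, and the final (N+1-th) encoder
layer runs on the short sequence [CLS; K selected tokens]. A final LayerNorm
yields the volume representation. The fused attention matrices are products
of row-stochastic matrices and hence row-stochastic themselves; this is
checked to 1e-5 at runtime in tests.

**Prototype classification.** After pretraining, the CLS features of all
training volumes are extracted, per-class feature centers (arithmetic means)
are computed, and each class stores the G = 2 training features closest to
its center in cosine distance — verbatim copies, not averages. A query is
assigned the class whose nearest prototype minimizes

    DIS_i = min_j [ 1 - cos(CLS, p_{i,j}) ] ,

ties broken toward the smaller class index. Distances live in [0, 2].

## Training protocol

Two stages, both with AdamW and a cosine learning-rate schedule with linear
warmup; the backbone stays frozen throughout (asserted byte-identical in
tests).

1. **Pretraining.** An FC + softmax head on the CLS embedding is trained
   with cross-entropy.
2. **Prototype stage.** The pool is built once from the pretrained features
   and then held fixed (an optional refresh interval can rebuild it). The
   loss is

       L = α · min_j d(CLS, p_{q,j})  −  β · mean_{i≠q} min_j d(CLS, p_{i,j})  +  CE ,

   with α = 1 and β = 0.05. The pull term draws a sample toward its own
   class's nearest prototype; the push term (non-target classes, each
   represented by its nearest prototype, averaged) separates classes. The
   push term's target is ambiguous in its source formulation (the prose
   argues different-class separation while the formula line reuses the
   same-class prototype); this package implements the different-class
   reading, which is the one consistent with the stated intent.

**CE term in the prototype stage.** Two readings are possible once the FC
head is nominally replaced by the prototype module: cross-entropy over the
FC head's logits, or over distance-based logits softmax(−DIS_i / τ). Both are
implemented (`TrainConfig.proto_ce = "fc" | "distance"`). The default is
`"fc"`: on the shipped hard configuration the distance-CE variant measurably
degraded test accuracy (~0.64 vs ~0.72 mean over seeds) because, at the small
scale this package targets, the pull term distorts features faster than the
weak distance-gradient can compensate, while the FC head keeps supplying a
strong discriminative signal. Evaluation always classifies by prototypes in
`fsm_pcm` mode regardless of this choice.

## Ablation configurations

- `base` — all N+1 encoder layers on the full token sequence, FC-head
  classification (token selection provably never runs; an instrumentation
  counter asserts this).
- `fsm` — token selection active, FC-head classification.
- `fsm_pcm` — token selection plus prototype classification with the
  two-stage protocol.

For module-ablation comparisons, `ablation_train_config` gives the prototype
stage the same epoch budget as pretraining (26 + 26): in the source protocol
the prototype stage is full training, and at desk scale a short stage cannot
reshape the embedding for the cosine metric enough for the module's
contribution to be measurable. The short default (26 + 8) is for quick
pipeline validation, where the easy dataset saturates either way.

## Synthetic data

Real fine-grained sequence data cannot ship with the package, so a generator
reproduces its statistical structure: per patient, a smooth ellipsoidal
"anatomy" with patient-specific scale (uniform in `body_scale_range`) and
base intensity (Gaussian, `intensity_shift_sd`), plus mild fixed texture;
per class, a small bright Gaussian cue (truncated at 2.5σ, under 5% of
voxels) planted at an anatomy-relative site so patient nuisance moves it;
additive Gaussian voxel noise. Cue sites lie on the mirror plane of the
lateral flip augmentation — otherwise mirror-symmetric site pairs would make
two classes indistinguishable under training-time flips. Three cue codes are
available: `blob-position` (site encodes the class), `blob-presence`
(bit-pattern of sites), `tube-intensity` (amplitude of a vessel-like tube).

Presets:

- `easy` — cue contrast 0.9, intensity shift sd 0.05, scale 0.95–1.05,
  noise sd 0.03. Classes are separable from raw voxels (a nearest-centroid
  baseline exceeds 90%), so an end-to-end run validates the whole pipeline
  rather than the model's limits.
- `hard` — cue contrast 0.45, intensity shift sd 0.25, scale 0.85–1.2,
  noise sd 0.05. Patient-level intensity variance (0.0625) exceeds the
  between-class cue amplitude variance (≤ 0.0506), the fine-grained regime:
  intra-class nuisance dominates the class signal, but the cue remains
  learnable within the desk-scale training budget. A first design with a
  weaker cue put the tiny network at chance, where module comparisons are
  meaningless; the preset was set once to the learnable regime and frozen.

What the generator does **not** emulate: MR physics (relaxometry, k-space
artifacts), anatomical variability beyond affine scale, multi-organ content,
class imbalance, scanner/site effects. Passing tests on synthetic volumes
demonstrate that the architecture, losses and protocol behave as specified —
not clinical performance on real MRI.

## Scale and defaults

All defaults are desk-scale so that the full test suite and the acceptance
script run on one CPU: volumes 16 x 32 x 32 (the full-scale crop contract,
48 x 256 x 256, is a config value), encoder N = 2 pre-selection layers, K = 4
heads, width 64, MLP ratio 2; pretraining 26 epochs (warmup 2) at peak LR
3e-3, batch 8; prototype stage 8 epochs at LR 1e-3; weight decay 0.01;
augmentation scale 0.8–1.25 with probability 0.75, lateral flip probability
0.5. Dataset presets use 4 classes, 10 patients, 5 volumes per patient and
class (200 volumes; a 4:1 patient-grouped split gives 160 train / 40 test).
G = 2 prototypes per class, α = 1, β = 0.05 follow the source settings.

## Numerical choices

- Trainable computation is float64 (robust gradient checks); the frozen
  backbone runs in float32.
- Volumes are min-max normalized to [0, 1] per volume before the network,
  which removes most of the global intensity nuisance a scanner would add.
- Cropping: uniform random offset during training, center crop at
  evaluation; volumes smaller than the crop are zero-padded symmetrically.
- Cosine distance clips the similarity into [-1, 1] before 1 − cos; zero
  vectors are rejected, not silently normalized.
- Argmax/argmin ties (token selection, classification, prototype ranking)
  always resolve to the smallest index, making every pipeline stage
  deterministic; training is exactly reproducible for a fixed seed because
  all randomness flows through explicitly seeded generators and numpy
  kernels are deterministic.
- The minimum over prototypes uses the standard subgradient (gradient flows
  to the argmin prototype distance only).

## Folds

Cross-validation folds are grouped by patient: a patient's volumes never
appear on both sides of a split, since same-patient volumes share anatomy
and pose cues that would leak. Patients are dealt round-robin to folds after
grouping by dominant class and shuffling within groups — fold patient counts
differ by at most one, and single-class patients are class-stratified.

## Known limitations

- The frozen backbone is randomly initialized by default (reproducible
  without external weights); a pretrained checkpoint can be loaded, and
  results on real data would likely require one.
- At this scale the prototype stage yields small, seed-dependent effects;
  the shipped ablation checks the direction of the module contributions,
  not their published magnitudes.
- Attention heatmap export is a qualitative aid (fused CLS attention
  upsampled to volume shape), not a validated localization method.
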