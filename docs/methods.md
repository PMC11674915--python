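# Methods

## The model

`amdnet` implements a compact convolutional classifier for retinal OCT
B-scans (three diagnostic classes: dry AMD, normal, wet AMD).  The network
chains four components:

1. **Stem** — Conv 5×5/32 → depthwise 3×3 → pointwise 1×1/32 → BatchNorm →
   3×3 max pool (stride 2).  This is the only spatial downsampling outside
   the ConvMixer patch embedding, taking 224×224×3 to 112×112×32.
2. **Modified Inception module (MIM)** — four parallel branches on the stem
   output: 1×1/64; depthwise 3×3 → pointwise 1×1/64; depthwise 5×5 →
   pointwise 1×1/64; 3×3 max pool → 1×1/64.  Outputs concatenate to 256
   channels.  Replacing the 3×3 and 5×5 standard convolutions of the classic
   Inception layout with depthwise separable pairs cuts the module from
   15,488 to 1,132 parameters on a 3-channel input (a ≥13× reduction), which
   the analytic auditor reproduces row for row.
3. **Post-Inception convolution + DSEB** — a 3×3/128 convolution followed by
   the depthwise squeeze-and-excitation block: depthwise 5×5 → pointwise
   1×1/64 → depthwise 3×3 → pointwise 1×1/64 → SE channel attention
   (global average pool → dense C→C/r → dense C/r→C with a logistic gate →
   channel-wise rescale).
4. **ConvMixer stage** — patch embedding (kernel = stride = patch size p=2,
   h=256 filters, GELU, BatchNorm) followed by d=16 blocks, each a residual
   depthwise 5×5 mixer and a pointwise channel mixer, both with GELU and
   BatchNorm; every block preserves the (n/p, n/p, h) grid.  Global average
   pooling and a softmax head close the model.

### Parameter accounting

Everything is built from a declarative spec tree (`specs.ConvSpec`,
`specs.BlockSpec`), so parameter totals exist in three independent forms:
the closed-form audit (`param_count` summed over the tree), the per-layer
audit of a compiled model (array sizes row by row), and the framework count
(`count_trainable`).  The test suite asserts three-way agreement for every
block, all seven ablation variants, and the full model.  Conventions:
biases on all conv/dense layers; BatchNorm contributes 2 scalars per channel
(scale and shift — moving statistics are not trainable); max pooling and GAP
contribute none.

### Reconciling under-determined hyperparameters

The architecture description leaves the SE reduction ratio, the widths of the
fully connected head, and secondary BatchNorm placement open, while the
published trainable-parameter total is 1,650,020.  `reconcile_config`
enumerates a small documented space — SE ratio ∈ {2, 4, 8, 16}, head hidden
widths ∈ {[], [128], [256], [512]}, biases on, post-Inception BatchNorm
on/off — and reports every configuration matching a target count, or the
nearest miss.  Under this space the defaults give 1,568,103 and no
combination reaches 1,650,020; the closest is 1,637,763 (SE ratio 2, one
256-unit hidden layer, post-Inception BatchNorm), a −12,257 shortfall.
Solving for a fractional head width shows no integer width closes the gap at
any SE ratio, and adding the non-trainable BatchNorm statistics (16,960
scalars) to the closest trainable counts still misses by several hundred.
The committed report is `configs/reconciliation.json`; the shipped default
config keeps the literal architecture text (SE ratio 16, no hidden layer)
rather than silently absorbing the discrepancy.

## Evaluation metrics

Accuracy is trace over grand total of the confusion matrix.  Precision and
recall are computed one-vs-rest per class and macro-averaged without class
weights; F1 is the harmonic mean **of the macro averages**, not the mean of
per-class F1.  On the reference clinical confusion matrix
(98/1/5, 0/133/0, 1/0/109) this convention yields 97.98 / 97.95 / 97.77 /
97.86 percent after half-up rounding to two decimals, whereas
mean-of-per-class-F1 gives 97.83 — the tests pin the implemented convention.
A class never predicted gets precision 0, a class with zero support gets
recall 0, both with warnings.

## Data handling

`split_sizes` uses floor for the 70% training fraction, half-up rounding for
the 15% test fraction, and gives the remainder to validation — the unique
simple rule consistent with both published partitions (2316 → 1621/348/347
and 4326 → 649 test).  Splits are image-level, unstratified, and a pure
function of the shuffle seed.  Patient-level grouping is not modelled; with
clinical data this split can leak a patient across partitions, which is a
known limitation of the emulated protocol.

## The synthetic B-scan generator

Real OCT data for this problem is clinical and not redistributable, so the
package generates grayscale B-scans that caricature the three classes:

* a shared per-index anatomy — six smooth, gently tilted/bowed horizontal
  bands (brightest at the RPE position) over a dark background;
* **dry AMD**: five drusen-like bumps (Gaussian deformations of the RPE band,
  default amplitude 12 px) with hyper-reflective material beneath;
* **wet AMD**: one dark sub-RPE fluid pocket (default radius 28 px) with a
  dome-shaped elevation of the overlying bands;
* multiplicative log-normal speckle (σ = 0.15), 8-bit grayscale replicated to
  three channels at 224×224.

Setting an effect size to zero removes that class's signal entirely, and the
classes become pixel-identical when all pathology and noise are off — a
tested invariant.  Defaults are 32 images per class: enough for a meaningful
70/15/15 split (67/15/14) while keeping full training runs desk-scale.  The
generator emulates class *morphology*, not the statistics of real OCT
(speckle correlation, vessel shadows, device artefacts, patient-level
correlation between scans); passing the end-to-end test shows the assembled
architecture can learn separable retinal-band features, not that it attains
clinical accuracy.

## Training protocol

Adam (initial learning rate 1e-3 — conventional default, the protocol leaves
it open), categorical cross-entropy, no data augmentation, ReduceLROnPlateau
on validation loss (factor 0.3, floor 1e-6, patience 5 epochs — patience is
ours), and retention of the epoch with the best validation accuracy (ties to
the earliest).  Checkpoints capture BatchNorm running statistics alongside
the trainable weights; restoring weights against statistics accumulated in
later epochs does not reproduce the checkpointed model's validation accuracy,
and an early version of the trainer had exactly that defect.  Batch order is
a pure function of (seed, epoch), making histories bit-reproducible.

The end-to-end check trains a reduced model (ConvMixer depth 2, hidden dim
64; every other hyperparameter at its default) for 10 epochs at batch size
16 on the default synthetic dataset.  Batch size follows the data scale: the
67-image training split supports several optimizer steps per epoch at batch
16, where the published batch of 128 would collapse each epoch into a single
step.  Pixel values are scaled to [0, 1] with no further standardization.

## Numerical runtime

No deep-learning framework ships in the package's dependency set; the
executable model is a self-contained NumPy engine (`engine.py`) whose layers
implement explicit forward/backward passes, validated against central
differences in float64.  Standard and pointwise convolutions run as batched
BLAS matrix products (pointwise directly on the activation tensor; spatial
kernels through a chunked im2col buffer capped at ~256 MB per chunk, cached
between forward and backward).  Depthwise convolutions use JIT-compiled
per-channel kernels; the input gradient is the same-padded correlation with
the flipped kernel.  Max-pool gradients route to the first position
attaining the window maximum.  BatchNorm uses per-batch statistics in
training (ε = 1e-5, running-stat momentum 0.9) and running statistics at
evaluation; its batch statistics are accumulated in float64.  The softmax
output layer participates in training through the fused cross-entropy
gradient (p − onehot)/N.  The engine raises glibc's mmap threshold at import
so large per-layer temporaries are recycled through the malloc arena instead
of being returned to the kernel between passes.

Argmax ties (degenerate probability vectors) resolve to the lowest class
index.

## Known limitations

* The reconciliation gap above means the package cannot certify the published
  1,650,020 figure from the stated architecture; the committed nearest-miss
  report documents the discrepancy.
* Synthetic data bounds what the end-to-end tests demonstrate (see above);
  published real-data accuracies are out of desk scale and not reproduced.
* The runtime is CPU-oriented and single-threaded; it is built for
  auditability and desk-scale experiments, not for training at clinical
  dataset sizes.
* Only 2-D B-scans are supported; no volumetric OCT, no DICOM/E2E containers.
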