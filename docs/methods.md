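# Methods

## Model

The classifier is a densely connected convolutional network whose repeating
unit — here called an ARDT block — couples a dense block and a transition
block with a parameter-free spatial attention-residual module.

**Pre-activation ordering.** Every convolution in dense and transition blocks
is preceded by batch normalization and ReLU (BN → ReLU → conv). Internal
convolutions carry no bias (the BN shift subsumes it); the fully connected
head does. Batch-norm scale and shift are counted as parameters; running
statistics are not.

**Dense layers.** Each of the `layers_per_block` (default 12) layers is a
bottleneck: a 1×1 convolution to `4k` channels followed by a padded 3×3
convolution to `k` channels (growth rate `k`, default 12), concatenated onto
the layer input. A block therefore maps `C → C + layers_per_block·k`
channels at unchanged spatial size.

**Transitions and the residual shortcut.** The transition projects back to
the *block input* channel count with a 1×1 convolution and halves the side
with 2×2 average pooling. Because input and output of the whole
dense+transition path then agree in channels, and a 2×2 average pooling of
the block input agrees in spatial size, an additive shortcut exists at the
block level. That is the granularity adopted here: one attention-residual
module per block, spanning dense + transition. A residual joined immediately
after the dense block alone would be shape-inconsistent (the concatenation
grows channels), so no such second shortcut is attempted.

**Attention-residual combine.** With `F` the transition output and `G` the
pooled shortcut, the mask is a per-channel spatial softmax of `F`
(exponents stabilized by subtracting the per-channel maximum), `W = mask ⊙ G`
element-wise, and the block output is `F + G + b·W`. The Hadamard product is
used (mask and `G` share shape and the mask has per-position attention
semantics; a true matrix product would need an arbitrary flattening). With
`b` fixed (default 0.001) the module contributes zero trainable parameters —
a property the test suite asserts by comparing full-model parameter counts
with the module on and off. A config flag makes `b` a trainable scalar (one
parameter per block). The final block has no transition — its 7×7 resolution
is already the classifier's working size — so no shape-compatible shortcut
exists and the module is bypassed there.

**Stem and head.** A 3×3 convolution with stride 2 to `4k` channels, then a
2×2 average pool, precede the blocks; stride 2 is required for the intended
spatial flow 224 → 112 → 56 → 28 → 14 → 7 → 1. After the last block a final
BN → ReLU precedes global average pooling and the 2-way softmax head; without
it the last dense block's output would reach the head un-normalized, and the
final normalization is standard practice in pre-activation dense networks.

**Implementation.** All layers are explicit NumPy (float32, NCHW):
convolution by im2col + matmul with a hand-derived adjoint for the backward
pass, standard batch-norm gradients, and the softmax Jacobian for the
attention combine (`dF = dout + m⊙(u − Σ u⊙m)` with `u = b·dout⊙G`,
per channel over spatial positions). Gradients were verified against central
finite differences across every layer type. Weights use He (fan-in)
normal initialization from a seeded generator, so model construction is
reproducible bit for bit.

## Parameter accounting

A declarative `LayerSpec` list is assembled from the same configuration as
the numeric network; closed-form counts (conv: `kh·kw·Cin·Cout (+Cout)`;
FC: `in·out (+out)`; BN: `2C`; pooling/activation: 0) are summed and checked
against the numeric arrays' sizes. A 16-weight-layer VGG spec (13 3×3
convolutions, 3 fully connected layers, biases, no BN) serves as the size
reference; its total is 138,357,544 ≈ 138 M. The default dense model totals
0.56 M. Published totals of 21.2/20.3 × 10⁶ for nominally similar 100-layer
dense networks are not reproducible from any self-consistent reading of the
architecture used here (they would require a different, internally
inconsistent transition-kernel size) and are not targeted.

## Data pipeline

**Manifest dialect.** CSV rows of `ISIC_<image_id>, task1[, task2]` with an
optional header. The default polarity stores 0 = melanoma in column two
(and 0 = seborrheic keratosis in column three); labels are flipped on read so
that in-memory labels are always 1 = positive class. A `standard` polarity
reads columns as already positive-coded, since public releases of the ISIC
ground truth use the opposite encoding; which the original experiments truly
used is ambiguous, hence the flag.

**Oversampling.** Each minority class is replicated `floor(max/n)` whole
times and topped up by seeded sampling without replacement, so every original
is retained, per-class counts all equal the majority count, and the set of
distinct source images per class is unchanged. Duplicated records keep a
`source_id` and get de-duplicated ids.

**Patches.** "Scale `s` of the original image" is realized as square crops of
side `round(s · min(H, W))` — this keeps every crop square and inside the
frame for any aspect ratio. Crop placement is uniform over positions whose
crop covers the image center pixel (random placement "from the center");
this jitter is also what "random cropping" denotes in the augmentation list,
so no second cropping stage exists. Crops are resized by corner-aligned
bilinear interpolation (output pixel `u` samples input coordinate
`u·(in−1)/(out−1)`; corners exact). Remaining augmentation is rigid —
horizontal flip, vertical flip, rotation by a multiple of 90°, each with
probability 1/2 — restricted to multiples of 90° to avoid interpolation and
boundary-fill artifacts; the pixel multiset is exactly preserved.

**Test-time scoring.** An image's score is the mean positive-class softmax
probability over its 60-patch set. Averaging over the full set (rather than a
single patch) is the lower-variance reading of the patch-scoring protocol.
SE/SP/ACC use a 0.5 decision threshold, ties classified positive. AUC is the
trapezoidal area under the empirical ROC over all thresholds (equal to the
Mann–Whitney pair-counting statistic, which the tests assert); AP is the area
under the precision–recall step curve. Metrics with empty denominators are
reported as undefined, never as 0.

## Synthetic data generator

The generator emulates the decision-relevant structure of dermoscopy images,
not their photometry: a skin-toned background (base tone plus smoothed
Gaussian noise), one elliptical lesion whose boundary radius is modulated by
seeded harmonics of order 2–7, class-dependent boundary amplitude (0–0.05 for
the smooth class, 0.25–0.40 for the irregular class — deliberately disjoint
ranges so a learnable signal exists by construction), and class-dependent
pigmentation (one uniform pigment vs. 3–5 blobs from a melanin-like palette).
The task-2 label is driven by an independent attribute, internal texture
variance, mirroring a dataset with two distinct binary labellings. The
default 448-pixel side keeps all four patch scales ≥ ~90 pixels before
resizing. Everything derives from one seed via `SeedSequence`, so datasets
are byte-reproducible.

What passing tests on this data do **not** show: robustness to hair and ruler
artifacts, color-constancy variation, off-center or cropped lesions,
class-imbalanced photometry, or any real-image statistics. The generator
exists to verify the pipeline's mechanics and that the architecture can learn
boundary/variegation cues at all, not to predict benchmark performance.

## Desk-scale training configuration

The learning sanity check uses a reduced architecture (k = 6, 6 layers per
block, 2 blocks, 64×64 inputs; ~31 k parameters) trained on 120 synthetic
images (one 4/5-scale center patch each, no augmentation) for 30 epochs with
SGD momentum 0.9, initial learning rate 0.1 halved every 10 epochs, batch 10.
The full-scale schedule (1e-4 over 100 epochs) is tuned to a much larger
model and dataset; at this scale a larger rate with a faster-decaying
schedule is the appropriate analogue. Under these conditions the model
reaches ≥ 0.95 training accuracy within 30 epochs and ~0.83–0.85 held-out
accuracy (AUC ~0.9) averaged over 3 seeds, which the acceptance script
recomputes end to end in about two minutes on one CPU.

## Numerical choices and edge cases

- Probabilities are clamped to (1e-7, 1 − 1e-7) before logarithms in the
  weighted binary cross-entropy (whose per-sample weight is realized as a
  per-class weight, defaulting to 1 since oversampling already balances
  classes).
- Spatial softmax subtracts the per-channel maximum before exponentiation;
  non-finite inputs are rejected.
- Average pooling requires even spatial sides (a shape error otherwise);
  the architecture validator requires the input side to be divisible by the
  total downsampling factor so every pooling stage is exact.
- Checkpoints are single `.npz` files holding the configuration and every
  parameter and running-statistics array; round-trips are bit-exact.
- Training aborts with a diagnostic if the loss becomes non-finite.

## Known limitations

- CPU-only NumPy execution: the full 224-input, four-block configuration
  forward/backward is functional but slow; the package is intended for
  architectural study and desk-scale experiments, not benchmark training.
- Determinism is guaranteed for model construction, data generation and the
  patch pipeline; training is deterministic up to the floating-point
  reduction order of the underlying BLAS.
- No artifact removal (hair, rulers), color constancy or segmentation-guided
  cropping; multi-class (> 2) heads are supported by configuration but the
  loss and metrics target the two binary tasks.
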