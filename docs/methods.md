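# Methods

## Model

The segmentation network is a five-level encoder–decoder over 2-D axial
slices. The encoder stacks MA blocks (conv 3×3 → batch norm → ReLU →
conv 3×3) at filter counts (32, 64, 128, 256, 512) with 2×2 max pooling
after levels 1–4, so the bottleneck sits at 1/16 of the input
resolution; inputs must therefore be divisible by 16. The bottleneck is
an FCN block: three chained convolution branches with ReLU, tanh and
sigmoid activations whose outputs are concatenated channel-wise (3×
width) and merged by a ReLU convolution. Each decoder level upsamples
with a 2×2/stride-2 transpose convolution, gates the encoder skip with
an additive attention block (1×1 theta/phi convolutions, ReLU, 1×1 mask
convolution, sigmoid), concatenates the gated skip with the upsampled
features and applies an MA block. A 1×1 convolution and per-pixel
softmax produce class probabilities.

All convolutions in MA/FCN blocks are 3×3 with "same" padding and
stride 1; attention convolutions are 1×1. The convolution primitive
obeys the spatial contract v = n + 2p − f + 1 at stride 1.

Design points that were genuinely open, and how they were resolved:

- **FCN branch wiring.** The block's equations chain the branches
  (tanh branch reads the ReLU branch's output, sigmoid reads tanh's)
  while an alternative reading has all three branches in parallel from
  the block input. The sequential form is the default; a
  `parallel=True` switch builds the other wiring. The third branch uses
  sigmoid.
- **Attention multiplication target.** The sigmoid mask multiplies the
  theta-transformed skip `T` (default), with a `gate_raw_skip` switch
  to multiply the untransformed skip instead.
- **Batch normalization affine.** The bare normalization
  (Y − μ)/√(σ² + ε) would freeze every channel at unit scale, so a
  learned per-channel scale and shift follow it, as in standard batch
  norm. ε = 10⁻³. Running statistics use exponential moving averages
  with momentum 0.9 — faster to converge at desk-scale step counts than
  the common 0.99, so inference-mode predictions track training within
  a few dozen updates.
- **Head initialization.** The final 1×1 classifier's weights are
  scaled by 0.1 at initialization so the untrained network predicts
  near-uniform class probabilities (initial cross-entropy ≈ ln K); this
  keeps early training stable and the initial loss interpretable.
- **Other silent choices.** Transpose convolutions use 2×2 kernels at
  stride 2; attention inter-channels equal the level's filter count
  with a single-channel mask; weights use variance-scaling (He) uniform
  initialization from the config seed; Adam runs with β₁ = 0.9,
  β₂ = 0.999.

The whole network, including batch norm, pooling, transpose
convolutions and the attention gates, has hand-written backward passes
in numpy (im2col convolution). The backward pass is verified against
central finite differences in a dedicated gradient-flow test; training
is bitwise-reproducible for a fixed seed because all randomness flows
through one seeded generator and execution is single-threaded.

## Losses and metrics

Categorical cross-entropy (mean over pixels of −Σ t·log(p + s),
s = 10⁻⁶) is the training loss. Tversky, focal and boundary losses are
named monitoring metrics whose exact formulations were not fixed by
the roster they appear in; the standard literature definitions are used
and should be read as reconstructions:

- Tversky: 1 − (TP̃ + s)/(TP̃ + α·FP̃ + β·FÑ + s) with soft per-class
  counts, α = 0.7, β = 0.3 (α = β = 0.5 reduces exactly to soft-Dice
  loss).
- Focal: mean of −α(1 − p_t)^γ log(p_t + s) with γ = 2, α = 0.25
  (γ = 0, α = 1 recovers cross-entropy).
- Boundary: mean over foreground classes of Σ pred_c ⊙ φ_c / N, where
  φ_c is the signed Euclidean distance map of the true class region
  (negative inside, computed with scipy's distance transform). The
  value is signed by construction; classes with empty truth contribute
  zero.

Evaluation metrics come in two equivalent routes, tested against each
other: confusion counts (accuracy, precision, recall) and region sets
(sensitivity |C1∩G1|/|G1|, specificity |C0∩G0|/|G0|, Dice
2|C∩D|/(|C|+|D|)). Composite regions follow the BraTS conventions:
WT = {1,2,3}, TC = {1,3}, ET = {3} on mapped labels. Conventions for
degenerate inputs are explicit and tested: Dice of two empty sets is
1.0; any rate with a zero denominator returns 0.0 with a warning.
Multi-class accuracy is overall pixel accuracy; per-class metrics use
one-vs-rest binarization, and sensitivity is reported both at the
whole-tumor level and as a per-class average since either reading is
defensible.

## FLOP and memory accounting

One convolution costs 2·K·Cin·Cout·Hout·Wout FLOPs (K = kernel
footprint; a multiply-accumulate counts as two operations). A
layer-level variant that counts kernels instead of kernel×input-channel
products (2·Cout·K·Hout·Wout) exists behind `per_kernel=True`; only
the canonical form reproduces the reference block totals. Block totals
count convolutions only — MA: 2, attention: 3, FCN: 4 — with
elementwise additions, activations, multiplications and pooling priced
at zero. The reference dimensions K=8, Cin=Cout=64, Hout=Wout=128 are a
reconstruction: they make one convolution cost exactly 2³⁰ FLOPs, so
the three block totals come out at 2,147,483,648 / 3,221,225,472 /
4,294,967,296 and sum to 9,663,676,416. `model_flop_table` prices the
actual assembled graph at its real per-layer output sizes (transpose
convolutions are priced at footprint 1 per output pixel, since 2×2
stride-2 tiles do not overlap). Parameter memory is
(trainable + non-trainable)·bytes/2²⁰ MB.

## Data pipeline

Volumes are read with nibabel in native orientation, 0-based voxel
indexing, no resampling. Preprocessing: map BraTS codes {0,1,2,4} to
{0,1,2,3} (label 3 does not occur in BraTS-2020-style data); min-max
normalize each volume to [0,1] before slicing (constant volumes map to
zeros); slice axially; resize bilinearly for images and nearest-
neighbor for masks so labels are never blended; one-hot encode; shuffle
with a fixed seed and yield batches in which every slice appears
exactly once per epoch. Slices with empty masks can be dropped via
`drop_empty` (default keeps them). Min-max rather than z-score
normalization was chosen because the network's sigmoid/tanh branches
behave well on a bounded input range and the choice was otherwise
unconstrained.

## Synthetic phantoms

The phantom generator emulates the structure of multimodal brain-tumor
data: an ellipsoidal brain inside a (64, 64, 48) volume with nested
spherical tumor shells — enhancing (r = 4) inside necrotic core (r = 8)
inside whole tumor (r = 12) — so the composite-region nesting
ET ⊆ TC ⊆ WT holds exactly by construction. Four modality volumes give
each tissue a distinct mean intensity, following clinical contrast:
edema hyperintense in FLAIR/T2, enhancing tumor hyperintense in
contrast-enhanced T1; additive Gaussian noise (σ = 0.02 on a unit
intensity scale) is seeded. An optional angular ripple perturbs the
tumor surface for irregular shapes (default off so voxel counts match
analytic sphere volumes within voxelization error). Fixture datasets
are written as uncompressed NIfTI-1 so identical seeds produce
byte-identical files.

What the phantoms do not contain: anatomy, bias fields, partial-volume
effects, registration error, inter-rater label noise. Tests passing on
phantoms therefore demonstrate that the implementation is correct and
that the architecture can fit structured multimodal data — not that it
reaches any particular accuracy on real BraTS volumes.

## Problem sizes

Tests and examples run the architecture at reduced width
(`width_multiplier` 0.05–0.25, which scales every filter count) and at
16×16–64×64 slice sizes; these sizes exercise every code path of the
full-width network, whose architecture is identical up to channel
counts. The overfit check trains a quarter-width model on one repeated
64×64 slice (batch 4, ≤150 epochs, early stop at foreground Dice 0.95);
the end-to-end check trains a width-0.1 model for 2 epochs on three
phantom subjects. Reproducing published-scale accuracy figures would
require the real BraTS data and GPU-scale training and is explicitly
out of scope.
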