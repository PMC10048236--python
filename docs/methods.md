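# Methods

## Problem setting and model

The package treats fruit surface-defect detection as binary image
classification backed by pixel-level segmentation. A segmentation network
localizes candidate defect pixels; a small decision module aggregates the
segmentation evidence globally and issues the per-image verdict. The split
matters in the small-sample regime: the pixel-wise stage-1 loss treats each
pixel as a training sample (a 512×512 image contributes ~260k of them),
while the image-level head that is most prone to overfitting holds only a
few thousand parameters and is trained separately against a frozen
backbone.

### Segmentation backbone

Four encoder levels with depth-dependent convolution blocks: level ℓ
applies `depconv_counts[ℓ]` = (1, 2, 3, 4) repetitions of 5×5 convolution →
batch normalization → ReLU at C₀·2ℓ channels, with three 2×2 max-poolings
between levels. The census — 10 encoder convolutions + 3 decoder
convolutions + 1 segmentation head = 14 counted convolutions, 3 poolings,
3 up-convolutions, 1 additional mask projection — is exposed by
`count_layers` and pinned by tests. Counting convolutions and poolings in
forward order, the bottleneck is the 13th layer, where the mask shortcut
taps in.

Design choices where the architecture description leaves freedom:

* **Channel widths.** C₀ = 32, doubling per level. This is forced by the
  decision head's 66-neuron descriptor: 2·C₀ + 2 = 66.
* **Per-level block depths.** (1, 2, 3, 4): grows with depth, sums with the
  decoder and head to exactly 14, and places the bottleneck at layer 13.
* **Decoder kernel.** 3×3 (the 5×5 statement covers only the encoder
  blocks); heads are 1×1.
* **Mask fusion point.** The mask is concatenated onto the bottleneck
  before the first up-convolution — the only place the resolutions already
  match.
* **Mask supervision.** An auxiliary BCE between the mask map and the
  8×-max-pooled ground-truth mask (weight 1.0, switchable) supervises the
  shortcut directly in stage 1; max-pooling is the right reduction for a
  "any defect pixel in this cell" target.
* **Padding/up-sampling.** Same padding throughout; 2×2 stride-2 transposed
  convolutions.
* **Initialization.** Normal(0, 0.01) weights, zero biases. Batch-norm
  after every convolution keeps activations in range despite the small
  init.

With these choices the default backbone has ~7.5 M parameters
(`AUNet.num_parameters()` reports the exact count). Published figures for
comparable two-network detectors are roughly twice that; the difference
sits in unstated width/decoder choices (a single convolution per decoder
stage here), and no attempt is made to force-match a printed figure.

### Decision module

Attention scores come from a learned 1×1 projection of the feature map —
the minimal parametric scoring consistent with attending over "hidden"
feature vectors; each direction (vertical/horizontal) has its own
projection. The combination `A·max(C_I, C_II) + B·min(C_I, C_II)` uses
fixed constants A = 0.84, B = 0.16 with A + B = 1 enforced at
configuration time; they are exposed for sweep experiments, not learned.
Concatenating (C_I, C_II, add, weight) quadruples channels, so a learned
1×1 fusion convolution restores C₀ channels — required for the 2·C₀ + 2
descriptor arithmetic. Both global max- and average-pooling are applied to
both inputs (features and mask); applying one pooling to each input cannot
produce a 66-long descriptor for any integer width.

### Numerical engine

No deep-learning framework is used: `fruitscan.nn` implements the layer
set in NumPy (im2col convolution, einsum transposed convolution, argmax
max-pooling, batch norm with running statistics, manual reverse-mode
gradients, numerically stable softmax/BCE). Gradients of every layer and
of the composed networks are validated against central finite differences
(in float64) in the tests. Tensors are float32; losses are accumulated in
float64. Max-pooling routes gradients to the first maximum on ties; the
max/min blend routes the max branch to C_I on ties (the operands are equal
there, so the value is unaffected).

## Training protocol

Plain SGD, no momentum, coupled L2 weight decay 5·10⁻⁴ applied to
convolution/linear weights only (not biases or batch-norm parameters),
batch size 1, cross-entropy losses. The full-scale `paper` profile uses
learning rate 0.1 for 100 epochs; where conflicting learning rates are in
circulation for this family of settings (0.1 vs 0.0005), the value is a
config field with 0.1 as the default. Stage 2 freezes the backbone in
eval mode; since its outputs are then constants per image, they are
computed once and cached — mathematically identical to re-running the
frozen forward pass every step. Freezing is asserted by hashing the
serialized backbone weights and batch-norm statistics before and after
stage 2.

The balanced sampler yields (defective, non-defective) pairs: defectives
without replacement (epoch ends when they are exhausted, so every
defective appears exactly once per epoch), normals uniformly with
replacement. An epoch therefore has 2·n_defective samples and need not
visit every normal image.

## Synthetic data generator

The generator emulates the statistical structure of sorting-chamber fruit
images rather than their photometry: a shaded disk (radial brightness
falloff — the limb-darkening that causes false positives at fruit edges)
with one specular highlight on a dark chamber background, plus an optional
stem/calyx-like dark spot that is *not* labeled as defect — the classic
confounder. Four defect morphologies are drawn inside the fruit: rot
(harmonic-perturbed dark blob), disease (speckle cluster), laceration
(thin streak with configurable aspect ratio, oriented within 12° of an
image axis so the elongation is measurable in the axis-aligned bounding
box), mechanical injury (low-contrast diffuse ellipse). The mask marks
exactly the altered pixels; a pixel whose blend would round-trip to its
original 8-bit value is nudged so the mask ⇔ changed-pixels invariant is
exact.

Class mixes: the emulated training distribution (79.2% normal, 6.2% rot,
4.2% disease, 5.4% laceration, 5.0% mechanical; largest-remainder
rounding, ties by enumeration order) and a balanced test mix (75% normal,
defect classes uniform — per-class counts for the defective test images
are not specified anywhere, so uniform is the neutral default). Datasets
are PNG images + {0,255} PNG masks + CSV manifest + JSON config sidecar,
byte-identical under identical (config, seed).

What the generator does **not** model: texture of real peel, color
variation across varieties, camera noise statistics, motion blur,
multi-fruit scenes. Passing the end-to-end tests therefore demonstrates
that the architecture, losses, protocol and metrics interlock correctly —
not field performance on photographs.

## Desk-scale profile

The `fixture` profile (128×128 inputs, C₀ = 8, learning rate 0.01,
10 epochs per stage, 64 training / 32 test images, half defective,
full-contrast defects of 6–14% fruit area) is the package's chosen
problem size for CPU execution of the complete pipeline; the lower
learning rate keeps batch-norm statistics stable at batch size 1 with the
narrower network. Under this profile the held-out 11-point AP reaches 1.0
(seed 0) in about two minutes.

## Evaluation conventions

* Score ≥ threshold predicts defective (ties inclusive).
* Plain accuracy/precision/recall are reported at threshold 0.5 (softmax
  argmax).
* 11-point AP: mean over recall levels {0.0, …, 1.0} of the maximum
  precision among operating points with recall ≥ r, computed from all
  distinct score cutoffs.
* Best-F threshold: exhaustive scan of distinct scores; ties resolved to
  the lowest threshold; FP/FN reported there.
* Errors at 100% recall: FP at the highest threshold still reaching
  recall 1 (the minimum positive score) — the fewest errors compatible
  with full recall.
* Zero denominators raise an explicit undefined-rate error; F1 of
  (0, 0) is defined as 0 with a warning.
* Evaluation is image-level throughout; pixel-level IoU can be derived
  from the segmentation output but is not part of the reported metrics.
* Repeated k-fold cross-validation re-splits randomly each repeat,
  records the best fold metric per repeat and averages those best values.

## Known limitations

* Batch size > 1 is supported by the layers but the protocol defaults to
  1; there is no learning-rate schedule (none is part of the protocol).
* The attention scoring is one interpretation of an under-specified
  mechanism (a learned scalar projection); a parameter-free variant would
  change the descriptor only through the fusion layer.
* The NumPy engine is single-threaded per operation (BLAS aside); the
  full-scale 512×512 profile trains slowly on CPU and is intended for
  architecture verification, not routine training.
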