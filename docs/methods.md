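# Methods

## The classification problem

Input: a single diatom, cropped from an annotated micrograph, resized to the
canonical 432×128 (width × height) frame and scaled to [0, 1].  Output: a
softmax distribution over species.  The target dataset profile is 68 classes
with strong imbalance (6–386 images per class, 3,027 in total), which drives
two design points: stratified splitting with guaranteed per-class
representation, and support-weighted reporting of every metric.

## Architecture and its accounting

The network is a three-module, depth-10 member of the dimension-reduced
inception family (see README for the layer list).  The `archspec` module
describes it declaratively; building, shape tracing, and parameter counting
all consume the same spec, so the structural claims are checkable without
weights:

* **Shape rules.** Convolutions use `same` padding (pad `floor(k/2)`):
  `d → floor((d + 2·floor(k/2) − k)/s) + 1`.  The 3×3/2 max pools use
  ceiling division with no padding (edge windows clipped):
  `d → ceil((d − k)/s) + 1`.  This convention set reproduces the published
  output chain 216×64 → 108×32 → 54×16 → 27×8 → 13×4 exactly.
* **The reconciliation pool.** A size-preserving inception module cannot map
  13×4 to the published 6×2×1,024 row.  The spec therefore inserts an
  explicit, parameter-free max pool 3×3/2 after the third inception module
  (`pool5`), which yields 6×2 and keeps both the following 6×2 average pool
  and the parameter total intact.  Whether the original implementation used
  an extra pool, strided branches, or simply a table irregularity is not
  derivable from the source; the choice here is recorded, not asserted as
  the original authors' intent.
* **Parameters.** Convolution `k×k, c_in→c_out` contributes
  `k²·c_in·c_out + c_out`; the linear head `c_in·c_out + c_out`; inception
  modules sum their six internal convolutions; pooling, cross-channel
  normalization, dropout, and softmax contribute nothing.  With 3 input
  channels the total is 1,854,996 (1.85 M, 2 dp); with 1 channel it is
  1,848,724, which also rounds to 1.85, so the budget does not disambiguate
  the input depth.  Color input (3 channels) is the default because the
  source imagery is color photomicrographs.
* **Depth.** One unit per sequential learnable stage: stem conv (1), the
  1×1/3×3 stem pair (2), each inception module (2), the linear head (1) —
  total 10.

## The numpy engine

The trainable network runs on a self-contained channels-last numpy engine
(`engine.py`): im2col + GEMM convolutions with per-kernel-row column fills
and reused buffers, running-max pooling with per-window offset indices,
cumulative-sum cross-channel normalization, inverted dropout, and a fused
softmax/cross-entropy head for training.  Every backward pass is
hand-derived and verified against central finite differences (≤1e-4
relative error in float64 across all layer kinds; in practice ~1e-7).  One
deliberate subtlety: ReLU uses the right subgradient at exactly zero, so
finite-difference checks randomize biases to keep pre-activations off the
kink.

Numerical conventions:

* Glorot (Xavier) normal initialization: zero-mean Gaussian with variance
  `2/(fan_in + fan_out)` (`fan = k²·c` for convolutions); biases start at
  zero; fully determined by one seed.
* Cross-channel (local response) normalization uses
  `x / (k + α/n · Σ_window x²)^β` with window 5, k = 2, α = 1e-4, β = 0.75 —
  the GoogleNet-lineage constants with the α-per-window-size scaling
  convention.
* Softmax is computed with max subtraction; argmax ties (prediction and
  activation-channel selection) break to the lowest index.
* Inference is a pure function of (parameters, input); dropout draws from a
  dedicated seeded stream only in training mode.

## Preprocessing

Each annotated object is rotated so the principal axis of its polygon — the
major eigenvector of the centered vertex second-moment matrix — lies
horizontal, then cropped to the rotated polygon's bounding box.  The 180°
axis ambiguity is left unresolved; the flip augmentations cover both senses.
Pixels outside the polygon are replaced by the median intensity of a
2-pixel dilated annulus around the boundary, avoiding hard dark borders the
network could latch onto.  Rotation and resizing are bilinear (reflective
boundary); resizing to 432×128 is a direct rescale that does not preserve
aspect ratio, matching the single fixed input size.  Degenerate (zero-area)
polygons are skipped with a logged warning.

Augmentation is the flip family {original, vflip, hflip, vhflip} — a Klein
four-group, so the dataset size exactly quadruples and augmenting an
augmented crop is rejected as an error.

## Splitting

Per class with `n` crops: `floor(0.70·n)` to training, `floor(0.15·n)` to
validation, remainder to test; any empty split of a class with ≥3 crops
receives one crop from that class's largest split.  Within-class assignment
is a seeded permutation.  The floored splits land within one assignment
unit of their target and the remainder split within two.  By default the
four flip variants of one source object are assigned as a single unit, so
near-duplicates never straddle the train/test boundary; splitting variants
independently (the behavior implied by split totals in which augmented
counts are not four times the original counts) is available behind an
explicit option.

## Training protocol

SGD with momentum in heavy-ball form (`v ← μv − η·grad; w ← w + v`),
mini-batches of 16 in seeded shuffled order (short final batch kept), mean
cross-entropy loss.  Full-scale defaults follow the source protocol:
η = 1e-4, μ = 0.9, up to 300 epochs, early stopping on validation loss
(patience 10, min_delta 0, best weights restored).  Validation runs once
per epoch in inference mode.  A non-finite loss aborts with the epoch and
batch named.

An optional `val_accuracy_goal` stop rule ends training once validation
accuracy reaches a target; it is off by default and used by the desk-scale
demo, where the goal is 0.97.

## Evaluation

Per class: precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
`F = 2PR/(P+R)`; weighted metric `Σ_c (support_c/N)·metric_c`; accuracy
`trace/N`.  Weighted recall equals accuracy by algebraic identity, which
the report computes independently and the tests assert.  Zero-denominator
per-class values are set to 0 and flagged in the report.  "Weighted
accuracy" is read as plain overall accuracy.  The implementation is
hand-coded from these formulas; scikit-learn serves only as an independent
cross-check in the test suite (agreement to 1e-12 on random confusion
matrices).

## Interpretability

Activation maps anchor *early* at the first stem convolution, *intermediate*
at the second inception module, and *deep* at the last; on the reduced
architecture (one inception module) intermediate and deep coincide.  The
"maximally activated" channel is the one with the largest spatial sum
(largest single pixel selectable via `mode="peak"`).  Heat maps are the
deep-layer map bilinearly upsampled to crop resolution and min–max
normalized; constant maps come back all-zero with a flag.  These are
activation-derived maps, not gradient attribution.

## Synthetic data: what it does and does not show

The generator draws elongated capsules with class-specific length, aspect
ratio, base intensity, sinusoidal striae perpendicular to the major axis,
and sparse dark pores, placed without overlap at uniform random
orientations on a lightly textured canvas, with additive Gaussian noise
(σ = 0.04) and per-object illumination jitter (σ = 0.02).  Every object
carries a boundary polygon, a pixel mask, and its true orientation, so
preprocessing (orientation recovery to ≤1°), splitting, training, and
heat-map localization are all testable against exact ground truth.  The
68-class census of the target dataset (sum 3,027) parameterizes the
imbalance emulation used to stress weighted metrics.

The `easy_benchmark` fixture — five classes × 100 crops at 432×128,
pre-split 70/15/15 — separates its classes jointly by base intensity
(0.30→0.80), stria frequency (0.03→0.25 cycles/px), and size, a separation
chosen once so that the benchmark isolates *trainability of the
implementation* rather than feature-learning difficulty.  The depth-reduced
network (stem + first inception + linear head) trained at η = 0.03, μ = 0.9
reaches ≥0.95 test accuracy within 20 epochs on one CPU.  The larger
desk-scale learning rate is a deliberate choice: the 1e-4 of the full
protocol belongs to a 300-epoch budget on a dataset 24× larger.

Passing these tests demonstrates that the pipeline — extraction through
evaluation — is internally correct and trainable end to end.  It does not
demonstrate real-data performance: synthetic classes are separable by
design, lack the inter-species subtlety, focus variation, debris, and
annotation noise of real micrographs, and use one texture model for all
classes.  Claims about accuracy on real diatom imagery require the real
dataset.

## Problem sizes and runtime choices

The test suite trains the depth-reduced network once (500 crops, ≤20
epochs, typically stopping around epoch 8 via the validation-accuracy goal)
and reuses that run for the localization check; all other tests run on toy
specs of ≤1,000 parameters or tiny synthetic batches.  The `demo` command
uses the same benchmark scale.  Checkpoints store spec, seed, parameters,
and metadata in one `.npz` archive with bit-exact round-tripping.

## Known limitations

* The engine is single-device and float32-first; float64 is supported (and
  used for gradient checks) but slow.
* Max-pool gradient routing sends ties to the first maximal offset, which
  differs from frameworks that split gradients across ties (measure-zero
  effect in training practice).
* `same`-padded pooling inside inception pads with −∞ semantics (window
  clipped to valid pixels), matching ceiling-mode pooling conventions, not
  zero-padded averaging.
* The synthetic texture model is deliberately schematic; it is a test
  instrument, not a diatom simulator.
* Activation-derived heat maps follow whichever channel is globally most
  active, which for low-contrast (dim) classes can be a channel that tracks
  the background rather than the valve; on the synthetic benchmark the
  inside-the-mask > outside-the-mask localization property holds for the
  bright classes and can invert for the dimmest one.  Gradient-based
  attribution would resolve this but is out of scope.
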