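# diatomnet

A lightweight inception-style convolutional network for classifying diatom
species from microscopy crops, together with the complete workflow around it:
annotated-micrograph preprocessing, flip augmentation, stratified dataset
splitting, SGD training with early stopping, support-weighted evaluation, and
activation-map interpretability — all runnable on a plain scientific-Python
stack (the CNN engine is pure numpy, no deep-learning framework required).

## Who this is for

Diatoms are unicellular algae whose silica cell walls carry species-specific
ornamentation (striae, pores, valve outlines).  Their community composition
is a standard bioindicator for water quality and paleoclimate work, which
makes automated species-level classification of micrograph crops a recurring
need.  The network implemented here targets exactly that task: 68 unbalanced
classes of elongated frustules, input crops of 432×128 pixels (the average
crop size of the source imagery), and a parameter budget small enough for
CPU-bound deployments.

## The model

DiatomNet is a depth-10 variant of the inception family with three
dimension-reduced inception modules instead of GoogleNet's nine:

```
conv 7×7/2 (64) → maxpool 3×3/2 → cross-channel norm
→ conv 1×1 (64) → conv 3×3/1 (192) → maxpool 3×3/2
→ inception(64, 96, 128, 16, 32, 32)   → maxpool 3×3/2
→ inception(192, 96, 208, 16, 48, 64)  → maxpool 3×3/2
→ inception(384, 192, 384, 48, 128, 128) → maxpool 3×3/2
→ avgpool 6×2 → dropout 0.40 → linear(68) → softmax
```

Each inception module runs 1×1, (1×1→3×3), (1×1→5×5), and
(3×3-maxpool→1×1) branches in parallel and concatenates channels.  Every
convolution carries a bias and ReLU; there is no batch normalization.  With
3-channel input the network totals **1,854,996 learnable parameters
(1.85 M)** — the number the package's analytic accounting, the constructed
network, and the acceptance script all agree on.

The `archspec` module is the single source of truth: the same declarative
spec builds the trainable network, traces every layer's output size in
closed form, and counts parameters without allocating a single weight.

## Worked example

Inspect the canonical architecture (shape trace, per-layer parameters, and a
regression check against the published layer table):

```
$ diatomnet inspect
layer                  output size     weights   biases
conv1                216 x 64 x 64        9408       64
pool1                108 x 32 x 64           0        0
norm1                108 x 32 x 64           0        0
conv2_reduce         108 x 32 x 64        4096       64
conv2               108 x 32 x 192      110592      192
pool2                54 x 16 x 192           0        0
inception1           54 x 16 x 256      163328      368
pool3                 27 x 8 x 256           0        0
inception2            27 x 8 x 512      293120      624
pool4                 13 x 4 x 512           0        0
inception3           13 x 4 x 1024     1202176     1264
pool5                 6 x 2 x 1024           0        0
avgpool               1 x 1 x 1024           0        0
dropout               1 x 1 x 1024           0        0
fc                      1 x 1 x 68       69632       68
softmax                 1 x 1 x 68           0        0
depth 10; total parameters 1,854,996 (1.85 M)
all published output sizes reproduced
```

Reading the output: each row is one layer with its analytic output size
(long axis × short axis × channels) and parameter split; `pool5` is the
size-reconciling max pool that brings the third inception module's 13×4 map
to the 6×2 consumed by the global average pool; the final two lines confirm
the depth-10 convention and the 1.85 M budget.

The full pipeline — synthetic benchmark generation, training the
depth-reduced network, weighted evaluation, and heat-map rendering — runs as

```bash
diatomnet demo --seed 0 --out rundir/
```

which trains on 5 well-separated synthetic classes (100 crops each, split
70/15/15) and writes a checkpoint, learning curves, an evaluation report
(weighted accuracy/precision/recall/F over the test split), a heat-map
panel, and the architecture inspection report into `rundir/`.  Individual
stages are available as `diatomnet synth / preprocess / split / train /
evaluate / cam`.

Because no public diatom imagery ships with the package, all executable
examples run on the synthetic generator (`diatomnet.synthetic_data`), which
emulates the structural properties the pipeline relies on — elongated
textured objects at arbitrary orientations, pixel-level polygon annotations,
and the published 68-class imbalance profile (class sizes 6–386, 3,027
images total).  Real data enters through the same annotation-JSON dialect
(`{image_id, width, height, objects: [{species, polygon}]}`).

## Layout

```
src/diatomnet/
  archspec.py        declarative specs, shape tracing, parameter counting
  engine.py          numpy forward/backward kernels (im2col convs, pooling, LRN)
  network.py         Glorot-initialized trainable network, checkpoints
  preprocess.py      polygon extraction, horizontal normalization, flips
  datasets.py        stratified 70/15/15 splitting, manifests
  training.py        SGD + momentum, early stopping, curve logging
  evaluation.py      confusion matrices, support-weighted metrics
  interpret.py       activation maps and input-resolution heat maps
  synthetic_data.py  procedural diatom-like imagery with ground truth
  cli.py             `diatomnet` command-line entry point
docs/methods.md      model, assumptions, numerical choices, limitations
```
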