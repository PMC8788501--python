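# Methods

## Architecture

The network is a five-level encoder–decoder for 2D axial CT slices.

**Encoder.** Level 1 applies a multi-scale convolution block to the input
slice at full resolution; levels 2–5 each max-pool 2×2 and apply another
block, doubling the channel count every level.  With base width 64 and a
256×256 input the spatial ladder is 256, 128, 64, 32, 16 and the width
ladder 64, 128, 256, 512, 1024.  The input size must be divisible by 2⁵ and
the base width by 4 (the attention bottleneck).

**Central processing.** Channel attention gates each of the four skip
features; the dual (channel + position) attention module gates the deepest
feature before decoding.  The design places channel attention on the
low-level skip features — where channel interdependence matters most — and
the full dual module only at the bottleneck; applying it to decoder features
as well is possible but was not adopted.

**Decoder / feature box.** Each of the four decoder levels upsamples with a
learned 2×2 transposed convolution, concatenates the attended skip of
matching resolution, and applies a multi-scale block whose split count
follows the schedule below.  Every decoder feature produces a coarse
class-score map through a 1×1 convolution head, bilinearly upsampled to the
input resolution; the final map is a 1×1 fusion of the four concatenated
coarse maps.  The last decoder feature does not feed the fusion directly —
only through its own coarse head.

**Argmax rule.** Hard labels come from the final map only; exact score ties
resolve to the lower class index (background).

## Attention modules

* Channel descriptor: per-channel spatial mean (entries 1..C) then
  per-channel spatial maximum (entries C+1..2C).  The gate is
  σ(W₂ ReLU(W₁ z_C + b₁) + b₂) with a C/4 bottleneck; W₁ consumes the full
  2C-dimensional descriptor.  Fully connected layers carry biases
  (initialized to zero); weights are He-uniform.
* Position descriptor: three H×W planes — channel maximum, channel mean and
  a learned 1×1 projection.  The mean (not the sum) keeps the descriptor
  scale independent of C; a `literal_sum` switch restores the sum.  The 3×3
  gate convolution feeds the sigmoid directly, with no normalization layer
  in between.
* Dual attention is the element-wise sum of the branches.  With all gate
  parameters zero, every sigmoid is 0.5, so each branch halves its input and
  the dual module is the exact identity — a property the tests verify to
  machine precision.

## Multi-scale convolution

A block is one 3×3 convolution (which performs the level's channel change)
followed by two Res2Net modules with independent parameters (no weight
sharing; the choice was open and independence is the less constrained
default).  Each convolution is followed by batch normalization and ReLU;
both can be disabled (`norm=False`), which the algebraic tests use.

Inside a Res2Net module the leading 1×1 convolution projects to the nearest
multiple of the split count S, so the split into S equal subsets is always
exact even at widths such as 512 with S = 6; the trailing 1×1 convolution
projects back.  Subset 1 bypasses the 3×3 chain entirely (identity), subset
i ≥ 2 is convolved together with the previous output, so the number of 3×3
convolutions on the path to Yᵢ grows with i and the module mixes receptive
fields.

Split schedule: encoder levels 1–3 use S = 4, levels 4–5 use S = 6; decoder
levels 1–2 (deepest) use 6, levels 3–4 use 4.

## Loss

Soft Dice per class on softmax probabilities (no argmax during training),
averaged over classes, with ε = 1e-5 added to numerator and denominator so a
class absent from both label and prediction scores perfectly instead of 0/0.
Binary segmentation uses two classes (background/vertebra) with one-hot
labels.  The training loss is the weighted sum over the four auxiliary heads
and the final head; all five weights default to 1.  Auxiliary maps are
upsampled to full input resolution before the loss, so supervision is
uniform across heads.

## Metrics

* DSC and IOU on strictly binary masks; the both-empty case is defined as
  1.0.  The identity DSC = 2·IOU/(1+IOU) holds per case.
* Boundary points are foreground pixels with at least one background
  4-neighbor (6-neighbor in 3D); pixels on the image edge count as boundary.
* HD95 is the 95th percentile — linear interpolation between order
  statistics — of the pooled symmetric set of directed nearest-point
  distances between the two boundaries.  The classical maximum Hausdorff
  distance is exposed separately (`hausdorff`).  Distances are Euclidean in
  physical units via the per-axis spacing, defaulting to pixels; after 1 mm
  isotropic resampling the two coincide.
* 3D cases can be evaluated per volume (default) or per axial slice
  (`per_slice=True`); an empty-mask case reports HD95 as missing (NaN),
  never as 0.
* `paired_compare` is a two-sided paired t-test on per-case values and
  rejects zero-variance differences as degenerate.

## Preprocessing and augmentation

Volumes are resampled to 1 mm isotropic spacing (linear for intensities,
nearest for labels; output extent = round(extent × spacing)).  Intensities
are clipped to the window [−200, 1200] HU and that window is mapped affinely
to [0, 1].  The mapping is fixed by the window, not by the volume content:
per-volume min-max would make a tissue's normalized intensity depend on what
else is in the scan and would break train/inference consistency (an
all-background volume would stretch its noise to the full range).  The
window bounds are configurable.

Axial slices are resized to the network input size (linear for images,
nearest for masks, so masks stay binary).  Augmentation applies, each with
probability 0.5: rotation by an angle uniform in ±0.1 rad, horizontal flip
(vertical flips are anatomically implausible for axial slices), contrast
scaling about the image mean with a factor uniform in [0.8, 1.2], and
additive Gaussian noise with σ uniform in [0, 0.02] on the [0, 1] scale;
images are re-clipped to [0, 1] and masks are never touched by intensity
transforms.  Every augmentation is a pure function of its seed.

Slices are split 4:1 into train/validation, stratified by volume id (each
volume contributes ~80% of its slices to training), seeded.  Whether
vertebra-free slices should be filtered is left to the caller; the default
keeps all slices.

## Training

AdamW with learning rate 0.001, weight decay 0.01 (the optimizer's
conventional default), mini-batch 16, at most 100 epochs.  After each epoch
the validation Dice of the final head's hard predictions is computed,
averaged over slices (slice-averaged rather than pixel-pooled; the
alternative is a one-line change in `dataset_dsc`).  "Does not rise" is
interpreted against the best value so far (strict improvement resets the
counter); after 10 consecutive non-improving epochs the learning rate is
halved and the counter resets.  No minimum-rate floor is applied unless
configured.  The best-by-validation-Dice model is checkpointed; optimizer
moments and the RNG state are saved with each epoch so interrupted runs
resume bit-exactly.

## Numerical backend

The model runs on a small reverse-mode automatic-differentiation engine
(`vertebox.nn`) written in numpy.  Convolutions are stride-1 'same'
(shift-and-matmul, with the padded input re-derived in the backward pass to
bound memory), upsampling is either a learned kernel==stride transposed
convolution (decoder features) or a separable bilinear operator
(auxiliary-head maps), pooling is non-overlapping 2×2 max with int8 argmax
indices, and batch normalization is a fused op.  Gradients of every
primitive are verified against central finite differences in the test suite.
Activations are float32; gradient tapes are single-use and freed eagerly
during the backward pass.  A full forward+backward of the base-width-64,
256×256 configuration fits in well under 8 GB of memory.

## Synthetic phantoms

A phantom slice is: a uniform soft-tissue background (0.20), one bright
elliptical vertebral body (~0.6–0.7) with up to three attached process
rectangles (one spinous, two transverse), optional gray-matched elliptical
distractor blobs painted only outside the mask (intensity within ±0.05 of
the body), an optional hyper-intense lesion disk inside the body (+0.2–0.3,
part of the mask), and additive Gaussian noise (σ ≤ 0.02), clipped to
[0, 1].  Default geometry puts the mask fraction at roughly 2–15% of pixels,
matching the foreground sparsity of real axial vertebra slices.

Profiles: `easy` (no distractors/lesions), `interference` (1–3 gray-matched
distractors), `lesion` (hyper-intense patch), and `mixed` (40/30/30
allocation by largest remainder, deterministic).  `generate_phantom` is a
pure function of its spec (including the seed), and every dataset ships a
JSON manifest from which it can be replayed bit for bit.

What the phantoms do **not** emulate: anatomical shape variation, cortical/
trabecular texture, partial-volume effects, CT reconstruction artifacts, and
inter-vertebra context in 3D.  Tests passing on phantoms therefore establish
that the architecture, losses, metrics and pipeline are implemented
correctly and that the network can learn the stated challenge structure —
not that the reported clinical-data accuracy transfers.

## Problem sizes in the checks

The test suite and the acceptance script use a miniature configuration
(base width 8, 64×64 input) for everything that trains: an 8-phantom
capacity run of 300 optimizer steps (training Dice ≥ 0.95) and a
24-train/8-validation run of 500 steps evaluated on 16 held-out phantoms.
These sizes were chosen so the whole pipeline — generation, training,
inference, evaluation — runs end to end on one CPU in minutes while still
exercising every component at realistic sparsity.  The full-size
configuration (base width 64, 256×256) is exercised for one forward/backward
pass to verify the shape ladder and gradient flow.

## Known limitations

* Convolutions support stride 1 only (pooling handles downsampling), and
  transposed convolutions require kernel == stride.
* Training on CPU limits practical problem sizes; the miniature
  configurations above are the intended regime for experimentation.
* The 300-step miniature hallucinates a small amount of foreground (a few
  percent of pixels) on out-of-distribution all-background input; the
  volume-inference test bounds this at 5%.
* Binary (background/vertebra) semantic segmentation only; no instance
  labels per vertebra and no 3D network variant.
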