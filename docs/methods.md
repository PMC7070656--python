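# Methods

## Counting by density-map regression

The package estimates the number of fish in a single underwater frame from
one point annotation per fish center. Detection-style counting breaks down
in a shoal (occlusion, arbitrary pose); global regression ignores spatial
structure. The middle ground is a density map: a nonnegative function
whose integral over any region is the expected number of fish there, and
whose integral over the frame is the count. The network regresses this map
and the count is read off by summation.

### Ground-truth construction

An image with N labels x₁…x_N is encoded as H(x) = Σ δ(x − xᵢ) and
smoothed with per-point isotropic Gaussians, σᵢ = β·d̄ᵢ with β = 0.3 and
d̄ᵢ the mean Euclidean distance to the k = 3 nearest labels. The
k-nearest-neighbour bandwidth is the perspective compensation: fish
imaged close-up are large and far apart (wide kernels), distant fish are
small and dense (narrow kernels). k is a package default — small k tracks
local crowding, which is the purpose of the adaptive kernel; it is
exposed on `KernelParams` along with β.

Numerical choices:

* Kernels are truncated at 4σ and each point's in-frame mass renormalized
  to exactly 1. This makes Σ(grid) = N an exact invariant (tested at
  1e-6), including points on the image border, where an unnormalized
  kernel would lose up to ~3/4 of its mass off-frame.
* A label with no neighbour (single-point image) gets fallback σ = 15 px,
  on the order of a fish-head region at the target resolution.
* Coordinates are 0-based, x = column, y = row; kernels are evaluated at
  pixel centers; sub-pixel σ degenerates to a unit impulse at the nearest
  pixel.
* Training ground truth is rendered at full resolution and block-sum
  downsampled by 8 to the network's output grid — block summation
  preserves the count exactly, whereas interpolation would not.
  Non-divisible dimensions are zero-padded bottom/right first.

## Image enhancement

Underwater frames have a blue-green cast (red absorbed first) and low
contrast (scattering). Two stages, all arithmetic in float64 on the 0–255
scale with a single round-half-up quantization at the end of the pipeline
(this keeps the mean-128 law below exact):

1. **Grey-world color correction.** Per channel, a piecewise-linear
   stretch anchored at the channel minimum (mean ≤ 128) or maximum
   (mean > 128) maps the channel mean exactly to 128; outputs are clamped
   to [0, 255] after the transform. A channel in which more than 70 % of
   pixels are ≤ 40 — typically the attenuated red channel — would be
   violently amplified by that stretch, so it instead shifts by
   −λ(mean − 128) with λ = 0.5. λ = 0.5 is a package default (a mid-range,
   half-strength pull toward mid-grey; the branch exists to avoid
   overcorrection). The shift branch takes precedence; applying both
   would double-shift. A constant channel maps to 128, the limit of the
   stretch target.
2. **Contrast enhancement.** The corrected image S₀ is blended with a
   reference Sr by minimizing
   F(E) = α‖E−S₀‖²_W12 + (1−α)‖E−Sr‖²_W12, with ‖u‖²_W12 = ‖u‖² + ‖Du‖².
   Both terms share the operator (I + DᵀD), so the minimizer is the
   pointwise blend E = αS₀ + (1−α)Sr regardless of the difference stencil;
   the test suite confirms this against an L-BFGS minimization of the
   discretized functional (forward differences, 8×8 planes, 1e-4/pixel).
   α = 0.5 is the default: equal weight to the two information sources.
   Sr is per-channel global histogram equalization of S₀ — the canonical
   contrast-expanded reference — using the classic 8-bit cdf-min LUT, so
   a constant channel is a fixed point and an already-full-range two-level
   channel is unchanged.

## Network

Three convolutional columns (kernel ladders 9-7-7-7, 7-5-5-5, 5-3-3-3;
filter ladders 16-32-16-8, 20-40-20-10, 24-48-24-12) look at the same
frame with three receptive-field scales, accommodating the size and pose
spread inside a shoal. Each column applies three 2×2 stride-2 max-pools,
so all three emit spatially aligned maps at 1/8 resolution ("same"
padding, stride 1 throughout), fused by channel concatenation. The filter
widths follow the published multi-column counting architecture this front
end is based on, and are fully configurable.

The back end deepens the network without further pooling: six 3×3
convolutions with dilation rate 2 (filters 64-64-64-32-32-16), widths
deliberately below VGG-16 scale for a single-scene task. A dilated kernel
covers (kr − r + 1) = 5 pixels per side with only 9 nonzero taps,
enlarging the receptive field at constant resolution and parameter count —
the package exposes this arithmetic (`effective_kernel_size`,
`dilated_kernel_footprint`) and, because the network is NumPy with
hand-written backward passes, verifies it empirically from the nonzero
input-gradient positions of a single output unit.

A 1×1 convolution (not a fully-connected layer) ends the network, so any
input size is accepted; sides not divisible by 8 are zero-padded
bottom/right. Every convolution is followed by a ReLU, including the head,
which guarantees a nonnegative density. Inputs are scaled to [0, 1].

Initialization: all convolution weights N(0, 0.01), biases 0, deterministic
per seed. Two deliberate deviations from a pure Gaussian draw:

* The head's weights take absolute values. Head inputs are post-ReLU
  (nonnegative), and a signed draw can start the rectified head with all
  pre-activations negative — a permanently dead output with zero gradient,
  observed in practice on narrow configs. Nonnegative head weights
  guarantee a live head; the weight-standard-deviation contract is
  unaffected in aggregate.
* `build(..., init_std="he")` selects variance-preserving He
  initialization (std = √(2/fan_in)). With the 0.01 init, activations
  shrink by roughly an order of magnitude per layer, and useful learning
  begins only after Adam has inflated the weights over many thousands of
  steps — affordable in a long GPU-scale run, not in a CPU-scale one. The
  CPU-scale experiments therefore use He init; the default `build()` keeps
  the 0.01 recipe.

## Training and evaluation

Online learning: batch size 1, Adam lr 1e-5 (default), MSE on density
maps, 100 epochs (default), no early stopping; the validation split is the
last 10 % after a seeded shuffle, and the whole loop is deterministic per
seed. History records per-epoch training loss and validation MAE/RMSE/MAPE.

Metrics over per-image count pairs: MAE, RMSE (√ of mean squared error),
MAPE as a percentage, accuracy = 100 − MAPE (an algebraic identity, kept
exact by computing both from the same mean), and Pearson correlation.
MAPE requires strictly positive truths and errors out otherwise. The
range report buckets images by true count into half-open intervals
[0,60), [60,100), [100,140), [140,180), [180,∞) and reports per-bucket
accuracy; the error series is estimate − truth in input order with a
configurable-width histogram.

## Synthetic scenes

The generator emulates the target imagery — a shoal photographed from
below — with seeded, label-consistent scenes: a blue-green background with
smooth low-frequency variation and attenuated red; N ∼ U{30…214} (the
shoal-size span the method targets) silver-grey ellipses with random
heading; a vertical size gradient (top-of-frame fish ~50 % smaller)
standing in for perspective; overlap allowed, labels at true centers;
global Gaussian blur for scatter. Defaults: 256×256 px, fish length
10–22 px. The two augmentations follow the dataset-expansion recipe:
additive Gaussian noise of variance 0.001 on the [0, 1] scale, and
salt-and-pepper noise corrupting a 0.001 fraction of pixels (impulse
noise is parameterized by corruption density; "variance" is not a natural
parameter for it). `make_dataset` emits the 4× expansion — original,
enhanced, Gaussian-noise, salt-and-pepper variants sharing one annotation
set — and keeps all four variants of a scene in the same split, so no
fish distribution leaks between train and test.

What the generator does **not** emulate: fish texture and fins, 3-D depth
(the density map is inherently 2-D), nonuniform illumination, turbidity
gradients, motion blur, or camera distortion. Tests passing on these
scenes demonstrate that the pipeline's machinery is correct and that the
architecture can learn to count blob-like objects under a color cast;
they say nothing about accuracy on real footage.

## CPU-scale learning experiment

The stochastic end-to-end check trains a quarter-width model
(`reduced_config(0.25)`) on 200 scenes at 128×128 with 5–40 fish of length
8–16 px — the default object density per pixel, kept at a smaller canvas —
and evaluates on 50 held-out scenes. Recipe: He init, Adam lr 3e-4, 16
epochs, seed-pinned (≈2.5 min on one CPU). Expected behaviour, asserted by
the test: training loss decreases, held-out Pearson ≥ 0.9, MAPE well below
the untrained model's. Representative run: Pearson ≈ 0.95, MAPE ≈ 13 %
versus ≈ 100 % untrained. The learning rate and epoch count are the scaled
experiment's own recipe; the full-scale defaults remain lr 1e-5 / 100
epochs.

## Known limitations

* The NumPy network is CPU-bound; the full-width model is practical for
  inference and small experiments, not for full-scale training.
* Histogram equalization quantizes to 256 levels inside an otherwise
  float pipeline; the reference image is inherently 8-bit.
* Pearson is undefined (NaN) for constant estimate or truth vectors
  unless they are identical; callers should treat NaN as "no linear
  relationship measurable".
* The range-bucket names assume the default four edges; custom edges get
  generic names.
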