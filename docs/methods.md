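# Methods

## The preprocessing model

`ctprep` implements a two-part preprocessing module for non-contrast brain
CT slices. A compact convolutional **parameter generator** `h` looks at a
bilinearly downscaled copy `I_s` of the windowed slice `I_o` and emits a
handful of scalar filter parameters,

    p_1..n = h(I_s),

which drive a bank of predefined differentiable filters. The enhanced
slice is the original plus the sum of filter *residuals*, clipped to the
display range:

    I_e = clip( I_o + sum_i w_i * (F_i(I_o, p_i) - I_o), 0, 1 ).

The residual convention matters: a literal sum of full filter outputs
would roughly (n+1)-fold the signal before clipping, and neutral
parameters would not reproduce the input. With residuals, zero gains give
a bit-exact identity and each filter is an additive correction. Because
the learned component only emits scalars - it has no pixel-synthesis
pathway - the module can rescale, sharpen or shift a slice but cannot
invent anatomy. That is the core safety argument for using it upstream of
stroke-lesion segmentation, where a hallucinated edge could become a
false "infarct boundary".

### The filter bank

| filter        | parameters  | definition |
|---------------|-------------|------------|
| brightness    | b in [-1,1] | `I + b` (additive; clip deferred to the pipeline) |
| contrast      | r in [-1,1) | `0.5 + (I-0.5)*s(r)`, `s(r) = 1/(1-r)` for r>0 else `(1-r)`; a `literal` mode omits the 0.5 restore |
| sharpen       | q per channel in [-1,1] | convolution with `(K + M q)/nu(q)`; `K` = 5x5 binomial outer product with center replaced by -476, `M` = ring map (0.8/0.9/1), `nu(q) = -256 + 21 q` |
| gaussian blur | sigma > 0 | sampled centered 2-D Gaussian on a (2k+1)^2 grid, renormalized to unit sum; trainable sigma mapped into (0, 2] px |
| median        | none        | exact 3x3 order statistic (non-trainable) |
| kernel combo  | 3 softmax logits | `sum_i alpha_i (K_i^pretr * I)` with frozen multi-scale kernels (5x5, 7x7, 11x11) |

All convolutions use mirror (reflect) boundary handling. Every kernel that
reaches the image either sums to 1 (blur, sharpen, combo) or is a pure
pointwise map, so constant images pass through the whole bank unchanged -
the property the uniform-phantom protocol checks.

The default pipeline is the empirically strongest combination: kernel
combo + brightness + sharpen + contrast. Median and blur are registered
but off by default. Per-filter gains exist (default 1) for neutrality
tests and ablations; they are not trained.

The brightness and contrast heads of the *pipeline* are bounded to
±0.25: the module exists to undo photometric degradations of roughly
±20%, and bounding the corrections to that order is part of the safety
design (a bounded filter cannot drive a slice onto the clip rails). The
library functions `brightness_apply` / `contrast_apply` accept the full
range.

### Parameter generator

Three conv blocks (3x3, stride 2, padding 1, BatchNorm, ReLU) reduce
3x128x128 to 128x16x16, followed by two fully connected layers and
per-group activations (sigmoid for unit-range parameters, tanh for signed
ones, identity otherwise). Two head variants:

* `lite` (default): global average pooling into the 512-unit FC, and
  depthwise-separable convolutions in blocks 2-3, ~83k parameters.
* `flatten`: flattening the full 32,768 features (~17M
  parameters), kept for comparison; the flatten wiring and a "lightweight"
  parameter count cannot both hold, so the lite head is the default.

Three design choices make the generator safe and trainable:

1. **Identity initialization.** The final head layer starts at zero, so
   every signed parameter begins at its neutral value. With standard He
   initialization the tanh heads start saturated, the clipped output
   kills the gradients, and training freezes.
2. **Mean-centered input.** The generator sees the downscaled slice minus
   its own mean (re-centered on 0.5). Corrections are therefore estimated
   from structure and contrast, not from the absolute intensity level.
3. **Reference calibration.** Head pre-activations are taken relative to
   those of a featureless mid-gray image passed through the same forward.
   Combined with (2), any constant input presents the generator with
   exactly the reference, so its parameters are *exactly* neutral and the
   uniform-phantom output equals the input identically. The
   negative control thus holds by construction, not merely empirically.

The kernel-combination logits are shared trainable weights of the
pipeline (not per-image predictions): the frozen kernels came from
pretraining and only their three mixing weights adapt.

### Kernel pretraining

A 5-level U-Net whose skip paths each contain one convolution of fixed
size (5x5 shallowest, 7x7, 11x11) is trained on synthetic phantoms -
segmentation with Dice loss by default, reconstruction with L1 as an
alternative. Each skip convolution's weight tensor is reduced to one
spatial kernel (channel mean by default; first-channel and Frobenius-top-1
are selectable), L1-bounded, and given unit DC gain by a center
correction. Dividing by the raw kernel sum - the obvious normalization -
is ill-conditioned: a channel-averaged kernel can sum to nearly zero, and
the exploded kernel forces the rest of the pipeline to fight the block.
The manifest records the reduction and normalization. After assembly the
kernels are frozen; only the softmax logits train.

## Training

* Restoration objective: `w_s * (1 - SSIM(I_e, I_gt)) + w_1 * mean|I_e - I_gt|`
  with equal unit weights. SSIM uses the standard 11x11 Gaussian window
  (sigma 1.5) and stabilizers C1 = 0.01^2, C2 = 0.03^2 on the [0,1] range;
  the local map is border-cropped before averaging, making the value
  independent of any padding convention (and equal to scikit-image's).
* Segmentation objective: soft Dice over core and penumbra only
  (background excluded), smoothing eps = 1.
* Optimizer: AdamW, decoupled weight decay 0.05, betas (0.9, 0.99), cosine
  decay of the learning rate to zero. The full-scale schedule
  (`TrainConfig()`) is 10 pretraining + 40 joint epochs at batch 32 with
  lr 1e-4 (1e-6 at the joint stage). The desk profile
  (`TrainConfig.scaled()`) used by the examples, tests and the acceptance
  script is 200 paired phantoms, 5 epochs, batch 8, crops at 128x128, and
  lr 3e-3 - at ~125 optimization steps the schedule-equivalent rate is
  necessarily larger than the full run's.
* Every run is a pure function of (config, seed) on one CPU thread.

## Synthetic data

The phantom generator produces 512x512 windowed-slice lookalikes: an
elliptical high-intensity skull ring, smooth textured parenchyma with a
faint ventricle, and (with configurable probability) a hypodense lesion -
a penumbra blob (-0.04) containing a darker core (-0.09 total) with
consistent disjoint masks. About 15% of dataset slices are near-empty
apex/base slices (air, a faint skull cap), mirroring the low-content
slices real CT volumes contribute. Uniform-intensity phantoms serve as
negative controls.

Paired training data applies a random subset of mild degradations, each
with probability 0.5, drawn inside fixed ranges: Gaussian blur
sigma in [0, 0.20] px, additive Gaussian noise with variance 10-50 on the
8-bit scale (sd/255 in intensity units), center crop to 400-512 px then
resize back, rotation within ±10 degrees, brightness/contrast within
±20%. Geometric draws are replayed onto the clean target (and, with
nearest-neighbour resampling, onto the masks), so the restoration pair is
spatially aligned and only photometric damage separates source from
target; draws that destroy more than 25% of the core are redrawn with the
count recorded. Datasets generated at 512 can be stored at the training
resolution (`store_size`) to bound memory.

What the phantoms do *not* model: scanner physics (beam hardening,
streaks, photon starvation), anatomical variability, partial-volume
effects at lesion rims, and real annotation noise. Passing tests on
phantoms therefore demonstrates the mechanics and safety of the method,
not clinical segmentation accuracy.

## Metrics

Slice-wise Dice and Jaccard; volumetric Dice/IoU by summing per-slice
intersections and sizes over the stack (equal to the voxel-wise 3-D
statistic); Hausdorff distances over boundary voxels (mask minus its
erosion) in millimetres using the (z, y, x) voxel spacing, default
(5, 0.5, 0.5) mm, in maximum, 95th-percentile (directed percentiles
symmetrized by max) and average-symmetric variants; and a trimap
F-measure restricted to a band (default 5 px, Euclidean) around the true
boundary. Conventions: overlap metrics are 1.0 when both masks are empty;
distance metrics raise on an empty surface and the report skips those
slices with a recorded count; optional nearest-neighbour z-interpolation
onto a near-isotropic grid is off by default and recorded in the report.

## Numerical infrastructure

No GPU framework is used. All networks run on a small in-package
reverse-mode autodiff engine over float64 numpy arrays: broadcasting
arithmetic, matmul, reductions, activations, im2col-based 2-D convolution
(stride/groups), a vectorized depthwise convolution, reflect/zero
padding, pooling, nearest upsampling, and bilinear resizing expressed as
constant interpolation matrices (hence exactly linear). Gradients of
every operator are verified against central finite differences in the
test suite; convolutions are additionally checked against scipy and
brute-force dense loops. Backward passes dismantle the graph after use so
long trainings run in constant memory.

## Scaled results and known limitations

With the desk profile (seed 1234) the trained preprocessor reduces the
held-out restoration loss by roughly a third relative to the identity
baseline, and the uniform-phantom control returns SSIM = 1.0 identically
(the calibration result above; the output standard deviation on constant
inputs is at floating-point rounding level).

The directional claim that preprocessing improves a *downstream
segmenter* is not resolvable at desk scale, and the package reports this
honestly: in a three-arm control (degraded / clean / enhanced inputs to
the same toy 3-level U-Net at 64x64, 125 training steps), even perfectly
clean inputs do not outperform degraded ones - the soft degradations do
not measurably impair a BatchNorm segmenter at this scale, so there is no
headroom for any preprocessor to show a benefit, and run-to-run variance
dwarfs the candidate effect. The paired-seed acceptance test encodes the
directional property faithfully and is expected to behave like a coin
flip at this scale. Demonstrating the segmentation benefit requires
realistic data volumes and backbone capacity.

Other limitations: the median filter is forward-only (non-trainable by
design); the flatten generator variant is provided but not trained
by default; and the phantom SSIM guarantee concerns structureless inputs -
on structured inputs the module by design changes contrast and sharpness,
and its output is judged by the restoration loss, not by perceptual
fidelity.
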