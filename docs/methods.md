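# Methods

`rdagan` implements ×2 single-image super-resolution (SISR) for bright-field
microscopy with a residual dense attention generator trained adversarially
against two discriminators. This note records the model, the numerical and
design choices that were genuinely open, what the synthetic data emulates,
and what the tests do and do not demonstrate.

## Model

**Generator.** The LR image enters a shallow feature extractor (a 9×9 conv
to G0 = 64 channels, then a 3×3 conv), passes through D = 16 residual dense
attention blocks (RDABs), a dense-feature-fusion stage, and a sub-pixel
reconstruction head. Each RDAB runs C = 6 densely connected conv+ReLU
layers — layer c consumes the block input concatenated with all previous
layer outputs and emits G = 58 new channels — then fuses the full
concatenation (G0 + C·G channels) back to G0 with a 1×1 conv (local feature
fusion), refines the fused map with CBAM, and adds the block input (local
residual learning). Block outputs are concatenated (D·G0 channels), fused by
1×1 and 3×3 convs (global feature fusion), and added to the shallow features
F0 (global residual learning). Reconstruction is one 3×3 conv → ×2
pixel-shuffle → PReLU stage per factor of two, then a 9×9 conv to RGB.

**CBAM.** Channel attention: global average- and max-pooled descriptors
share a two-layer bottleneck MLP (ratio r = 4, ReLU, no biases); the two
logits are summed and sigmoid-squashed into per-channel gates. Spatial
attention: per-pixel mean and max over channels form a 2-channel map,
convolved 7×7 to one channel and sigmoid-squashed. Gating is strictly
channel-then-spatial and is applied to the fused block output *before* the
local residual addition (`cbam_position: pre_residual`; the alternative
reading is a config switch). All gates lie in (0, 1), so refinement never
increases an activation's magnitude.

**Discriminators.** The image discriminator is the classic pixel-domain
patch classifier: eight 3×3 convs at widths w, w, 2w, 2w, 4w, 4w, 8w, 8w
(w = 64) alternating stride 1/2, LeakyReLU(0.2), batch norm from the second
conv on, and a dense sigmoid head bound to the training patch size. The
feature discriminator classifies *frozen VGG-19 feature maps* of real vs
generated patches (four stride-2 convs, global average pooling, dense
sigmoid head); because those maps encode structure, it pushes the generator
toward real structural high-frequency content rather than noise. The VGG-19
extractor taps the activation after conv5_4 (post-ReLU, before the fifth
pool) by default; its weights come either from a seeded Kaiming
initialization (the offline default — deterministic given the seed) or from
a user-supplied `.npz` conversion of pretrained weights. Extractor
parameters are frozen: gradients flow through to the image, never into the
weights.

**Losses.** With I_g the SR output, I_h the real HR patch, ϖ the extractor:

    C_p  = ‖I_g − I_h‖² + ‖ϖ(I_g) − ϖ(I_h)‖²          (batch means)
    C_ai = −log D_i(I_g)          C_di = −log D_i(I_h) − log(1 − D_i(I_g))
    C_af = −log D_f(ϖ(I_g))       C_df = −log D_f(ϖ(I_h)) − log(1 − D_f(ϖ(I_g)))
    C_g  = C_p + λ (C_ai + C_af),   λ = 10⁻³

λ scales both adversarial terms (`lambda_scope: both`; the reading in which
it scales only the image term is one flag away). The pixel and feature
weights inside C_p are individually configurable. Probabilities are clamped
to [ε, 1−ε], ε = 10⁻¹², before logarithms; clamping perturbs a loss by at
most |log(ε/(ε+δ))| for outputs within δ of a boundary.

**Training.** One step is a full alternation: (1) D_i descends C_di against
the detached SR batch, (2) D_f descends C_df on frozen features, (3) the
generator descends C_g with both discriminators in eval mode, so their
parameters *and* normalization statistics are bitwise untouched by a
generator update. Every optimizer is Adam (β₁ = 0.9, β₂ = 0.999) at
2×10⁻⁴, halved once after epoch 200 (a `lr_decay_every` flag enables
repeated halving instead). Training patches are 192² HR crops (96² LR),
aligned by drawing the crop origin on the LR grid, augmented with the eight
dihedral symmetries. Batch size defaults to 16, epochs to 400. An optional
`pretrain_epochs` warmup (perceptual term only) and an optional `grad_clip`
(global L2 gradient-norm ceiling per update) are off by default; the
separate `disc_lr` defaults to the generator rate.

## Compute core

The networks run on a small reverse-mode autodiff engine over NumPy arrays
(`rdagan.nn`): im2col convolutions, pooling, pixel-shuffle, batch norm and
Adam, in float32, NCHW. Every op's backward pass is validated against
central-difference numeric gradients in float64 in the test suite. All
randomness flows through explicit `numpy.random.Generator` objects created
from recorded seeds; there is no global RNG state, which is what makes the
bitwise determinism and checkpoint-resume contracts testable.

## Parameter calibration

The architecture leaves C (convs per block), G (growth rate) and several
head widths open; the reference parameter budget of 11.25 M for the
generator is the binding constraint (the budget is read as generator-only —
the comparator models it sits among are generator-only networks).
`expected_parameter_count` gives the closed-form count and
`calibrate_growth_rate` searches G against the budget. The frozen result:

    D=16, C=6, G=58, G0=64, CBAM r=4 (k=7), 9×9 first/last convs,
    a second 3×3 shallow conv, GFF 1×1+3×3, one ×2 pixel-shuffle stage
    → 11,254,580 parameters = 11.25 M (two decimals)

C = 6 with G in {32, 48, 64} alone lands at 8.26 M / 13.12 M — the budget
pins G = 58 with the SRGAN-style 9×9 head/tail convs, the RDN-style second
shallow conv, and r = 4.

Two further zero-parameter choices stabilize optimization and are defaults
at every scale: inputs are shifted by −0.5 on entry and +0.5 on exit
(`mean_shift`, the EDSR practice — image tensors are far from zero-mean),
and residual-branch weights are scaled by 0.1 at initialization
(`residual_init_scale`, the ESRGAN practice), so the network starts near a
shallow-plus-identity map and the reconstruction head dominates early
optimization.

## Synthetic data

`synthesize_cell_scene` renders bright-field-like fields: a warm bright
background with a random linear illumination gradient, elliptical cell
bodies with soft edges and an eosin-like tint, darker offset nuclei,
multiplicative intra-cell texture (smoothed noise), then Gaussian blur and
additive sensor noise, clipped to [0, 1]. A scene is fully determined by
its spec and seed. Defaults (256² canvas, 12 cells of radius 10–24 px, blur
σ = 0.8, noise σ = 0.01) imitate the scale of cells in a high-magnification
field.

What the generator does **not** emulate: real optics (defocus PSFs,
chromatic aberration, vignetting beyond a linear ramp), stage stitching,
the registration error between physical 20×/40× acquisitions, and the
texture statistics of any particular stain. LR images are always the
bicubic ×2 decimation (Catmull-Rom a = −0.5, antialiased, via Pillow's
float-mode resize) of the HR image — the same degradation pairing used for
the real corpus — so passing tests demonstrate that the machinery learns
to invert this degradation on cell-like imagery, not that it reaches any
particular fidelity on real microscope data.

## Evaluation protocol

PSNR and SSIM are computed on the luma channel after a BT.601 studio-swing
YCbCr conversion (Y ∈ [16, 235]/255; a full-swing flag exists), with a
border shave of `scale` pixels by default. PSNR uses peak 1.0 and reports a
100 dB cap with an `identical` flag instead of infinity. SSIM is the
11×11 Gaussian-windowed (σ = 1.5) index, k1 = 0.01, k2 = 0.03, covariance
normalization 1, map cropped by the window radius before averaging; it is
cross-checked against scikit-image's implementation in the tests. LPIPS
needs externally trained weights, so it is a plug-in callable: reports mark
it unavailable when absent and nothing ranks by it.

## The desk-scale smoke test

`TrainConfig.tiny_overfit` + `tiny_overfit_dataset` define the end-to-end
check that training actually learns super-resolution on one CPU in
minutes: eight 64² synthetic patches, 300 steps (10 epochs × 30) at batch
4, full three-phase alternation with cropping and dihedral augmentation.
Scaled-down choices, fixed once: generator D=2/C=3/G=16/G0=32 with a 3×3
head, discriminator width 16, feature tap conv2_2 with seeded-random
weights, pixel-only perceptual term, generator lr 5×10⁻³ (suited to the
small parameter count) with discriminators at the full-recipe 2×10⁻⁴, β₂ =
0.99. The patches are granule-dense scenes (80 cells of radius 1.2–2.5 px,
no blur) whose energy above the LR Nyquist frequency makes plain bicubic
upsampling a beatable baseline — on large smooth cells at this patch size
bicubic is near-perfect and the task degenerates. The adversarial weight is
zero in this configuration: a discriminator that has memorized eight images
drives the generator away from fidelity, so the fidelity assertion
(trained Y-PSNR > bicubic > untrained) is made under the pure perceptual
objective while both discriminators still train in their own phases.
Adversarial mechanics (alternation order, freeze contracts, loss bundles,
trace determinism) are asserted separately at λ = 10⁻³ over short runs
where no fidelity claim is made.

## Numerical notes and limitations

- Same-padding zero-fill everywhere; pixel-shuffle stages are the only
  spatial-size changes inside the generator. Generator output is un-clipped
  during training and clipped to [0, 1] at inference/serialization.
- Max-pool and max-reduction ties send the gradient to the first maximum.
- Checkpoints are `.npz` archives: a JSON header (schema tag
  `rdagan-checkpoint-v1`, config + hash, counters, data-RNG state) plus all
  parameter, buffer and optimizer-moment arrays. Resuming reproduces the
  unbroken loss trace bitwise given the same dataset.
- Single-process CPU only; the engine favors clarity and testability over
  throughput, and full-scale (D=16, 192² patches) adversarial training at
  the full-recipe epoch counts is far outside its practical envelope. The
  defaults nevertheless describe that full recipe faithfully; desk-scale
  work uses the reduced configs above.
- Scales other than powers of two are rejected; anisotropic scales are
  unsupported.
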