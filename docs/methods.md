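# Methods

## Problem setting

CBCT volumes carry scatter-induced artifacts — shading, cupping, reduced
contrast, beam hardening — and their grey values are not calibrated to
Hounsfield units. The package treats CBCT→CT correction as 2D slice-wise
image-to-image translation: a generator maps a normalized CBCT slice to a
synthetic CT (sCT) slice, trained either supervised (paired slices,
pixel-wise mean absolute error) or unsupervised (unpaired pools, a
cycle-consistent adversarial game). Everything runs on synthetic phantoms so
that the full pipeline is exercisable and testable on a single CPU.

## Synthetic data model

A phantom slice is an elliptical soft-tissue body (semi-axes drawn per
subject; uniform tissue value in [−100, 100] HU plus Gaussian texture) on an
air background (−1000 HU), with 3–6 elliptical bone inserts (700–1200 HU)
and, with some probability, an elliptical gas cavity (−1000 HU, at most 15%
of the body area). All values are clipped to [−1024, 3200] HU.

The CBCT degradation operator acts inside the body mask:

    CBCT(x) = gain · CT(x) + offset − A·(1 − (r/R)²) + B·(r/R)^p + ε(x)

with `r` the distance from the body centroid and `R` the body's effective
radius, taken as the mean of the mask's principal semi-axes (computed from
second central moments; exact for ellipses, well-defined for irregular
masks). The cupping term depresses the centre by `A` and vanishes at `r = R`;
the hardening term brightens the periphery with exponent `p`. `ε` is
Gaussian noise in HU, applied before clipping, as a one-parameter stand-in
for quantum and scatter noise. Outside a circular field of view
(`fov_radius_fraction` of the image half-width) everything is truncated to
air. Anatomical mismatch is emulated by filling the CT's gas cavities with
the median surrounding tissue and re-drawing the same number of cavities at
independent positions and shapes (an independent sub-seed); count is
preserved, position and shape are not. Finally the image is shifted by an
integer-pixel isocenter offset and clipped.

Cupping and hardening are additive radial polynomial fields rather than the
output of a physics simulation: three parameters reproduce the
characteristic concave intensity-profile signatures, which is what the
translation networks react to. The default per-subject sampling ranges —
gain 0.9–1.1, offset ±80 HU, cupping 20–120 HU, hardening 0–60 HU with
power 2–4, noise 5–20 HU, FOV fraction 0.85–1.0, isocenter shift ±6 px —
are plausible clinical magnitudes chosen once; they are package defaults,
not measured values. Specs and artifact models are sampled once per subject
(intra-subject consistency); sub-seeding is keyed by (seed, subject, slice)
via `SeedSequence`, so a given slice is stable under dataset-size changes.

What the phantoms do **not** contain: realistic anatomy and texture
statistics, streak/motion artifacts, projection-domain effects,
3D cone-beam geometry, couch structures, or metal. Passing tests therefore
demonstrate that the pipeline's mechanics (masking, alignment, training
dynamics, metric behaviour, anatomy preservation under mismatch) work as
specified — not clinical-grade correction on patient data.

## Pre-processing

- Otsu threshold computed once per volume (not per slice), then per slice:
  largest connected component, binary hole filling, one 3×3 erosion to trim
  the partial-volume halo. A constant volume raises a degenerate-histogram
  error.
- Masked-out background is set to −1000 HU (air) — anatomically meaningful
  and distinct from the −1024 clip floor; configurable.
- Pair alignment is an integer-pixel translation derived from the isocenter
  offset (mm → pixels via spacing); no interpolation or rotation, so no
  resampling blur. Vacated pixels are filled with air.
- Normalization: `y = (clip(x, −1024, 3200) + 1024) / 4224`; the inverse is
  exact on the clip window. Resampling is bilinear with pixel spacing
  rescaled to preserve physical extent.
- Augmentation: rotations by multiples of 90° and horizontal flips, the same
  transform applied to both members of a pair (8 distinct configurations),
  re-sampled each epoch from a per-epoch seed.

## Architecture

ConvBlock = 2D convolution → affine instance normalization → swish
(`x·sigmoid(x)`). InceptionBlock = four parallel ConvBlocks with kernels
1/5/7/11 and equal branch widths, concatenated: simultaneous small- and
large-receptive-field views for multi-scale feature extraction.

The generator is a five-level U-Net: the two shallowest levels are
InceptionBlocks (global context), the deeper three are 3×3 ConvBlocks (fine
localisation); 2×2 max-pool downsampling; nearest-neighbour ×2 upsampling
followed by a 3×3 ConvBlock (avoids checkerboard artifacts); skip
connections by concatenation; a final 3×3 convolution and sigmoid map to one
channel in [0, 1].

The published reference totals — 2,554,977 generator and 429,185
discriminator parameters, 5,968,324 for the two-generator/two-discriminator
ensemble — are used as exact architecture anchors. Since per-level channel
counts are not part of the printed description, they were resolved by
exhaustive search over channel layouts and block conventions until the
totals matched exactly:

- generator channels per level **(32, 40, 120, 200, 200)**, ConvBlocks with
  conv bias and affine instance norm;
- discriminator channels **(32, 64, 128, 128)** with 4×4 kernels and strides
  (2, 2, 2, 1), **bias-free** convolutions, **no normalization in the first
  block** (the usual PatchGAN convention), and a 4×4 convolution head
  (128→1, with bias) + sigmoid producing the 32×32 patch map.

Both totals are reproduced exactly by `count_trainable_parameters`, and
`2·(2,554,977 + 429,185) = 5,968,324` closes the ensemble arithmetic.

**Residual variant.** `GeneratorConfig(residual=True)` adds the input to the
final pre-sigmoid activation in logit space and zero-initializes the last
convolution, so the network starts from the exact identity mapping and
learns the artifact correction as a residual. This is standard practice in
image-restoration networks, adds no parameters (the anchors above are
unaffected), and is essential for the desk-scale training runs below, where
the optimization budget is ~80 gradient steps: a randomly initialized
generator starts at a ~900 HU validation error and cannot reach a useful
operating point in that budget, while the residual generator starts at the
corruption level itself.

**Initialization.** Convolutions are drawn from N(0, 0.02²) (the convention
for normalized GAN generators/discriminators); instance-norm scale/shift
start at 1/0. In blocks configured *without* normalization the 0.02
convention collapses activation magnitudes layer after layer, so those fall
back to He initialization (`std = sqrt(2/fan_in)`).

## Training

Both routines use ADAM (lr 2·10⁻⁴, β₁ = 0.5, β₂ = 0.999), batch size 10,
25 epochs at reference scale, coherent per-epoch augmentation, and
checkpointing of the weights with maximal validation SSIM (computed over the
body mask). The supervised loss is the mean absolute pixel difference
between sCT and the paired CT.

The unsupervised routine trains G_CT, G_CBCT, D_CT, D_CBCT. Generator loss =
BCE(D_CT(sCT), 1) + BCE(D_CBCT(sCBCT), 1)
+ λ_cyc·[L1(G_CBCT(sCT), CBCT) + L1(G_CT(sCBCT), CT)]
+ λ_id·[L1(G_CT(CT), CT) + L1(G_CBCT(CBCT), CBCT)], with λ_cyc = 10 and
λ_id = 5 (canonical cycle-consistency defaults; both exposed in config). The
discriminator loss is BCE(D(real), 1) + BCE(D(fake), 0) on the sigmoid patch
map, fakes detached. A least-squares adversarial criterion is available
behind a flag. The two pools are shuffled independently each epoch — pairing
is never used by the unsupervised objective; the paired validation split is
used only for the checkpoint rule. No image-history buffer is used (kept as
a possible extension). `TrainConfig.d_steps` performs k discriminator
updates per generator update (the classic k-step discriminator schedule),
with fresh real batches and the current fakes; `d_learning_rate` decouples
the discriminator's step size.

Gradients are implemented per layer with per-call caches, so a generator can
be traversed several times inside one optimization step (cycle and identity
terms) before any backward pass. Generator and discriminator optimizers each
step only their own parameters; cross-contaminated gradients are zeroed
before the other side's update, which the test suite verifies bit-exactly.

## Evaluation

MAE is computed in HU over the body mask (evaluating air trivially rewards
any method; a whole-image mode remains available). SSIM and PSNR are
computed on [0, 1] images with data range 1.0: PSNR = 10·log₁₀(1/MSE),
capped at 100 dB for identical images; SSIM uses an 11×11 Gaussian window
(σ = 1.5, K₁ = 0.01, K₂ = 0.03), averaged over full-window positions, or
over a mask when one is given. Cross-validation splits **by subject**
(never by slice) into k seeded near-equal folds; each fold is evaluated
with models trained on the others, alongside the raw-CBCT baseline, and
aggregated as median (interquartile range). Model comparison uses the
tie-corrected Kruskal–Wallis test per metric and, when p < α = 0.01,
pairwise Tukey–Kramer-type decisions on mean ranks with studentized-range
critical values.

## Desk-scale study conditions

The test suite trains on 200 paired 64×64 phantom slices from 20 subjects
(10 slices each, 80/20 train/validation split), corrupted with a fixed
operator: gain 1.1, offset 40 HU, cupping 60 HU, noise 10 HU — the
unsupervised variant additionally enables gas-cavity mismatch. Runs last
5 epochs at batch size 10.

- **Supervised recovery** uses the residual generator with channels
  (16, 16, 32, 32, 32) and the reference optimizer (ADAM, 2·10⁻⁴, 0.5,
  0.999); the checkpointed model must cut the body-masked validation MAE to
  below half of the raw-CBCT baseline (≈22 HU → ≈10.5 HU in practice; the
  residual noise floor of E|N(0, 10 HU)| ≈ 8 HU bounds what 80 steps can
  remove).
- **Unsupervised recovery** uses residual generators with channels
  (8, 8, 16, 16, 16), a (8, 16, 32, 32) discriminator, generator lr 5·10⁻⁴,
  discriminator lr 2·10⁻³ with 15 discriminator steps per generator step.
  The adversarial channel is the only source of correction here (cycle and
  identity terms are satisfied by the identity map), and a discriminator
  needs several hundred updates before it reliably detects the ~1%
  normalized-intensity domain gap; at the reference schedule the whole
  system provably idles at its initial state for 5 toy epochs. The k-step
  discriminator schedule and the enlarged step sizes are therefore the
  desk-scale operating point; at reference scale (thousands of steps) the
  defaults revert to the 1:1 schedule and lr 2·10⁻⁴. The checkpointed G_CT
  must bring validation MAE below the raw-CBCT baseline and must preserve a
  held-out mismatched gas cavity (the sCT cavity mean must stay closer to
  the CBCT's gas than to the CT's tissue) — the anatomy-preservation
  behaviour that motivates unsupervised training.

## Numerical choices and degenerate inputs

- HU window [−1024, 3200] everywhere; normalization range 4224 HU.
- BCE probabilities clamped to [1e−7, 1−1e−7]; instance-norm ε = 1e−5;
  residual logit clamp 1e−4.
- PSNR cap 100 dB at MSE = 0; Kruskal–Wallis on all-tied data returns
  p = 1 (no rejection) instead of failing.
- Max pooling requires even spatial sizes; generator inputs must be
  divisible by 2^(levels−1), discriminator inputs by 8.
- Ties in max pooling resolve to the first occurrence (argmax convention).
- All randomness flows from integer seeds through `numpy.random.Generator`;
  identical seeds reproduce loss histories bit-for-bit.

## Known limitations

- Training is NumPy on CPU; reference-scale (256×256, 25-epoch) runs are
  supported but slow — the package's quantitative claims are desk-scale.
- The degradation operator is additive/radial; it does not model streaks,
  motion, or projection-domain scatter.
- 2D slice-wise only; no 3D context, no DICOM-RT, no dosimetry.
- The unsupervised desk-scale improvement is driven by a brightness-scale
  domain gap; richer anatomical domain gaps need longer schedules than the
  toy budget allows.
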