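# Methods

`braincae` implements a diagnostic-label-free feature-extraction
pipeline for structural gray-matter (GM) volumes: a family of 3D
convolutional autoencoders (CAEs) is trained to reconstruct
standardized GM maps, the encoder's latent activations are used as
subject-level features, the features are evaluated by ridge regression
against clinical/demographic targets and compared with an ROI-averaging
baseline, and gradient saliency maps localize what drives a
prediction.  This note documents the model, the numerical choices, the
synthetic phantom that stands in for real MRI, and what the shipped
tests do and do not establish.

## Input model and standardization

A subject enters the pipeline as a smoothed, modulated GM
probability/volume map on a shared grid with a binary GM mask (the
full-scale standard-space grid at 1.5 mm spacing is 121 x 145 x 121
voxels; re-gridding the 91 x 109 x 91 / 2 mm field of view at 1.5 mm
gives exactly these counts).  Before training, each volume is
standardized per subject:

    x'_i = (x_i - mu) / sigma   for i in the GM mask,   0 otherwise,

with mu and sigma the mean and *population* SD over mask voxels only.
The population/sample-SD choice is immaterial at the voxel counts
involved (>= hundreds) but is fixed and documented here.
Standardization is idempotent on its image and invariant to positive
affine rescaling of the in-mask intensities; volumes that are constant
inside the mask are rejected rather than silently zeroed.

## Architecture family

The grid has two axes: the number of blocks B in {1,2,3,4} and the
extraction-layer channel count C in {1,4,16,32} — 16 configurations.
A block is two 3x3x3 stride-1 zero-padded convolutions (ReLU, 32
channels) followed by 2x2x2 stride-2 average pooling; after B blocks an
extraction pair (conv to 32, conv to C, both ReLU) emits the latent
map.  The decoder mirrors the encoder: an entry pair (conv C->32,
conv 32->32), then per block nearest-neighbour unpooling and two
convolutions, the very last convolution mapping to one channel with a
*linear* output (standardized targets are negative half the time; a
ReLU there would clip them).  Reading the architecture this way makes
the 3-block encoder exactly eight convolutional layers and gives an
effective receptive field of 68 voxels per axis, both of which are
checked in the tests (the receptive field twice: by the closed-form
recursion rf += (k-1)*jump, jump *= stride, and by backpropagating a
one-hot latent gradient through an all-positive-weight encoder and
measuring the gradient support).

Pooling uses ceil semantics (odd extents are implicitly zero-padded,
the divisor stays 8), so odd grid axes such as 121 and 145 round-trip;
the decoder output is center-cropped to the input grid.  Unpooling
replicates each value into its 2x2x2 cell — with average pooling there
are no argmax switches, and replication is the adjoint-consistent
choice.  Latent features are taken after the extraction layer's ReLU
and flattened channel-major (channel, then x, y, z); the order is
serialized with every feature matrix.

## The conv-net core

No deep-learning framework is part of the dependency set; the network
core is a self-contained NumPy implementation.  Convolutions are
lowered to one BLAS GEMM per layer via an im2col unfolding built from
a zero-copy strided view; the backward pass is the exact adjoint
(weight gradients from the cached unfolding, input gradients as a
flipped-kernel convolution of the output gradient, which stays on the
GEMM fast path).  Everything is float32, channel-major
(C, B, D, H, W), and deterministic given the weight seed.  Weight
gradients were verified against central finite differences on random
weights and inputs; the receptive-field probe doubles as an
independent check of the backward geometry.

## Training

The loss is the mean absolute error (MAE) over *all* voxels of the box
— background included, matching the unqualified sum in the training
objective; a mask-restricted variant exists behind a config flag.  The
optimizer is Adam (alpha 1e-4, beta1 0.9, beta2 0.999) on shuffled
mini-batches of 8, up to a configured iteration cap (reference value
50,000); "maximum iterations plus validation monitoring" is read as
best-validation checkpointing: training always runs to the cap and the
weights with the lowest validation MAE are returned.

The reference level for reconstruction is the **average brain**: the
voxelwise mean of the training volumes, i.e. the best
input-independent predictor.  Its MAE on any evaluation set is a pure
data statistic, logged once per set alongside every learning-curve
record.  A model below that level has, by construction, encoded
individual differences.

### Initialization

Plain fan-in (He) initialization fails for this architecture family in
a specific, reproducible way: average pooling attenuates weakly
correlated activations by up to sqrt(8) per block, so with 2+ blocks
the deep decoder layers start in, or are quickly pushed into, the
all-dead ReLU regime, from which no gradient returns — training then
converges to a constant output.  `CAE.calibrate_init` therefore runs
once before training and applies three standard remedies:

1. LSUV-style variance scaling: each hidden convolution's weights are
   rescaled for unit pre-activation SD on a sample batch;
2. a small positive bias (0.05) on every hidden convolution;
3. a zero-initialized final reconstruction layer, so the output starts
   exactly at 0 where the absolute-error loss is flat for background
   voxels (sign 0): the head first grows as a linear probe on live
   decoder features, and upstream layers only move once an output path
   exists.  This removes the early uniform-shrink transient that
   otherwise kills decoder ReLUs.

With this initialization, training at the reference Adam settings
shows the expected phases on phantoms: a warm-up of a few hundred
iterations while the head grows, a fast descent as the shared anatomy
is learned, then a slower descent below the average-brain level as
individual structure is encoded.  Narrow configurations (one
extraction channel) have a much longer warm-up at desk scale — their
single latent channel receives weak, noisy gradients — which is why
the per-configuration smoke tests of the training loop use a live
(scaled) head and a larger test-scale step size, which put short runs
in the immediately-descending regime, and assert a decreasing trend.

## Phantom cohorts

The phantom module generates cohorts of GM-like volumes with fully
known structure.  A subject's volume is an ellipsoidal cortical shell
(outer semi-axes 0.44 x grid, relative thickness 0.35 — roughly a quarter of the box, GM-like) carrying:

* baseline intensity 0.6 inside the shell;
* a **shared anatomy field**: smooth Gaussian random field (FWHM
  32 mm), amplitude 0.15, identical for all subjects — the analogue of
  common cortical anatomy, representable by the average brain;
* a **subject random field**: smooth field (FWHM 48 mm), SD = 1.5 x
  `noise_sd` per subject — individual anatomical variability,
  spatially coherent and hence compressible by a CAE but invisible to
  the average brain.  Without such a component the benchmark is
  degenerate: after per-subject standardization a flat shell plus
  i.i.d. noise has near-zero per-voxel cross-subject mean, the
  absolute-error gradient carries almost no consistent signal, and the
  average brain is essentially unbeatable;
* a scalar subject intercept (SD = 2.0 x `noise_sd`; removed again by
  standardization, kept for realism of the raw maps);
* planted spherical covariate effects: by default a dose sphere
  (slope 2e-3 intensity per CPZE-mg, i.e. a ~0.2 intensity swing over
  the dose range against the 0.6 baseline) and a weaker negative age
  sphere, both centred on the shell;
* i.i.d. voxel noise (`noise_sd`, default 0.05), Gaussian smoothing to
  8 mm FWHM (sigma = FWHM/2.355 converted to voxels), exact zero
  outside the mask.

Every stochastic subject component scales with `noise_sd`, so
`noise_sd=0` yields bit-identical volumes (given one site and no
effects).  Sites shift the global intensity scale (x1.12 for the
second site) and thicken the shell by one voxel — a deliberately crude
two-site shift, not scanner physics.  Covariates: age ~ U(20, 65),
diagnosis ~ Bernoulli(0.5); patients additionally get dose and
positive/negative symptom scores driven by a shared latent severity,
and onset/duration consistent with age.  Patient-only fields are NaN
for healthy subjects, as in a real clinical table.

What the phantom does *not* emulate: real anatomy, tissue
segmentation, registration error, scanner artifacts, site effects
beyond the two knobs above.  Tests passing on phantoms therefore
establish that the pipeline's machinery is correct and that its
statistics behave as designed — not that any specific empirical result
transfers to real MRI.

## Evaluation harness

Ridge regression (penalty 1.0 by default; the reference work does not
state its penalty) with fivefold cross-validation repeated ten times;
feature columns are standardized with training-fold statistics only.
Continuous targets are scored by RMSE, the binary diagnosis by
accuracy of the 0.5-thresholded prediction.  Clinical targets exist
for patients only; callers restrict rows first.  Architecture grids
are compared by two-way fixed-effects ANOVA (channels x blocks, with
interaction) on the ten per-repeat mean scores per cell, with Tukey
HSD within each factor; a feature set is compared to the ROI baseline
by an unpaired equal-variance t-test on the repeat means (alpha 0.05).
The ANOVA/Tukey/t-test path is statsmodels/scipy behind the module
surface, and the tests pin it to hand-written sums-of-squares and
pooled-variance arithmetic at 1e-10.

The ROI baseline averages post-standardization intensities over the
parcels of an integer-labelled atlas intersected with the subject's GM
mask (116 parcels in the reference atlas).  In phantom mode a
Voronoi-style partition of the shell into a configurable parcel count
replaces the atlas file.

## Saliency

For a fitted ridge model R and frozen encoder S, the subject-level map
is the gradient of R(S(x)) with respect to the input volume, averaged
over `n_noise` Gaussian perturbations of the input (SmoothGrad-style;
defaults: noise SD = 0.1 x the subject's in-mask intensity SD,
n_noise = 25, seedable — the reference work states neither value).
Since R is linear, its latent gradient is the coefficient vector
rescaled by the feature standardization; that vector is reshaped to
the latent grid and backpropagated through the encoder.  Group maps
are voxelwise |mean / SD| across subjects (population SD, absolute
value last); zero-SD voxels are set to 0 and counted.  Non-linear
regressors are rejected rather than approximated.

## Desk-scale study conditions

The trained-model tests run one shared configuration: a two-site
phantom cohort of n=60 (42 primary-site subjects split 30/6/6, 18
transfer-site subjects) on a 12 x 16 x 12 grid at 12 mm spacing, and a
2-block/16-channel CAE trained for 2000 iterations at the reference
Adam settings.  These sizes are the package's chosen desk-scale
conditions: they keep a full training run in the minutes range on one
CPU core while the shell, the planted spheres, the two-site shift and
the latent bottleneck (16 x 3 x 4 x 3 = 576 features from 2304 voxels)
all remain resolvable.  The acceptance checks on this configuration
are qualitative reproductions: validation and transfer-site MAE below
the respective average-brain levels, planted-dose recovery by ridge on
latent features against a permutation null, and >2x enrichment of the
top-percentile saliency voxels inside the planted sphere.

## Known limitations

* The NumPy conv-net core is single-threaded GEMM-bound; full-scale
  (121 x 145 x 121) training is possible in memory but slow — the
  package's scope is the method and its desk-scale validation, not
  large-scale training throughput.
* Absolute-error training of deep ReLU autoencoders has a genuinely
  slow warm-up phase; at desk scale the 1-channel extraction models
  barely leave it.  This is a property of the objective (sign
  gradients weight the 85% background as heavily as the tissue), not
  of the implementation.
* Saliency maps inherit SmoothGrad's edge emphasis; no edge correction
  or anatomical labelling of peaks is attempted.
* The phantom's site shift is a two-parameter caricature; transfer
  results on it say nothing about real scanner harmonization.
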