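# Methods

## Problem and models

The package classifies mild cognitive impairment (MCI, positive class)
against healthy controls from two imaging modalities: T1-weighted
structural MRI volumes registered to a 192×192×182 grid, and resting-state
MEG magnetometer segments of 102 sensors × 8,192 samples at 500 Hz,
band-limited to 0.5–98 Hz. Five models are implemented.

**Branches.** Both feature extractors are residual CNNs with a constant
channel width C (default 16). The MEG branch stem is a 1×15 convolution
applied along time within each sensor row (stride (1,2)) followed by a 3×3
convolution mixing adjacent sensor rows; the residual blocks stride only
the time axis with schedule (2,2,2,4), giving a total time downsampling of
64 (8192 → 128) while the sensor axis stays at 102. The MRI branch stem is
a 7×7×7 convolution (stride 2) and the blocks stride (2,2,1,1), giving
192 → 24 per axis. Residual blocks are conv–norm–ReLU–conv–norm plus a
projected shortcut where the shape changes. Constant width was chosen so
the branch output shapes are exactly (C, 102, 128) and (C, 24, 24, 24) for
any configured C; the schedule is configurable, and any schedule with the
same stride product is accepted.

**Normalization.** The full-size default is instance normalization
(per-sample, per-channel), which keeps batch-size-2 training stable.
A caveat discovered while building the reduced benchmarks: per-sample
normalization of each channel *removes that channel's energy*, which is
precisely the feature that carries a band-power class effect in MEG. With
large inputs the information survives through spectral-shape interactions,
but at reduced scale it does not; the reduced configurations therefore
default to batch normalization, and the norm is a per-config choice
(`instance | group | batch`).

**SCCAF.** The fusion module takes the two branch feature maps. MMPE
applies adaptive average pooling to output grids (64,64) and (16,16,16) —
the only reading under which both modalities produce the same token count
P = 4096 — flattens spatial positions into P×C token matrices, applies a
per-channel scale+bias (the kernel-size-1 depth-wise projection) and adds a
learned P×C positional embedding per modality (on by default, off in the
oracle tests). SCA computes Z_a = softmax(Q_b K_aᵀ/√C) V_a with queries
mapped from the MRI tokens and keys/values from the MEG tokens, and
symmetrically Z_b; the six Q/K/V maps are bias-free linear layers, and the
softmax scale is √C (single head; the head count is configurable, with
per-head scale √(C/h)). CFA concatenates (Z_a, Z_b), applies a two-layer
MLP (hidden width 2C) producing one logit pair per (token, channel), and a
softmax over the pair yields weights on the 2-simplex that convexly mix the
*MMPE token matrices* (so all operands share the P×C shape); a per-channel
variant that averages logits over tokens is available. The weight matrices
are therefore C×N with N = P by default — the token-resolved reading of the
reference weight shape, adopted without claiming the original intent.

**Heads and strategies.** Every classifier head is adaptive-pool to the
token grid → flatten → linear (hidden 16) → ReLU → linear (2 classes);
softmax lives inside the loss. InterFusion feeds the fused P×C tokens to
one head; LateFusion gives each branch its own head and fuses the 2+2
logits with a final linear layer; EarlyFusion resizes the MEG image to the
volume's in-plane grid and mean-projects the volume along z, stacking both
as a 2-channel 2D input to one small backbone (a 3D variant broadcasting
the MEG image along z is available; neither is claimed canonical — the
shared input space is genuinely unspecified upstream). The flatten-based
head (rather than global average pooling) is what reproduces the reference
complexity ordering params(Early) < params(Inter) < params(Late): late
fusion pays for two full-width per-modality classifiers, intermediate
fusion for one classifier plus the comparatively small attention module.

**Loss and training.** Cross entropy L = Σ p log(1/q) (batch-averaged) on
softmax probabilities; Adam with lr 0.001, batch size 2, weight decay
0.0001, 100 epochs — the reference protocol, kept as `TrainConfig`
defaults — with stratified 5-fold cross-validation (stratified by group;
optionally group×site), final-epoch weights (no early stopping is
specified upstream), and per-fold derived seeds. Metrics are computed from
the confusion counts at a 0.5 threshold on the MCI-class probability;
degenerate ratios return 0 with a warning. ROC uses a tie-grouped
threshold sweep with trapezoidal AUC (equal to the Mann–Whitney
concordant-pair fraction, ties half-weighted); PR uses step-wise average
precision. Method comparisons use a paired t-test on fold-wise accuracies
with Bonferroni adjustment m = number of comparisons, all-zero differences
giving p = 1 and constant nonzero differences flagged degenerate.

## Neural-network substrate

All layers are implemented in NumPy with explicit backward passes
(im2col + BLAS matmuls for convolutions; the backward input-scatter loops
only over kernel offsets). Correctness is established by central
finite-difference checks on every layer and on the assembled fusion module.
Activations are float32; intermediate buffers are cached only in training
mode, so full-resolution inference stays within a few hundred MB.
Determinism holds run-to-run on one machine; bit-exactness across BLAS
implementations is not promised.

## Synthetic cohort generator

The generator emulates the *outputs* of the upstream acquisition chain, not
the chain itself (no signal-space separation, artifact rejection or
diffeomorphic registration).

* **Metadata.** Per-group marginals follow the reference summary: site and
  sex as Bernoulli draws (91/75 vs 68/90 and 82/84 vs 80/78 at the
  marginal counts 166/158), and age, education, MMSE and recording duration
  as truncated normals (MMSE in [0,30], duration ≥ 120 s). The location
  parameter of each truncated normal is solved so the *truncated* mean
  equals the declared mean — without this, the MMSE bound at 30 biases the
  HC mean by ~0.3 points. The reference marginal counts (166/158) exceed
  the post-exclusion counts (163/144); both are exposed and deliberately
  not reconciled.
* **MEG.** Per-sensor pink (1/f) noise synthesized in the Fourier domain
  and band-limited to 0.5–98 Hz, plus a 10 Hz alpha component and a weak
  oscillation at the effect-band center. The MCI effect multiplies the
  Fourier coefficients inside the chosen band by √ratio, so band *power*
  scales by exactly the requested factor (up to window leakage in a Welch
  estimate — the ensemble check recovers a ratio of 2 within a few
  percent).
* **MRI.** Smoothed white noise (Gaussian kernel, σ = 3 voxels by default)
  normalized to unit interior voxel SD. The MCI effect subtracts
  d × SD(region mean) inside an axis-aligned box, where the sampling SD of
  the region mean is computed exactly from the separable kernel
  autocovariance; a two-sample Cohen's d on region means therefore
  recovers d (checked within 0.15 on a 500-per-group ensemble).
* **Seeding.** One integer seed; subject i draws from SeedSequence streams
  (seed, i, domain) with domain 0/1/2 for metadata/MEG/MRI. Identical
  arguments give bit-identical outputs; null effects make the groups
  identical in law.

What the generator does *not* emulate: artifacts, sensor covariance
structure, site/scanner batch effects, anatomical structure, per-subject
effect-size variability (every MCI subject receives the identical effect).
Consequently the benchmarks certify that the pipeline can *recover
designed, homogeneous effects* — they say nothing about real-data accuracy,
and real-data accuracy figures are out of scope here.

## Reduced-scale benchmarks

Full-size 100-epoch training is a cluster job; the packaged benchmarks are
scaled to minutes on one CPU while keeping the study's logic. Shapes:
16 sensors × 512 samples (~1 s at 500 Hz) and 24³ voxels with an 8³ effect
box; models use C = 8, two residual blocks per branch, token grid
P = 8×8 = 4×4×4 = 64, batch normalization; training uses Adam at the
reference lr and weight decay with batch size 8 for 8 epochs.

* **Complementary-signal benchmark** (150 subjects per group): MRI region
  deficit d = 1 and MEG high-gamma power ratio 1.6 — each modality carries
  a partial, independent signal (the MRI Bayes ceiling is ≈0.75 accuracy,
  the MEG signal is strong but spectrally narrow). The acceptance check is
  the ordering: fused mean 5-fold validation accuracy ≥ each unimodal
  model.
* **Separable benchmark** (60 per group, d = 2, ratio 3): a learnability
  smoke test — training accuracy ≥ 0.9 within a few epochs.

## Numerical choices and conventions

* Yates continuity correction is clamped, max(|O−E|−0.5, 0), so a
  zero-deviation table scores exactly 0; this convention reproduces the
  reference 4.04/0.01 and coincides with scipy when no cell deviation is
  below 0.5. Continuous rows use the pooled-variance two-sample t (Welch
  optional); the reference continuous statistics reproduce at the
  post-exclusion counts 163/144.
* Band edges: delta 2–4, theta 4–8, alpha 8–12, beta 12–30, low gamma
  30–48, high gamma 52–86, broadband 0.5–98 Hz. Filtering is a 4th-order
  Butterworth applied forward–backward (zero phase, order configurable);
  band-wise analyses re-filter the broadband signal. Resampling is
  polyphase with anti-aliasing.
* Volume padding 182 → 192 zero-pads the third axis, split evenly with the
  odd voxel trailing, shifting the affine origin so world coordinates are
  preserved; the center crop is an exact inverse.
* FLOPs are counted as 2 × multiply-accumulates for conv/linear/attention
  at actual output shapes plus bias additions; normalization, activations
  and pooling are excluded, and the convention tag is embedded in every
  report. Absolute reference FLOP/parameter values depend on an unstated
  counting tool and channel width, so only ordering and ratio relations
  are asserted.
* Degenerate inputs: constant arrays normalize to zeros; zero-variance
  paired differences give p = 1 (all-zero) or a degeneracy flag;
  single-class label sets make ROC/PR an error rather than a silent NaN.

## Known limitations

* The strip-convolution stem shares one 1×15 kernel set across sensor
  rows; a per-sensor (depth-wise over sensors) variant is not implemented.
* Batch normalization aside, no regularization beyond weight decay — no
  augmentation, dropout or early stopping, mirroring the reference
  protocol.
* The attention softmax scale follows the standard √C form.
* CPU-only; no attempt at multi-head efficiency or sparse attention.
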