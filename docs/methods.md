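# Methods

## Signal model

Every stage rests on the two-compartment (bi-tensor) model of the diffusion
signal.  A voxel's measurement at weighting `b` along unit direction `g`
mixes tissue and free water:

    S(b, g) = S0 [ (1 − f) exp(−b gᵀ D g) + f exp(−b D_iso) ]

with `f ∈ [0, 1]` the free-water volume fraction, `D` the symmetric PSD
tissue tensor, and `D_iso` the free-water diffusivity, fixed at
3.0·10⁻³ mm²/s (the body-temperature value; configurable).  At `b = 0` the
model returns `S0` exactly.  Because `D`'s eigenvalues are well below
`D_iso`, the compartments decay at different rates and are only reliably
separable when several b-values are measured; single-shell separation is
ill-posed and is the regime the learned estimator addresses.

## Phantom generator

`generate_phantom` draws, per voxel, a prolate tissue tensor (FA uniform in
[0.2, 0.9], MD uniform in [0.5, 0.9]·10⁻³ mm²/s, random orientation) and a
fraction field.  The default field emulates a tissue–CSF interface: a
smooth sigmoidal ramp from 0 to 1 across the last axis (so every
partial-volume fraction occurs) on top of a mild background contamination
f ∈ [0, 0.2], lightly low-pass filtered for spatial coherence.  Directions
are quasi-uniform per shell via antipodal electrostatic repulsion from a
seeded Fibonacci start, regenerated per seed (minimum pairwise angle at 90
directions is well above 5°).  The default acquisition mirrors a
research-grade HARDI protocol: shells {1000, 2000, 3000} s/mm², 90
directions each, 18 interleaved b0s.  Noise is Rician —
`sqrt((S+n₁)² + n₂²)` with `n ~ N(0, (S0/SNR)²)` — because magnitude MR
data is Rician; SNR is referenced to S0 and defaults to 30 for training
phantoms, a mid-range value for preprocessed research data (the phantom's
noise level is a package choice, not a measured property of any cohort).

What the phantom does *not* emulate: crossing fibers (one tensor per
voxel), spatial correlation of tensor orientations, eddy/motion/
susceptibility artifacts, Gibbs ringing, or the spatially varying noise of
parallel imaging.  Tests passing on phantoms therefore validate the
algorithmic contracts (model inversion, equivariance, training mechanics),
not clinical performance.

## Multi-shell fitting (silver standard)

`fit_dti` is the classical two-pass weighted least squares on the
log-signal (OLS pass, then weights equal to squared predicted signals);
nonpositive signals are floored at 10⁻⁶·S0 before the log.  FA/MD come from
the eigenvalues clamped at zero.

`fit_fwdti` fits `(f, D)` per voxel by trust-region nonlinear least squares
(scipy `least_squares`) on the normalized signal with `D_iso` fixed: `f` is
box-constrained to [0, 1] and `D` is parameterized by its Cholesky factor,
which preserves PSD without constraints.  Initialization: `D` from the
plain DTI tensor with eigenvalues clipped to [0.1, 2.4]·10⁻³ mm²/s, and `f`
by placing the voxel's DTI MD linearly between a tissue reference MD
(0.6·10⁻³) and `D_iso`, clipped to [0.05, 0.95] — this avoids the f↔MD
degeneracy trap.  A small multi-start over f (initial guess plus 0.1, 0.5,
0.9) guards against local minima; the best residual wins.  Tolerances are
xtol=ftol=gtol=10⁻¹², max 400 evaluations; a voxel that fails outright is
flagged and keeps its initialization.  Single-shell input raises an
ill-posedness error pointing to the learned estimator.

After fitting, the MD-threshold regularization runs: voxels whose plain-DTI
MD exceeds 2.7·10⁻³ mm²/s (approximately the free-water diffusivity) are
assumed pure free water — f := 1, tissue tensor := 0, flag := thresholded.

## Harmonization

Off-scheme shells are recalibrated under the linear-decay approximation
(log-signal linear in b for 500 < b < 1500 s/mm²):
`S_bnew = S0 exp((b_new/b_orig) log(S_b/S0))`, exact for mono-exponential
decay.  A remap is accepted when either endpoint lies in (500, 1500], which
admits the 1500→1000 and 700→1000 recalibrations used for aging and
clinical protocols; upward extrapolation from below 500 warns.  When two
shells sit at or below 1500 only the lowest is remapped and the rest are
dropped with a warning (their recalibration would collide) — a documented
choice the caller can override by remapping shells individually.
Normalization divides by the voxelwise mean b0 signal and clips to
[10⁻⁶, 1.5]; remapping always precedes spherical-harmonic fitting, and
remapped measurements keep their directions.

## Feature representations

Per present shell, the normalized signal is expanded in the real,
antipodally symmetric (even-degree) spherical-harmonic basis up to degree
8 — 45 coefficients per shell, ordered degree-major with m from −l to l
(m<0 ↦ √2·Im Y_l^|m|, m=0 ↦ Y_l⁰, m>0 ↦ √2·Re Y_l^m).  This ordering is
part of the checkpoint contract.  Shells with at least 45 well-spread
directions are fit unregularized; sparser shells get a Laplace–Beltrami
penalty (weight 6·10⁻³) for conditioning.  Absent shells contribute
zero-filled blocks, and the K-bit shell code records which blocks are real;
zero-filling provably equals the features of genuinely single-shell data.

The SHORE baseline uses the order-6 3-D SHORE basis (50 coefficients:
generalized-Laguerre radial functions times real spherical harmonics) with
Tikhonov regularization 10⁻⁸ and radial scale ζ = 1/(8π²τ·MD), MD from the
voxel's DTI fit (nonpositive MD falls back to 0.7·10⁻³ with a warning).
τ defaults to 0.025 s when acquisition timing is unknown; it only scales ζ
and is recorded in the features.

The raw-signal ANN input is the first 6 normalized b0 values followed by
the shell's directional measurements — N_b = 96 for a 90-direction shell.
The 6/90 split is a package contract (the baseline's input composition is
not otherwise determined).

## The spherical network

The estimator is exactly rotation-invariant by construction.  All
equivariant algebra happens in SH coefficient space:

* **Dynamic first (S²) layer.**  A two-layer perceptron maps the K-bit
  shell code to a positive scaling matrix (2·sigmoid, zero-initialized ⇒
  scaling ≡ 1 at start) applied multiplicatively to a learned base kernel.
  The layer itself mixes the K shell channels per degree.  Identical codes
  always produce identical kernels; the scaling form keeps the head's
  parameter count linear in K.
* **SO(3) and restricted generalized convolutions.**  In coefficient space
  a group convolution is a per-degree linear mix of channels (one weight
  matrix per degree, shared across orders m — Schur's lemma); layers
  differ only in their channel counts and degree caps.
* **Tensor-product activations.**  The feature is synthesized on a
  Gauss–Legendre × uniform-azimuth grid whose quadrature is exact to
  degree 2·L_in + L_out, mapped through g ↦ g + g² pointwise (the
  channel-wise tensor product with itself, with the linear term kept so
  sign information survives), and projected back to degrees ≤ L_out.
  Exact quadrature makes the layer exactly equivariant; truncation removes
  whole degrees, which is also equivariant.
* **Restricted batch normalization.**  Each (channel, degree) fragment is
  divided by the running batch average of its norm and multiplied by a
  learned gain — scaled, never translated, so equivariance is preserved
  (ε = 10⁻⁵, momentum 0.1).
* **Invariant head.**  Degree caps fall as (8, 8, 10, 6, 2, 0) — the
  even-degree realization of the bandlimit schedule (20, 10, 10, 6, 3, 1)
  for a degree-8 input — while channels grow (K, 20, 22, 24, 26, 28).  The
  rotation-invariant (degree-0) fragments of every stage, including the K
  per-shell input means (the most fraction-informative invariant), are
  concatenated and passed through fully connected layers (default widths
  64, 32, 1) with a sigmoid output in [0, 1].

L1 regularization (strength 10⁻⁵) applies to convolution weights only,
never the FC head or the normalization gains.  Float32 is the working
precision; the rotation-invariance error of the forward pass is at the
float32 rounding level (~10⁻⁶), far below the 0.02 acceptance band used
for trained-model probes.

The ANN baseline is the 4-layer FCN (N_b → N_b/2 → N_b/4 → 1) with batch
normalization and dropout 0.1; the SHORE baseline is 50 → 100 → 50 → 1.
All three models are pure functions of (input, checkpoint) in evaluation
mode.

## Training

The loss is RMSE.  Each batch of the spherical network draws a shell code
from a distribution over the 2^K − 1 = 7 valid configurations (uniform by
default) and zeroes the corresponding feature blocks — shell-configuration
dropout, which is what lets one network serve every acquisition subset.
Optimization is Adam (lr 10⁻³, batch 256) with cosine learning-rate decay
across the run; these are package defaults, logged into every checkpoint.
Train/validation splitting is by contiguous voxel blocks (group size 64) so
spatially correlated neighbours do not straddle the split.  Validation RMSE
of the spherical network is averaged over all 7 codes; the returned
checkpoint is the best-validation epoch, and early stopping uses patience
10.  Targets are true fractions on phantoms and silver-standard fractions
on real data.

Fine-tuning updates the fully connected head only: every other parameter —
convolutions, the dynamic head, normalization gains and running statistics —
is verified bit-identical by SHA-256 before/after (a mismatch is a hard
error), and the best checkpoint is seeded with the untrained-on-this-data
model so adaptation can only improve validation RMSE.

## Correction and evaluation

`eliminate_free_water` subtracts `S0 f exp(−b D_iso)` per measurement;
at b=0 this yields Ŝ0 = S0(1−f), and downstream fits on corrected data use
that corrected b0, keeping normalization self-consistent.  Negative results
(possible under Rician noise) are floored at zero and counted.

Evaluation: fraction RMSE over a mask; FA/MD mean ± sd in a centered cubic
ROI (clipped to the volume with a warning); 100-bin histograms (FA on
[0, 1], MD on [0, 3.5·10⁻³]); scan–rescan percentage difference per region,
`100 |m₁ − m₂| / ((m₁ + m₂)/2)` — absolute, with the symmetric session-mean
denominator (first-session denominator available as an option).

## Problem sizes and reproducibility

The reference experiments (tests and `scripts/acceptance.py`) use a
40×40×32 (~51k-voxel) SNR-30 phantom for estimator training (20 epochs),
a ~1.2k-voxel noiseless phantom for silver-standard recovery, a 16³
phantom with 1500/3000 s/mm² shells (1500 remapped to 1000) for
fine-tuning, and 500 voxels for the rotation probe — sizes chosen so a
full pass completes in minutes on one CPU while leaving each mechanism
clearly measurable.  All randomness flows from explicit integer seeds;
repeated runs are bit-identical.

## Known limitations

* Single-tensor tissue compartment: no crossing-fiber or multi-compartment
  microstructure; estimator accuracy on real brains is bounded by the
  silver standard used as its target.
* The linear-decay remap is approximate for non-mono-exponential tissue;
  700→1000 recalibration extrapolates beyond its validated range.
* The learned estimator only conditions on subsets of its K training
  shells; genuinely different b-values must be remapped first, and shells
  outside (500, 1500] cannot be.
* Training at desk scale (~50k voxels, one phantom) demonstrates the
  mechanism; production use would train on orders of magnitude more voxels
  across subjects.  At this size the single-shell accuracy difference
  between the spherical network and the raw-signal ANN baseline (~0.001–
  0.003 RMSE) is comparable to the spread across phantom seeds, so their
  ordering can flip from seed to seed; the packaged experiments use a fixed
  seed and report the measured values.
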