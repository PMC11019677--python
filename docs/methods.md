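# Methods

`sirenstack` represents a fluorescence z-stack as a continuous field
Φ: ℝ³ → ℝ learned by a sine-activated multilayer perceptron (a SIREN), and
uses that representation for two tasks: unsupervised correction of
intra-frame motion artifacts from repeated acquisitions, and prediction of
z-planes omitted at acquisition time.  This note records the model, the
parameters that matter, the synthetic data the package is evaluated on, and
the numerical choices behind the defaults.

## The coordinate network

The network is

    Φ(x) = W_n (φ_{n-1} ∘ … ∘ φ_0)(x) + b_n,
    φ_i(x_i) = sin(ω0_i · W_i x_i + b_i),

with three hidden layers of 128 units by default, ω0 = 32 on the input
layer and 34 on hidden layers, and a linear output head.  ω0 multiplies the
matrix product only; the bias enters unscaled.  Inputs are voxel centers
mapped affinely to [−1, 1] per axis; the z-coordinate is always computed
against the full stack extent so acquired and omitted planes share one
frame.  Intensities are percentile-normalized before fitting,

    y_norm = (y − P2) / (P99.9 − P2 + ε),   ε = 1e-20,

with no clipping; the inverse map is the only sanctioned path back to
acquisition units.  Training is full-batch Adam (β = 0.9/0.999, ε = 1e-8,
constant learning rate 1e-3) on the mean-squared error for a fixed number
of steps, with the sample re-shuffled each step; a `chunk_size` option
accumulates gradients over batch slices, which is arithmetically the same
update.  All arithmetic is float32.  The networks (SIREN, the baseline
correction CNN, and the denoiser) run on a small reverse-mode autodiff core
written for this package (`_autodiff.py`), gradient-checked against finite
differences in the test suite.

### Initialization, and a caveat about the literal scheme

The default initializer draws every layer's weights from
U(−√(6/n), √(6/n)) with n the fan-in, biases zero.  Applied to all layers
this makes the network map extremely stiff: ω0 is not compensated in the
hidden layers, so the composition has a Lipschitz constant of order
(ω0·‖W‖)³ ≈ 10⁶.  Volumetric image fits still work, but the configuration
cannot be optimized onto some simple targets — a pure 1-D sinusoid
sin(8πx) on 256 samples plateaus at the target variance.  The classic
sine-network scheme (first layer U(±1/n), later layers U(±√(6/n)/ω0)) is
available as `first_layer_init="classic"` and fits that target below 1e-6.
The representation-capacity test therefore uses the classic switch; the
literal scheme remains the default.

A second float32 effect: when full-batch Adam reaches extremely small
losses (~1e-7, only on toy problems) it can destabilize and jump out of the
minimum.  Capacity tests assert the minimum over the loss trace; image
fits never reach that regime.

### The phantom-scale profile

The stock hyperparameters are tuned for megapixel in-vivo stacks, where a
~50k-parameter network is 100×–400× underparameterized relative to the
training set.  That underparameterization is the mechanism of the method:
the fitted field regresses a smooth conditional mean, and uncorrelated
noise and motion artifacts are rejected because they exceed the network's
spectral budget.  On a 32-px phantom the same settings over-parameterize
and interpolate the noise instead, so every desk-scale experiment uses
`SirenConfig.for_phantom_scale()`: ω0 = 8 (matched to the phantom's spatial
band), the classic init, 175 steps (early stopping as the capacity control),
gradient chunks of 16384.  This is the package's scaled-down operating
point, calibrated once on the motion phantom and then frozen; all reported
trends were subsequently confirmed on held-out seeds.

## Motion correction

From R repetitions of one stack (R = 4 by default, matching standard
repeated acquisition) two training sets are built:

* **all** — every repetition contributes its full grid with identical
  coordinates.  Repetition identity is *not* an input: the network sees R
  conflicting targets per coordinate, and the MSE-minimizing field passes
  through their mean.  N = R·Z·Y·X.
* **sampled** — one target per voxel, drawn uniformly among the R
  repetition values.  N = Z·Y·X, exactly 1/R of the above, with
  proportionally faster training — the cost mechanism behind the two
  strategies' runtime difference.

The corrected stack is the fitted field evaluated on the full grid and
de-normalized.  Baselines: voxelwise averaging (naive, or restricted to
artifact-free repetitions per plane — on phantoms that mask comes from the
generator's artifact records), and a supervised 3-layer CNN (64/64/1
filters, 5×5 kernels, ReLU/ReLU/linear, SGD at 0.01 on MSE) trained on
(corrupt, clean) plane pairs; its inference input is the naive average of
the repetitions, the natural degraded observation.

## Interplane prediction

`select_planes(n, skip)` trains on planes {0, skip+1, 2(skip+1), …} and
predicts the omitted planes between them; trailing planes past the last
training plane would require extrapolation and are excluded from
evaluation.  The reference method is linear interpolation between the two
flanking training planes with weights (1 − k/(skip+1), k/(skip+1)).
Evaluation restricts deep stacks to their first 20 planes by default and
reports per-plane MSE/SSIM/PSNR (mean ± sd over planes) plus the
Fourier-spectrum MSE.

## Denoiser

A small U-Net-style 2-D encoder–decoder (filters doubling from 64 per
level by default, 2×2 max-pool, nearest-neighbour upsampling, skip
connections, linear 1×1 single-filter output) trained with Adam at 0.01,
batch 10, 100 epochs.  Its training inputs are SIREN reconstructions of
phantom acquisitions and its targets are the *noisy acquired* planes, not
the clean signal: the network learns to map the overly smooth SIREN output
back toward acquisition statistics.  Inputs are reflect-padded to the
pooling multiple and cropped back, so any plane size is legal.  Phantom
experiments use a scaled-down instance (8 base filters, 2 levels, 40
epochs), which already yields a consistent MSE improvement on interplane
predictions for up to three omitted planes.

## Evaluation metrics

MSE, PSNR (10·log10(range²/MSE), +∞ for identical images) and SSIM
(scikit-image, Gaussian-weighted 7×7 window — clamped to the image for
tiny test planes — K1 = 0.01, K2 = 0.03).  Unless given, the data range is
the joint max−min of the compared pair, since normalized-space images are
unbounded.  The Fourier-spectrum MSE compares per-plane linear DFT
magnitudes; by the shift theorem it is blind to translation, which is
exactly why it complements the spatial MSE for motion artifacts.

**Spine-recovery proxy.**  Spine counting through an external trained
segmentation model is out of scope, so recovery is scored geometrically
against the phantom's ground truth: candidates are Laplacian-of-Gaussian
local maxima (σ = 0.8 voxels) above the 98th percentile of the response
volume, greedily matched one-to-one to true spine centers within 3 voxels.
The detector was calibrated on clean phantoms (recovery ≥ 0.88, usually
1.0) before any cross-method comparison and then frozen.  It is a proxy:
absolute fractions are not comparable to counts from a trained
spine-segmentation network, but differences across methods and skips on
the same phantom are meaningful.

## The synthetic phantom

`generate_phantom` emulates a high-zoom two-photon acquisition of
GFP-labelled dendrites: smooth random centerline tubes (radius 2.2 vox)
carrying spines (head radius 1.6 vox on a thin neck, attached orthogonally
and mostly in-plane, since axially oriented spines are rarely resolvable at
a 1-µm z-step), rasterized as binary masks, blurred with a Gaussian PSF
(σ_z = 1.2, σ_xy = 0.8 vox), on a constant background.  Acquisition noise
is Poisson shot noise at `photon_scale` detected photons per unit intensity
plus Gaussian read noise; the default photon_scale = 12 reflects the low
single-frame SNR that motivates acquiring four repetitions in the first
place.  Motion artifacts shift a contiguous band of 60–90% of the rows by a
smooth raised-cosine lateral profile peaking at 60–100% of `max_shift_px`
(default 12 px) — a strong, clearly visible displacement of a large image
chunk, as intra-frame motion during resonant scanning produces.  Artifact
magnitude and frequency are free parameters of the generator (no published
quantification exists to pin them); the defaults above are the package's
frozen study conditions.

What the phantom does *not* model: realistic optical PSF anisotropy beyond
a Gaussian, photobleaching kinetics, scattering depth dependence, vascular
shadows, or the rich morphological variety of real dendrites.  Passing
trends on phantoms therefore demonstrate the mechanisms — mean-regression
artifact rejection, spectral-bias denoising, z-interpolation fidelity
decay — not performance on any particular in-vivo dataset.

## Study conditions and problem sizes

All experiments run on one CPU at deliberately small problem sizes, chosen
as the package's own desk-scale conditions:

| study | phantom | SIREN | notes |
|---|---|---|---|
| fidelity | 8×32×32, noise-free | stock config, 500 steps | train-grid PSNR ≥ 25 dB |
| motion correction | 16×32×32, photon_scale 12, artifact_prob 0.25 | phantom-scale, 175 steps | both strategies vs naive average on corrupted planes |
| data fraction | same | phantom-scale, 175 steps | 10% / 50% / 100% of sampled pixels |
| interplane | 17×32×32, σ_z = 2.5 | phantom-scale, 400 steps | skips 1, 2, 3, 7; linear baseline |
| denoiser | two sibling phantoms | 8 filters, 2 levels, 40 epochs | MSE benefit at skips ≤ 3 |
| spine recovery | 17×48×48, 10 spines, photon_scale 30 | phantom-scale, 400 steps | skip 1 vs 7 (detection at photon_scale 12 is noise-limited even on acquired data) |

Observed desk-scale behaviour worth noting: SIREN interplane MSE at skip 2
runs ≈ 1.4× the skip-1 value on these phantoms (the SSIMs agree within
25%); near-equality of the two holds only in SSIM terms here.

## Determinism

Every stochastic step takes an explicit seed; pipeline stages derive named
substreams from one global seed via SHA-256.  Two pipeline runs with the
same seed produce byte-identical metrics, stacks, and manifests (wall-clock
timings aside).  The provenance manifest records the package version, a
hash of the scientific configuration (output paths excluded), the seed, and
per-stage wall times.

## Known limitations

* The literal all-layers init is kept as the default for fidelity to the
  architecture description, despite its optimization pathology on sparse
  low-dimensional targets (above).
* The denoiser cannot reproduce a specific noise instance; its MSE benefit
  comes from correcting the systematic bias of SIREN reconstructions.
  Whether denoised outputs can surface more structure than the acquired
  image (reported for low-noise regimes) is not asserted on phantoms.
* The spine-recovery proxy saturates on very dense or very noisy phantoms;
  its absolute numbers are detector-dependent.
* Fourier-spectrum MSE is computed on linear magnitudes; power or
  log-magnitude variants would scale differently and are config-switchable.
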