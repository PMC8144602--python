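# Methods

`srskit` re-creates, on fully synthetic data, the computational core of a
high-speed fingerprint-window (1550–1750 cm⁻¹) hyperspectral stimulated-Raman
scattering (SRS) imaging pipeline: a forward model for low-SNR spectroscopic
image stacks, a spatial-spectral residual denoising network, pixel-wise
L1-regularized spectral unmixing, delay-line/spectral-axis calibration, and
the restoration metrics used to judge the result.

## Spectral axis and delay-line geometry

In a spectral-focusing acquisition, two linearly chirped pulses map
inter-pulse time delay onto Raman shift. The delay is produced by scanning
the Stokes beam along a blazed grating in Littrow configuration; the
geometric path span of one sweep is `L·sin(θ)·tan(α)` (scan-line length `L`,
grating rotation `θ`, blaze angle `α`). A retro-reflected beam traverses the
added path twice, so the optical delay is `round_trip_factor · span / c`
with a default factor of 2; the factor is configurable because whether the
geometric formula already includes the round trip is not fixed by the
geometry alone. A 3 mm span double-passed gives ≈ 20 ps, the upper end of
the delay tuning range.

Because the scanner speed is linear, channel index maps linearly onto Raman
shift. `fit_linear_calibration` is ordinary least squares on
(sample index, known shift) points — typically ~11 strong bands of standard
chemicals — with R² = 1 − SS_res/SS_tot (SS_tot about the mean).
Well-aligned hardware produces R² ≳ 0.999; noiseless collinear input must
give R² = 1 to machine precision (tested to 1e-12).

## Synthetic data: the stated world

The generator emulates the raw-acquisition regime the denoiser is meant for:

- **Reference spectra** are sums of Lorentzian lines convolved with a
  Gaussian instrument response of 10 cm⁻¹ FWHM (the platform's spectral
  resolution), max-normalized to 1. Band positions: amide I (BSA) 1650 cm⁻¹
  (broad, 45 cm⁻¹ intrinsic FWHM), acyl C=C (triglyceride) 1655 cm⁻¹,
  sterol C=C (cholesterol) 1669 cm⁻¹, limonene 1645 + 1678 cm⁻¹, pinene
  1660 cm⁻¹. Narrow-band intrinsic widths default to 12–15 cm⁻¹, typical
  for fingerprint C=C bands. The limonene doublet amplitude ratio (1 : 0.7)
  and the widths are modelling choices, not measured values.
- **Phantoms** are disks (lipid droplets), annuli (membranes), and
  rod-capsules (bacteria), each carrying a non-negative per-chemical
  abundance vector; overlaps resolve last-writer-wins. Background pixels
  carry zero abundance.
- **Clean stacks** follow the bilinear model `D = C·S` plus a smooth
  baseline emulating the cross-phase-modulation background: a fixed
  quadratic across the spectral axis (`1 − 0.4·t + 0.2·t²`, `t ∈ [0,1]`),
  constant across space, scaled by a configurable amplitude (default 0.05).
  The spatial structure of the real background is not characterized;
  constant-in-space is an explicit simplifying assumption.
- **Noise** is additive i.i.d. zero-mean Gaussian per voxel, approximating
  lock-in-detected shot/electronic noise. σ is set so that
  (mean clean signal over a mask at a reference channel)/σ equals the
  target SNR — 1.4 by default, the single-shot fingerprint regime.
  Signal-dependent noise is deliberately out of the default model.
- **Training pairs**: the raw frame is one noise realization; the ground
  truth is the mean of `n_avg` independent realizations (default 100),
  giving the √N ≈ 10-fold SNR gain of frame averaging. All randomness is
  seed-derived (SeedSequence substreams), so every pair is reproducible.

Default stack size is 128 × 200 × 200 (λ, y, x); tests and the bundled
pipeline use 32 × 64 × 64 for speed. What a green test establishes is that
the pipeline behaves correctly *in this stated world*; real acquisitions
add structured backgrounds, detector drift, and motion that the generator
does not emulate.

## The denoiser

The network is a U-net-style encoder–decoder over (λ, y, x) patches.
Each level expands channels with a linear 1×1×1 convolution and applies
`blocks_per_level` SS-Conv blocks; an SS-Conv block runs a 1×3×3 spatial
convolution and a 3×1×1 spectral convolution in parallel, sums them, adds a
bias, and applies ReLU. The parallel pair replaces a dense 3×3×3 kernel at
a third of the parameter cost while treating spatial and spectral
correlations separately. Pooling is spatial-only (1,2,2) max pooling so the
spectral sampling needed by unmixing is never decimated; the decoder mirrors
with nearest-neighbour upsampling and skip concatenation, and a linear
1×1×1 head predicts a residual added to the input.

Design choices where the architecture was genuinely open:

- **Parallel-path merge**: elementwise sum (keeps channel count and cost).
- **Depth/width defaults**: 3 levels, six blocks per level, base 16
  channels doubling per level — all config-exposed.
- **Residual head initialized at zero**, so the untrained network is
  exactly the identity and optimization starts from "no correction". This
  mattered in practice: with a randomly initialized head the first epochs
  are spent unlearning a random residual.
- **Optimizer**: Adam (lr 1e-4 default; the bundled tiny configs use 1e-3),
  MSE loss on randomly sampled 3-D patches, seed-deterministic init and
  sampling.
- **Normalization**: intensities are mapped to percentile anchors
  (0.3 / 99.7) computed per training set over the pooled raw stacks, stored
  with the model, and inverted after inference. No clipping — hot pixels
  stay above 1 but do not set the scale.

The implementation is pure NumPy with hand-written forward/backward passes,
gradient-checked against finite differences in the test suite. There is no
GPU path; training budgets are desk-scale (minutes for the test configs).

### Inference tiling

Stacks larger than one tile (default: twice the training patch per axis)
are processed tile by tile. Tiles overlap by a margin and only each tile's
centre crop is stitched into the output. When the margin is at least the
network's receptive-field radius (computed from depth and block count by
`receptive_margin`) and tile origins are aligned to the pooling grid, the
tiled result equals the whole-stack pass exactly; smaller margins (forced
when tiles are small relative to the receptive field) make the agreement
approximate. Overlap-blending was tried first and rejected: a trained
U-net's predictions near tile borders differ by ~1e-2 of the dynamic range,
and blending leaves visible seams at any affordable overlap.

## Unmixing

With the flattened stack `D` (pixels × channels) and the reference matrix
`S` (components × channels, rows max-normalized), each pixel solves

    Ĉᵢ = argmin_c ½‖D(i,:) − c·S‖² + β‖c‖₁

by cyclic coordinate descent with soft-thresholding; each coordinate update
is the exact 1-D minimizer, so the objective is non-increasing sweep over
sweep (asserted in tests). Convergence is declared when the largest
coefficient change in a sweep falls below `tolerance` (default 1e-6, max
1000 sweeps). Coefficients are unconstrained in sign by default, matching
the objective; a non-negative mode clamps the soft-threshold at zero for
physical concentrations. β acts on the raw intensity scale — normalize
stacks before unmixing or retune β when units change. All pixels are
updated simultaneously (vectorized sweeps), and pixels are mathematically
independent, so results do not depend on processing order.

β tuning is qualitative in practice; `tune_beta` makes it explicit with a
crosstalk score: the mean absolute off-component abundance inside regions
known to be pure in one component, minimized over a candidate list with
ties broken toward smaller β. This is a stand-in criterion, not a claim
about how practitioners tune by eye.

## Metrics

- **NRMSE** = RMS(pred − gt) / RMS(gt), after both images are placed on the
  ground truth's percentile (0.3/99.7) dynamic range. An optional
  least-squares affine fit removes global gain/offset before the error.
- **SSIM** uses the standard constants (k₁ = 0.01, k₂ = 0.03) and a uniform
  7×7 window, computed per spectral plane and averaged; the authors' exact
  3-D handling is unstated, and per-plane averaging respects the distinct
  spatial/spectral correlation structure.
- **SNR** = mean intensity over a signal mask / standard deviation over a
  disjoint background mask, at one spectral channel. Single-number SRS SNR
  reports do not come with a formula; this definition is the package's and
  is used consistently by the noise generator, so `target_snr` in
  simulation and `snr_measure` in evaluation agree by construction.

## Known limitations

- The Gaussian noise model ignores signal-dependent (Poisson-like) noise
  and correlated lock-in noise.
- The baseline is spatially constant; real cross-phase-modulation
  backgrounds vary with morphology.
- Training configs in tests are deliberately tiny (2 levels, 2 blocks,
  base 8–12 channels) to fit CPU budgets; conclusions about the full-size
  architecture's capacity do not follow from them.
- No real microscope data is bundled or emulated beyond the statistics
  described above; metric values quoted anywhere in this repository are
  computed on synthetic stacks at run time.
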