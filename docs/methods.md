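# Methods

This note documents the models, numerical choices and limitations behind
`wfdecon`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Image formation model

A widefield fluorescence z-stack `y` is modeled as a Poisson-noisy,
Gaussian-read-noise-corrupted blur of the specimen `x`:

    y ~ Poisson(H x) + N(0, sigma^2),    (H x)(v) = sum_u psf(v - u) x(u)

with a unit-sum, nonnegative point spread function (PSF). All internal
arithmetic is 32-bit float; reductions (sums, objectives, MSE) are 64-bit.

## Born-Wolf PSF (`wfdecon.psf`)

The scalar Born-Wolf model of an aberration-free objective:

    h(r, z) = |A(r, z)|^2,
    A(r, z) = ∫_0^1 J0(k·NA·r·rho) · exp(-i·k·z·rho^2·NA^2 / (2·ni)) · rho d(rho)

with `k = 2π/λ_em`. Parameters: numerical aperture `NA` (must satisfy
0 < NA < ni), immersion refractive index `ni`, emission wavelength
`λ_em` (nm), lateral pixel pitch `dxy` (nm), axial step `dz` (nm).
Typical values used throughout the benchmarks: NA 1.45, ni 1.515,
λ 460 nm, 130 nm voxels.

Numerical choices:

- **Quadrature.** The integrand oscillates through roughly
  `(k·NA·r + k·|z|·NA²/(2·ni)) / 2π` cycles. Composite Gauss-Legendre
  with 24 nodes per panel and one panel per cycle keeps ≥ 20 nodes per
  oscillation; against an adaptive-quadrature oracle the evaluation is
  accurate to machine precision over the tested range.
- **Radial table.** `h` is radially symmetric, so it is precomputed on a
  uniform radial grid (step `dxy/8`) at every required depth and
  interpolated with a Lanczos-3 kernel mirrored around r = 0. Kernel
  weights are renormalized to unit sum at each evaluation point, which
  restores partition of unity (a constant profile is reproduced exactly,
  and values at grid nodes are exact). Lanczos-3 has an intrinsic
  passband ripple of a few parts in 10³ of the profile scale; this is the
  accuracy floor of the tabulated path and is documented in the tests.
- **Pixel integration.** Each voxel value is the mean of the interpolated
  intensity over a 7×7 Gauss-Legendre grid spanning the pixel square
  (sensor pixels integrate light; sampling only the pixel center
  overestimates the peak of an undersampled PSF). 7×7 agrees with 32×32
  to better than 1e-4. `quad_order=1` degrades to center sampling for
  comparison studies. Only one lateral octant and the z ≥ 0 half are
  computed; mirroring fills the rest, which makes the x↔−x, y↔−y, x↔y
  and z↔−z symmetries exact by construction. The volume is normalized to
  unit sum.
- **Default extents.** For deconvolving an `nx × ny × nz` image the PSF
  defaults to `2·nz − 1` axial planes (so its support covers the full
  extended axial domain of the boundary model below) and the smallest odd
  lateral size containing every radius where intensity exceeds 1e-5 of
  the peak, capped at the image size.

## Deconvolution (`wfdecon.deconv`)

Richardson-Lucy (RL) maximum-likelihood deconvolution for Poisson noise,
with two additions.

**Missing-data boundaries.** The camera observes only a region Ω; light
from structures outside Ω still lands in it. The object is estimated on
an extended grid of size image + PSF − 1 per axis (rounded up to the next
7-smooth integer for the FFT; the rounding padding lies outside Ω and has
zero weight). With `w = H^T 1_Ω` (the fraction of each extended voxel's
blur reaching Ω), the update is

    x_{k+1} = (x_k / w) · H^T[ 1_Ω · y / (H x_k) ]

On this grid circular convolution introduces no wrap-around inside Ω, so
all transforms use the real-input FFT path. The weighted update conserves
flux exactly: `sum(x_{k+1}·w) = sum_Ω y`. Voxels with `w < 0.01` are
unidentifiable and frozen at mean(y). Division guards: `H x` is floored
at `1e-12 · mean(y)`; iterates are clamped at `1e-9 · mean(y)` (exact
zeros are absorbing states of a multiplicative update).

**Scaled-heavy-ball acceleration.** The RL update is applied at the
extrapolated point `v_k = x_k + β_k (x_k − x_{k−1})` with
`β_k = (k − 1)/(k + 2)`, clamped to the positivity floor. `β = 0`
reproduces plain RL bit-for-bit; the first iteration of either method is
identical. The Poisson data term (KL divergence over Ω) is evaluated each
iteration from the forward model already computed inside the step; five
consecutive increases (beyond 1e-6 relative) reset the momentum once, a
second streak aborts with a diagnostic. Measured on a bright point-source
phantom, the accelerated scheme reaches plain RL's minimum MSE within 2%
in about 1/7 of the iterations.

The stopping rule is a fixed iteration count — the tool's single tunable
parameter. There is no automatic stopping criterion: RL semi-converges on
noisy data, and the appropriate count depends on the noise level and on
what the downstream analysis needs.

## Tiling (`wfdecon.tiles`)

Large images are processed in lateral tiles (the axial extent is never
split). Core rectangles partition the image exactly; each tile is read
with overlap padding `p` on sides that have neighbors, deconvolved
independently, and blended with per-axis weights that ramp linearly
across the 2p-wide overlap band (weight 1 deep inside the core and at
image borders). For cores at least 2p wide the weights of the tiles
covering any pixel sum to one by construction; the assembler also
accumulates the weight sum and divides, which keeps the output correct
even for narrower cores. With `p` at least the lateral PSF half-extent
the tiled result matches the untiled one to well under 1% of the peak.
Tiles stream through raw float32 scratch memmaps (shape recorded in a
JSON sidecar), so resident memory scales with the tile, not the image.

## Synthetic smFISH stacks (`wfdecon.simulate`)

The generator emulates single-molecule FISH in a widefield microscope:

- Stack 255 × 255 × 40 voxels at 130 nm isotropic (the stated recipe
  makes the axial step equal to the lateral pitch; taken literally).
- Each transcript is a Gaussian blob, total intensity 10,000 (default)
  and sigma 0.7 px, rasterized exactly by products of per-axis Gaussian
  CDF differences across voxel boundaries; interior blob mass is
  conserved to 0.1%.
- Constant background 1,000 added last.
- Corruption: convolution with the Born-Wolf PSF (the volume is padded
  with the background level first — the field of view behaves like a
  crop from a larger uniform specimen), a per-voxel Poisson draw, then
  additive Gaussian read noise (sigma 10 default), clamped at zero.
- Dot centers are uniform with margins (3 px lateral, 2 planes axial) so
  recall accounting is clean; no minimum pairwise separation — crowding
  is the point of the benchmark.
- All randomness comes from a seeded NumPy PCG64 generator; identical
  seeds reproduce stacks bit-for-bit.

**SNR definition.** The signal-to-noise ratio is defined as the peak of
the PSF-convolved blob above background divided by the noise scale at
background level, `sqrt(background + sigma_sensor²)`; `amplitude_for_snr`
inverts this linear map. The definition is a design choice — the 3D
widefield PSF spreads a dot's energy over the whole axial range, so
SNR-matched amplitudes are large multiples of the blob's nominal total
intensity (SNR 5 ≈ amplitude 8.7e4 under the defaults). Alternative
readings (SNR from the pre-convolution blob peak, or varying the read
noise at fixed amplitude) were evaluated and rejected: both make the
crowded benchmark regime undetectable even for an ideal matched filter
supplied with the true dot template, which contradicts the purpose of
the benchmark. A green detection benchmark therefore establishes
performance under *this* SNR calibration, not under every conceivable
one.

What the simulator does not model: nuclei or structured autofluorescence,
camera gain maps and fixed-pattern noise, PSF mismatch between blurring
and deconvolution (the same PSF is used for both — the ideal scenario, so
results are upper bounds), depth-dependent aberrations, and confocal
acquisition.

## Dot detection (`wfdecon.dots`)

- **Candidates.** Strict local maxima under 6-connectivity: a voxel
  counts only if brighter than every *existing* face neighbor (border
  voxels have no phantom neighbors). Plateaus are not maxima.
- **Ranking.** Raw brightness (intensity mode) or the value after a
  difference-of-Gaussians band-pass (DoG mode; maxima are then taken on
  the filtered volume). Defaults `sigma1 = 1 px`, `sigma2 = 1.6·sigma1`;
  with known optics `sigma1 = λ/(4·NA)/dxy` is the expected blob scale.
  Ties break deterministically by (z, y, x).
- **Sub-pixel refinement.** Three-point parabolic fit per axis, offsets
  clamped to ±0.5 px.
- **FWHM.** 1D Gaussian-plus-constant fits along x and y through the
  peak, sigmas averaged, FWHM = 2·sqrt(2·ln 2)·sigma·dxy. Fit failures
  flag the record rather than aborting.
- **CNR.** `(signal − background)/noise`, where background and noise are
  the mean and population standard deviation (n = 100: the ring is the
  whole population) of 100 bilinearly interpolated samples on the lateral
  circle of radius 5 px around the refined center in the dot's z-plane.
  The ring is sampled on the raw image. Numerically flat rings return a
  flagged +inf.
- **Matching.** Greedy per-query nearest neighbor in physical (nm)
  coordinates with a 260 nm radius (2 px at 130 nm); an optional
  mutual-nearest filter makes matched counts symmetric. Recall against
  ground truth uses the same radius.
- **Size filter.** An optional plausibility window keeps dots with FWHM
  between 0.5 and 5 pixel sides (the tissue-workflow rule for rejecting
  speckle and large autofluorescent blobs).
- **Auto-threshold.** Gaussian KDE of log-transformed positive ranking
  values; the deepest local minimum between the two highest modes
  separates high- from low-quality dots; a unimodal density returns an
  absent-threshold sentinel.

FWHM/CNR are measured lazily for the top-ranked records only
(`n_metrics`): noisy stacks produce 10^4–10^5 candidate maxima and a
curve fit per candidate would dominate the runtime.

## Benchmarks (`wfdecon.bench`)

- `mse`: plain mean squared error in 64-bit, no rescaling or registration
  (the flux-conserving deconvolver keeps scales commensurate).
- `iteration_sweep`: records MSE against ground truth at every iteration
  and the argmin.
- `detection_grid`: for each (SNR, density, seed, variant): simulate →
  optionally deconvolve (100 iterations default) → detect → keep the
  top-n true-dot-count ranked dots → match at 260 nm → recall and
  precision. Top-n selection matches the benchmark's accounting; an
  auto-threshold mode is available separately.

## I/O (`wfdecon.io`, `wfdecon.cli`)

Multi-page grayscale TIFF in and out (pages = z, rows = y, columns = x);
16-bit output is rescaled by `s = 65535/max` (s = 1 when the data already
fit and preservation mode is on) and `s` is recorded in the run log,
because downstream quantification must be able to undo it. Every run
writes a plain-text log (parameters, seeds, per-iteration objective,
rescale factor) sufficient to reproduce it. Inputs are never mutated.
Positions in tables are 0-based, voxel-center, pixel units.

## Known limitations

- Scalar, depth-invariant PSF only (no Gibson-Lanni or vectorial model,
  no depth-varying aberrations); users may supply any PSF TIFF instead.
- The SNR calibration of the synthetic benchmark is a definition choice
  (above); detection percentages are comparable only within a fixed
  definition.
- Lanczos-3 interpolation bounds the tabulated-PSF accuracy at a few
  parts in 10³ of the peak; raising the radial oversampling improves it
  only linearly.
- The momentum schedule is the standard (k−1)/(k+2) heavy-ball ramp; the
  original acceleration's exact scaling is not published, so iteration
  counts are comparable in structure, not necessarily one-to-one.
- Single-process CPU execution; no GPU path.
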