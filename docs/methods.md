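# Methods

## Model and scope

The package reconstructs 2D slices from noiseless or noisy parallel-beam
sinograms p(t, φ): M equispaced views over [0, π), N detector bins of
unit size, rotation axis at bin (N−1)/2.  Two inverters share one
filtering front end (zero-padding, spectral filter, smoothing window):

* **Gridding (direct Fourier method).**  Each padded projection (length
  P) is FFT'd, multiplied by the filter, and its P signed frequency
  samples are scattered onto a G×G Cartesian grid (G = oversample × P)
  by convolution with a separable PSWF kernel; a 2D inverse FFT,
  division by the kernel's real-space window, and a central N×N crop
  give the slice.  The radial (Δω = 1/P) and angular (Δφ = π/M) measure
  factors are folded into the scattered values, so the output is on the
  phantom's grey scale with no free normalization — a uniform disc of
  grey value μ reconstructs to μ (verified to 1 % in the tests).
* **Filtered back-projection** (reference): the filtered projections
  are back-projected with linear interpolation at
  t = x cosφ + y sinφ, accumulated with weight π/M.

Assumptions: 2D parallel geometry, half-turn equispaced angles, real
projections, square output grids.  Fan/cone beams, detector blur, ring
artifacts and physics effects (beam hardening, phase contrast) are out
of scope.

## Filters

* `ramp`: |k|/P in FFT order; exactly zero in the DC bin.  Zeroing the
  whole width-1/P DC *bin* (instead of only the single frequency ω = 0)
  discards the lowest-frequency mass and leaves a negative constant
  background offset proportional to (sinogram mass)/P²; the tests
  measure −0.018 for the 512² standard head phantom at ZP = 1.5 and
  confirm the magnitude shrinks monotonically as ZP grows.
* `bandlimited`: the DFT of the truncated impulse response
  h(0) = 1/4, h(odd n) = −1/(π²n²), h(even n) = 0 (the inverse Fourier
  transform of the ramp restricted to |ω| ≤ 1/2 at unit sampling,
  verified in the tests against numerical quadrature).  Its DC value is
  strictly positive and the background offset drops below 10⁻⁴ of the
  dynamic range.  This is the default filter.
* Windows: Parzen (piecewise cubic, 0 at the band edge) for strong
  noise damping, Lanczos (one-lobe sinc, sinc(ω/ω_Ny)) for mild
  damping.  Applied on the padded band, so their shape in cycles/bin is
  padding-independent.

Zero-padding appends round(zp·N) zeros per side; zp ≥ 0.5 satisfies the
minimum N−1 zeros needed to linearize the circular convolution.  The
tests show the ZP = 0 wrap-around contamination of the border band
exceeds the ZP = 0.5 case by an order of magnitude, while ZP = 0.5 and
1.5 agree interiorly to ~5 × 10⁻⁶ — the default ZP = 1.5 is kept for
comparability of the offset experiment, not accuracy.

## PSWF kernel

ψ₀(c, x) is computed from the tridiagonal representation of the prolate
differential operator in the normalized Legendre basis (eigenvector of
the smallest eigenvalue, expansion degree 30 with a trailing-coefficient
convergence check); an independent dense-quadrature solution of the
sinc-kernel concentration eigenproblem agrees to 10⁻⁶ and supplies the
in-band energy fraction.  Defaults: support half-width L = 4 grid
cells, c = 12, lookup table with 2048 samples/cell and linear
interpolation (table vs direct evaluation ≤ 10⁻⁶), deapodization
clamped where the window falls below 10⁻² of its peak.  c = 12 is the
smallest scanned value whose kernel decays below 10⁻⁴ of its peak at
the support edge while keeping the real-space window above the clamp
across the field of view even at ZP = 0; band leakage 1−λ₀ ≈ 9 × 10⁻¹⁰.
With oversample = 2 (default) the full pipeline matches a brute-force
nonuniform Fourier summation of the same discretized inversion formula
to RMSE ≤ 10⁻³ (measured ~10⁻⁶) of the dynamic range on 32² and 64²
problems — the gridding step introduces no measurable additional error.

Numerical details that matter:

* The pixel-centre convention needs the image sampled at half-integer
  FFT positions for even N.  The fractional shift is applied as a
  linear phase *per polar sample at its continuous frequency* before
  scattering; applying it after gridding corrupts kernel footprints
  that wrap across the Nyquist boundary.
* The unpaired real Nyquist bin of the even-length projection FFT is
  split half/half between ±P/2 (the +P/2 copy conjugated, because the
  stored bin carries the rotation-axis phase evaluated at −1/2
  cycles/bin).  This keeps the gridded spectrum Hermitian to 10⁻¹⁰ and
  the inverse-FFT imaginary residue at rounding level.
* Footprint bounds carry a 10⁻⁹-cell margin so cells at exactly the
  support radius are treated consistently under last-bit rounding of
  sample positions.

## Grid-origin conventions and the resolution study

`origin="pixel-center"` (default) places the rotation axis at pixel
(N−1)/2 in both inverters — sub-pixel exact, and the convention used
everywhere unless stated.  `origin="fft"` reproduces the classic
FFT-based production codes, which keep the raw 2D-FFT grid whose origin
falls at pixel N/2: for even N the image is displaced by half a pixel
on both axes relative to the pixel-centre convention (the conventions
coincide for odd N).

This choice is consequential for point-spread measurements.  Under
sub-pixel-exact alignment the gridding output equals the direct Fourier
sum, so its PSF is *narrower* than linear-interpolation FBP (whose
interpolation acts as a triangular blur, sinc² in frequency): measured
FWHM ratios ≈ −6 % (Lanczos) and −4 % (Parzen).  The historical
comparison between the two production codes, however, pairs an
FFT-origin gridding output with a pixel-centre FBP; radially averaging
the gridding PSF about the nominal point positions then smears the
half-pixel offset into an apparent broadening.  The resolution study in
`tests/test_acceptance.py` and `scripts/acceptance.py` reproduces that
pairing (`origin="fft"` for the gridding arm) and yields FWHM increases
of ≈ +12 % (Lanczos) and ≈ +5 % (Parzen), independent of the view
count.  Users who want sub-pixel-registered output should keep the
default convention.

The FWHM instrument extracts a (2·8+1)² window at each of the 162
pattern points, rejects non-bell or overlapping windows, averages all
windows, bins the mean radially in half-pixel annuli (each represented
by its exact mean radius), and interpolates the crossing of
baseline + (peak − baseline)/2 linearly; the baseline is the window-rim
median.  On synthetic Gaussians of known σ the protocol recovers
2.355σ within 0.5 %.

## Synthetic data

The generator provides the canonical ten-ellipse head-phantom tables
(standard: shell grey value 2.0; modified low-contrast: shell 1.0),
exact analytic chord-integral sinograms, a discrete rotate-and-sum
projector for arbitrary images, a 162-point resolution pattern (nine
equispaced-radius rings, populations proportional to radius apportioned
by largest remainder, per-ring angular offsets, unit amplitudes
deposited into single bins/pixels), and additive Gaussian sinogram
noise with a mandatory seed.  Study conditions follow the validation
setup: 512² phantoms with 1501 views over 180° (oversampled, since
M > Nπ/2 ≈ 804), ZP = 1.5; the undersampled regime is exercised at
1024²/400 views (ZP = 0.5 to bound the FFT grid at 4096²) rather than
2048²/1501, keeping the angular-sampling ratio on the same side of the
Nyquist criterion at a tractable size.  What the generator does *not*
emulate: detector blur and photon statistics, beam hardening, ring
artifacts, axis misalignment — so passing tests demonstrate algorithmic
correctness on the discretized model, not robustness to real beamline
data.

## Known limitations

* With linear-interpolation FBP as the baseline, the gridding method's
  background texture (Lanczos window) is measured 1.3–1.4× *noisier*
  in both sampling regimes: the exact Fourier sum retains the discrete
  problem's full high-frequency streak/Gibbs field while FBP's
  interpolation low-passes it.  A noise *advantage* of gridding over
  FBP in the oversampled regime would require a noisier FBP baseline
  (e.g. nearest-neighbour interpolation) and is not reproduced here;
  the corresponding assertion in the acceptance suite is expected to
  fail and documents this.
* Analytic sinogram rows are chord profiles sampled at bin centres, so
  row sums conserve mass across angles only to the midpoint-rule
  residue (~6 × 10⁻⁴ relative at 512 bins), not exactly.
* Single-slice operation only: the two-slices-per-complex-FFT packing,
  multi-slice batching and distributed execution are out of scope, and
  no wall-clock performance claims are made or tested (the O(N² log N)
  vs O(M·N²) scaling is structural).
* Even output sizes are assumed throughout the studies; odd sizes are
  supported but the padded length must stay even for the FFT-order
  filters.
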