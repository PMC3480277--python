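# gridrec

Fast Fourier-method reconstruction for parallel-beam tomography, with a
reference filtered back-projection, analytic phantom simulation and the
accuracy instruments used to validate both.

## The problem

Synchrotron tomographic microscopy acquires on the order of a thousand
parallel projections p(t, φ) of a specimen per slice.  Filtered
back-projection (FBP) inverts them in O(M·N²) per N×N slice — too slow
to keep up with modern detectors.  The Fourier slice theorem offers an
O(N² log N) route: the 1D FFT of a projection at angle φ is a radial
line of the object's 2D Fourier transform, so the slice can be
recovered by filling Fourier space from the projection FFTs and
applying one 2D inverse FFT.  The catch is resampling the polar samples
onto a Cartesian grid: a pointwise interpolation error in Fourier space
spreads across the whole image.

The *gridding* solution implemented here convolves the polar samples

    F̂(u, v) = Σ_m Σ_k P(kτ, φ_m) · R(kτ) · W(u − kτ cosφ_m, v − kτ sinφ_m) · τ · Δφ

with a compact separable kernel W(u, v) = w(u)·w(v) built from
zeroth-order prolate spheroidal wavefunctions (PSWFs) — the functions
that maximize energy concentration for a fixed support — evaluated via
their Legendre-polynomial expansion.  After the 2D inverse FFT the
kernel's real-space window is divided out (deapodization).  R is the
reconstruction filter: either the ideal ramp |ω|, or the band-limited
discrete filter — the DFT of the impulse response h(0) = 1/4,
h(odd n) = −1/(n²π²), h(even n) = 0 — whose strictly positive DC value
removes the constant grey-level offset that plain-|ω| implementations
imprint on the slice.  Parzen or Lanczos windows damp high-frequency
noise, and zero-padding of the projections (ZP × the field of view per
side) prevents interperiod (wrap-around) interference from the circular
convolution.

## Worked example

```python
import gridrec as gr

spec  = gr.shepp_logan_spec("standard")          # 10-ellipse head phantom
truth = gr.rasterize(spec, 512)                  # grey values in [0, 2]
sino  = gr.project_ellipses(spec, 1501, 512)     # analytic line integrals
print(sino.data.shape)                           # (1501, 512)

cfg = gr.ReconConfig(filter="bandlimited", window="parzen", zeropad=1.5)
rec = gr.reconstruct_gridrec(sino, cfg)
print(f"{rec.pixels.min():.4f} .. {rec.pixels.max():.4f}")   # -0.0265 .. 2.0114

mask = gr.background_mask(spec, 512)
print(f"{gr.background_offset(rec, truth, mask):.2e}")       # 2.42e-05
```

The reconstruction recovers the phantom's grey scale directly (range
≈ [0, 2], RMSE 3.9 % of the dynamic range, dominated by edge Gibbs
oscillations) and its background sits within 2.4 × 10⁻⁵ of zero thanks
to the band-limited filter.  Repeating the reconstruction with FBP and
the plain |ω| ramp instead shows the classic DC artifact:

```python
cfg  = gr.ReconConfig(method="fbp", filter="ramp", window="none", zeropad=1.5)
fbp  = gr.reconstruct_fbp(sino, cfg)
print(f"{gr.background_offset(fbp, truth, mask):.5f}")       # -0.01837
```

a constant −0.018 grey-level offset across the slice.

The same pipeline is available from the shell:

```sh
gridrec project --variant standard --angles 1501 --bins 512 --out sino.tif
gridrec reconstruct --sino sino.tif --out slice.tif \
        --filter bandlimited --window parzen --zeropad 1.5
gridrec eval profile --image slice.tif --row 410 --out profile.csv
```

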