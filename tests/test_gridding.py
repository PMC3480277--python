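"""Gridding reconstruction core: spectra, scatter, inversion."""

import numpy as np
import pytest

import gridrec as gr
from gridrec.filters import make_filter, pad_sinogram
from gridrec.gridding import (
    fft_projections,
    grid_polar_to_cartesian,
    invert_and_deapodize,
)
from gridrec.pswf import build_kernel
from _oracles import direct_fourier_reconstruct


class TestFFTProjections:
    def test_constant_projection_killed_by_ramp(self):
        sino = gr.Sinogram(np.ones((3, 64)))
        spec = fft_projections(sino, gr.ramp_filter(64))
        assert np.abs(spec.data).max() < 1e-12

    def test_axis_delta_has_zero_phase(self):
        data = np.zeros((1, 65))
        data[0, 32] = 1.0  # odd length: axis exactly on a bin
        sino = gr.Sinogram(data)
        filt = gr.SpectralFilter(np.ones(65), "ramp")
        spec = fft_projections(sino, filt)
        np.testing.assert_allclose(spec.data[0].imag, 0.0, atol=1e-12)
        np.testing.assert_allclose(spec.data[0].real, 1.0, atol=1e-12)

    def test_real_projection_gives_hermitian_row(self, disc_sino_128):
        pad = pad_sinogram(disc_sino_128, 0.5)
        spec = fft_projections(pad, make_filter("bandlimited", "none", pad.n_bins))
        row = spec.data[5]
        np.testing.assert_allclose(
            row[1:], np.conj(row[1:][::-1]), atol=1e-10 * np.abs(row).max()
        )

    def test_length_mismatch_rejected(self, disc_sino_128):
        with pytest.raises(ValueError):
            fft_projections(disc_sino_128, gr.ramp_filter(64))


class TestScatter:
    def test_zero_spectrum_zero_grid(self):
        from gridrec.gridding import PolarSpectrum

        spec = PolarSpectrum(np.zeros((4, 32), complex), np.arange(4) * np.pi / 4)
        kern = build_kernel(grid_size=64)
        grid = grid_polar_to_cartesian(spec, kern, 2.0)
        assert not grid.data.any()

    def test_origin_sample_reproduces_kernel_footprint(self):
        """A single unit sample at omega = 0 paints the separable kernel,
        matching direct evaluation to 1e-6."""
        from gridrec.gridding import PolarSpectrum

        p_len = 32
        data = np.zeros((1, p_len), complex)
        data[0, 0] = 1.0
        spec = PolarSpectrum(data, np.zeros(1))
        kern = build_kernel(grid_size=64)
        grid = grid_polar_to_cartesian(spec, kern, 2.0)
        scale = np.pi / 1 / p_len  # measure factors folded into scatter
        hw = kern.half_width
        for i in range(-hw, hw + 1):
            for j in range(-hw, hw + 1):
                want = scale * float(
                    kern.lookup(np.abs([i]))[0] * kern.lookup(np.abs([j]))[0]
                )
                assert grid.data[i % 64, j % 64].real == pytest.approx(
                    want, abs=1e-6 * scale
                )
        # compact support: nothing lands outside the kernel footprint
        outside = np.ones((64, 64), bool)
        idx = np.arange(-hw, hw + 1) % 64
        outside[np.ix_(idx, idx)] = False
        assert not grid.data[outside].any()

    def test_quarter_turn_symmetry(self):
        """Gridding the same even row at phi and phi + pi/2 produces a
        grid invariant under a 90-degree coordinate rotation."""
        from gridrec.gridding import PolarSpectrum

        p_len = 32
        row = np.zeros(p_len)  # even in the FFT sense: row[k] == row[-k]
        row[0] = 1.0
        for k, v in [(3, 0.7), (8, -0.2), (13, 0.45)]:
            row[k] = row[p_len - k] = v
        row[p_len // 2] = 0.1
        data = np.stack([row, row]).astype(complex)
        spec = PolarSpectrum(data, np.array([0.0, np.pi / 2]))
        kern = build_kernel(grid_size=64)
        grid = grid_polar_to_cartesian(spec, kern, 2.0).data
        # cos(pi/2) is ~6e-17 rather than 0, which moves footprints by
        # ~1e-14 cells; allow for the table-lookup sensitivity to that
        np.testing.assert_allclose(grid, grid.T, atol=1e-9 * np.abs(grid).max())

    def test_gridded_spectrum_hermitian(self, small_sino):
        pad = pad_sinogram(small_sino, 0.5)
        spec = fft_projections(pad, make_filter("bandlimited", "none", pad.n_bins))
        kern = build_kernel(grid_size=2 * pad.n_bins)
        g = grid_polar_to_cartesian(spec, kern, 2.0, shift=0.5).data
        n = g.shape[0]
        flip = (-np.arange(n)) % n
        np.testing.assert_allclose(
            g, np.conj(g[flip][:, flip]), atol=1e-10 * np.abs(g).max()
        )

    def test_kernel_support_must_fit(self):
        from gridrec.gridding import PolarSpectrum

        spec = PolarSpectrum(np.zeros((1, 4), complex), np.zeros(1))
        kern = build_kernel(grid_size=8)
        with pytest.raises(ValueError):
            grid_polar_to_cartesian(spec, kern, 1.0)


class TestReconstruction:
    def test_all_zero_sinogram(self):
        sino = gr.Sinogram(np.zeros((16, 32)))
        rec = gr.reconstruct_gridrec(sino, gr.ReconConfig(zeropad=0.5))
        assert not rec.pixels.any()

    @pytest.mark.parametrize("n,m", [(32, 60), (64, 100)])
    def test_matches_direct_fourier_oracle(self, n, m):
        """Gridding agrees with the brute-force nonuniform Fourier sum
        to better than 1e-3 of the dynamic range."""
        spec = gr.PhantomSpec(
            ellipses=(
                gr.Ellipse(0.1, -0.05, 0.5, 0.35, 20.0, 1.0),
                gr.Ellipse(-0.2, 0.2, 0.15, 0.15, 0.0, 0.5),
            ),
            variant="standard",
        )
        sino = gr.project_ellipses(spec, m, n)
        oracle = direct_fourier_reconstruct(sino, zp=0.5)
        rec = gr.reconstruct_gridrec(sino, gr.ReconConfig(zeropad=0.5))
        dr = oracle.max() - oracle.min()
        rmse = np.sqrt(np.mean((rec.pixels - oracle) ** 2)) / dr
        assert rmse < 1e-3

    def test_linearity(self, small_sino):
        cfg = gr.ReconConfig(zeropad=0.5, window="parzen")
        a = gr.reconstruct_gridrec(small_sino, cfg).pixels
        doubled = gr.Sinogram(
            2.5 * small_sino.data, angles=small_sino.angles, center=small_sino.center
        )
        other = gr.Sinogram(
            np.roll(small_sino.data, 3, axis=1),
            angles=small_sino.angles,
            center=small_sino.center,
        )
        b = gr.reconstruct_gridrec(other, cfg).pixels
        combo = gr.Sinogram(
            2.5 * small_sino.data + 0.5 * np.roll(small_sino.data, 3, axis=1),
            angles=small_sino.angles,
            center=small_sino.center,
        )
        c = gr.reconstruct_gridrec(combo, cfg).pixels
        np.testing.assert_allclose(
            c, 2.5 * a + 0.5 * b, atol=1e-10 * np.abs(c).max()
        )

    def test_rotation_covariance_on_point(self):
        """Shifting the sinogram by one angular step rotates the image
        by pi/M (checked on the point centroid to sub-pixel accuracy)."""
        n, m = 64, 90
        spec = gr.PhantomSpec(variant="points", point_sources=((0.4, 0.1, 1.0),))
        base = gr.project_ellipses(spec, m, n)
        # advancing the sinogram by one angular step (wrapped row mirrored
        # about the axis, p(t, phi+pi) = p(-t, phi)) shows the phantom
        # rotated by -pi/M
        rolled = np.roll(base.data, -1, axis=0)
        rolled[-1] = rolled[-1][::-1]
        dphi = np.pi / m
        x, y = 0.4, 0.1
        xr = x * np.cos(dphi) + y * np.sin(dphi)
        yr = -x * np.sin(dphi) + y * np.cos(dphi)
        rspec = gr.PhantomSpec(variant="points", point_sources=((xr, yr, 1.0),))
        cfg = gr.ReconConfig(zeropad=0.5, window="parzen")
        rec_shift = gr.reconstruct_gridrec(
            gr.Sinogram(rolled, angles=base.angles, center=base.center), cfg
        )
        rec_rot = gr.reconstruct_gridrec(gr.project_ellipses(rspec, m, n), cfg)

        def centroid(img):
            p = np.clip(img.pixels, 0, None) ** 2
            iy, ix = np.mgrid[: img.size, : img.size]
            return (p * ix).sum() / p.sum(), (p * iy).sum() / p.sum()

        cx1, cy1 = centroid(rec_shift)
        cx2, cy2 = centroid(rec_rot)
        assert abs(cx1 - cx2) < 0.5 and abs(cy1 - cy2) < 0.5

    def test_uniform_disc_recovered_at_true_grey(self, disc_sino_128, disc_spec):
        rec = gr.reconstruct_gridrec(disc_sino_128, gr.ReconConfig(zeropad=0.5))
        xs = (2 * np.arange(128) + 1.0) / 128 - 1
        x, y = np.meshgrid(xs, xs[::-1])
        interior = x**2 + y**2 < 0.4**2
        assert rec.pixels[interior].mean() == pytest.approx(1.0, abs=0.01)

    def test_imaginary_residue_negligible(self, small_sino):
        pad = pad_sinogram(small_sino, 0.5)
        spec = fft_projections(pad, make_filter("bandlimited", "none", pad.n_bins))
        kern = build_kernel(grid_size=2 * pad.n_bins)
        grid = grid_polar_to_cartesian(spec, kern, 2.0, shift=0.5)
        img = np.fft.ifft2(grid.data)
        assert np.abs(img.imag).max() <= 1e-8 * np.ptp(img.real)

    def test_deterministic(self, small_sino):
        cfg = gr.ReconConfig(zeropad=0.5)
        a = gr.reconstruct_gridrec(small_sino, cfg).pixels
        b = gr.reconstruct_gridrec(small_sino, cfg).pixels
        assert np.array_equal(a, b)
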