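"""Zeroth-order prolate spheroidal wavefunctions and the gridding kernel.

The gridding convolution kernel is the separable product w(u)w(v) with
w a zeroth-order 1D PSWF: among functions supported on a finite
frequency interval it packs the largest energy fraction into a finite
spatial band, so a compactly supported Fourier-domain kernel can be
undone in real space (deapodization) with minimal aliasing leakage.

PSWFs are evaluated through their rapidly converging Legendre expansion:
the prolate differential operator is tridiagonal in the normalized
Legendre basis, and psi_0 is the eigenvector of the even-order block
with the smallest eigenvalue chi.  A sufficiently high expansion degree
matters; the trailing-coefficient ratio is checked and a too-low degree
raises instead of silently losing accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.linalg import eigh_tridiagonal

__all__ = ["pswf_eval", "pswf_legendre_coeffs", "PSWFKernel", "build_kernel"]

#: space-bandwidth product of the default kernel.  Chosen (with support
#: half-width 4) so that the kernel table decays below 1e-4 of its peak
#: at the support edge while the real-space window stays above 1e-2 of
#: its centre value at the field-of-view edge for any padding >= 0.
DEFAULT_C = 12.0
DEFAULT_HALF_WIDTH = 4
DEFAULT_TABLE_DENSITY = 2048
DEFAULT_DEGREE = 30
#: deapodization is clamped where the window falls below this fraction
#: of its maximum (far corners outside the resolution circle).
CLIP_FRACTION = 1e-2


def pswf_legendre_coeffs(c_param: float, degree: int = DEFAULT_DEGREE) -> np.ndarray:
    """Legendre-series coefficients of psi_0(c, x), unnormalized.

    Returns a coefficient vector usable with
    ``numpy.polynomial.legendre.legval`` (odd orders are zero).
    """
    if c_param <= 0:
        raise ValueError("c_param must be positive")
    if degree < 8:
        raise ValueError("expansion degree must be >= 8")
    ks = np.arange(0, degree + 1, 2, dtype=float)
    diag = ks * (ks + 1) + c_param**2 * (2 * ks * (ks + 1) - 1) / (
        (2 * ks + 3) * (2 * ks - 1)
    )
    off = c_param**2 * (ks[:-1] + 2) * (ks[:-1] + 1) / (
        (2 * ks[:-1] + 3) * np.sqrt((2 * ks[:-1] + 1) * (2 * ks[:-1] + 5))
    )
    _, vec = eigh_tridiagonal(diag, off, select="i", select_range=(0, 0))
    beta = vec[:, 0]
    if np.abs(beta[-1]) / np.max(np.abs(beta)) > 1e-12:
        raise ValueError(
            f"Legendre expansion of degree {degree} has not converged for "
            f"c={c_param}; increase the expansion degree"
        )
    coef = np.zeros(int(ks[-1]) + 1)
    coef[ks.astype(int)] = beta * np.sqrt(ks + 0.5)  # de-normalize basis
    return coef


def pswf_eval(x, c_param: float, degree: int = DEFAULT_DEGREE):
    """psi_0(c, x) on [-1, 1], normalized so psi_0(c, 0) = 1."""
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("pswf_eval requires |x| <= 1")
    coef = pswf_legendre_coeffs(c_param, degree)
    vals = npleg.legval(np.clip(x, -1.0, 1.0), coef) / npleg.legval(0.0, coef)
    return vals if vals.shape else float(vals)


@dataclass
class PSWFKernel:
    """Gridding kernel lookup table plus real-space deapodization.

    ``table`` samples the Fourier-domain kernel on [0, half_width] grid
    cells at ``table_density`` samples per cell; ``correction`` holds the
    clamped reciprocal real-space window along one axis of the final
    image grid (minimum at the image centre).
    """

    c_param: float
    half_width: int
    table_density: int
    grid_size: int
    legendre_degree: int = DEFAULT_DEGREE
    table: np.ndarray = field(default=None, repr=False)
    correction: np.ndarray = field(default=None, repr=False)

    def lookup(self, d: np.ndarray) -> np.ndarray:
        """Kernel value at offsets |d| <= half_width, linear interpolation."""
        pos = np.abs(d) * self.table_density
        idx = np.minimum(pos.astype(int), self.table.size - 2)
        frac = pos - idx
        return self.table[idx] * (1 - frac) + self.table[idx + 1] * frac

    def spatial_window(self, x: np.ndarray, grid_size: int) -> np.ndarray:
        """Real-space window w(x) of the kernel for an FFT grid of G cells.

        ``x`` is in image pixels from the centre; w is the (continuous)
        inverse Fourier transform of the tabulated kernel, w(0) maximal.
        """
        a = np.arange(self.table.size) / self.table_density  # offsets in cells
        # trapezoid quadrature of 2 * int_0^L psi(a/L) cos(2 pi a x / G) da
        wts = np.full(a.size, 1.0 / self.table_density)
        wts[0] = wts[-1] = 0.5 / self.table_density
        return 2.0 * np.cos(
            2.0 * np.pi * np.outer(np.asarray(x, float), a) / grid_size
        ) @ (self.table * wts)


def build_kernel(
    c_param: float = DEFAULT_C,
    half_width: int = DEFAULT_HALF_WIDTH,
    table_density: int = DEFAULT_TABLE_DENSITY,
    grid_size: int = 512,
    degree: int = DEFAULT_DEGREE,
) -> PSWFKernel:
    """Tabulate the separable PSWF kernel for a G x G Fourier grid.

    ``grid_size`` is the full Cartesian FFT grid size G; the correction
    array covers the centred G-point image axis.
    """
    if table_density < 256:
        raise ValueError("table_density must be >= 256")
    if half_width < 1:
        raise ValueError("half_width must be a positive integer")
    kern = PSWFKernel(
        float(c_param), int(half_width), int(table_density), int(grid_size), degree
    )
    u = np.arange(half_width * table_density + 1) / (half_width * table_density)
    coef = pswf_legendre_coeffs(c_param, degree)
    table = npleg.legval(u, coef)
    kern.table = table / table[0]
    xs = np.arange(grid_size) - (grid_size - 1) / 2.0
    w = kern.spatial_window(xs, grid_size)
    w = np.clip(w, CLIP_FRACTION * w.max(), None)
    kern.correction = 1.0 / w
    return kern
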