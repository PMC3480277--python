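"""Independent reference computations used by the test suite.

These deliberately avoid the package's reconstruction path: the direct
nonuniform Fourier sum evaluates the discretized inversion formula
term by term per image pixel, and the PSWF oracle solves the
concentration integral-equation eigenproblem by dense quadrature.
"""

import numpy as np

from gridrec.filters import make_filter, pad_sinogram


def direct_fourier_reconstruct(sino, kind="bandlimited", window="none", zp=0.5):
    """Brute-force evaluation of the discretized inversion sum.

    For every image pixel, sums filter(k/P) * S_m(k) * exp(2 pi i k t / P)
    over all angles m and the symmetric signed frequency band (the real
    Nyquist bin split between +-P/2), times the measure pi/(M P).
    """
    pad = pad_sinogram(sino, zp)
    p_len = pad.n_bins
    filt = make_filter(kind, window, p_len)
    spec = np.fft.fft(pad.data, axis=1) * filt.values
    k = np.fft.fftfreq(p_len) * p_len
    spec = spec * np.exp(2j * np.pi * k / p_len * pad.center)
    # symmetric band: conjugate half-weight copy of the Nyquist bin at +P/2
    half = p_len // 2
    k = np.concatenate([k, [p_len / 2]])
    spec = np.concatenate([spec, np.conj(spec[:, half : half + 1])], axis=1)
    spec[:, half] *= 0.5
    spec[:, -1] *= 0.5
    n = sino.n_bins
    c = (n - 1) / 2.0
    xs = np.arange(n) - c
    x, y = np.meshgrid(xs, xs[::-1])
    out = np.zeros((n, n))
    for m, phi in enumerate(pad.angles):
        t = x * np.cos(phi) + y * np.sin(phi)
        out += (
            spec[m][None, None, :]
            * np.exp(2j * np.pi / p_len * np.multiply.outer(t, k))
        ).sum(-1).real
    return out * (np.pi / pad.n_angles / p_len)


def bandlimited_ramp_integral(n, n_quad=200001):
    """Numeric inverse-Fourier integral of the band-limited ramp at offset n."""
    w = np.linspace(-0.5, 0.5, n_quad)
    return np.trapezoid(np.abs(w) * np.cos(2 * np.pi * w * n), w)


def pswf_quadrature(c, n_nodes=400):
    """Top eigenpair of the sinc-kernel concentration operator.

    Returns (eigenvalue, nodes, weights, eigenvector at the nodes); the
    eigenvalue is the in-band energy fraction of psi_0.
    """
    xs, ws = np.polynomial.legendre.leggauss(n_nodes)
    kernel = (c / np.pi) * np.sinc(c * (xs[:, None] - xs[None, :]) / np.pi)
    evals, evecs = np.linalg.eig(kernel * ws[None, :])
    i = np.argmax(evals.real)
    return evals[i].real, xs, ws, evecs[:, i].real


def pswf_quadrature_eval(x, c, n_nodes=400):
    """psi_0(c, x) from the quadrature eigenproblem (Nystrom extension)."""
    lam, xs, ws, vec = pswf_quadrature(c, n_nodes)
    kern = (c / np.pi) * np.sinc(c * (np.atleast_1d(x)[:, None] - xs[None, :]) / np.pi)
    vals = kern @ (ws * vec) / lam
    v0 = ((c / np.pi) * np.sinc(c * (0.0 - xs) / np.pi)) @ (ws * vec) / lam
    return vals / v0
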