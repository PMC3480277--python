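"""Frequency-domain reconstruction filters, smoothing windows and padding.

Two reconstruction kernels are provided.  The ideal ramp ``|omega|``
zeroes the whole DC frequency *bin* of the padded projection, which
imprints a negative constant grey-level offset on the reconstruction.
The band-limited discrete filter instead takes the DFT of the truncated
impulse response

    h(0) = 1/4,   h(n) = 0 (n even),   h(n) = -1 / (n^2 pi^2) (n odd),

i.e. the inverse Fourier transform of the ramp restricted to the
detector band |omega| <= 1/2 sampled at unit offsets.  Its DFT agrees
with |omega| away from the origin but has a strictly positive DC value,
which removes the offset.

All filters are stored over the padded length P in FFT (wrap-around)
order; frequencies are in cycles per bin, so the band edge is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Sinogram

__all__ = [
    "SpectralFilter",
    "ramp_filter",
    "bandlimited_impulse_response",
    "bandlimited_ramp_filter",
    "smoothing_window",
    "make_filter",
    "pad_sinogram",
]

FILTER_KINDS = ("ramp", "bandlimited")
WINDOW_KINDS = ("none", "parzen", "lanczos")


@dataclass
class SpectralFilter:
    """Nonnegative frequency-domain multiplier in FFT order."""

    values: np.ndarray
    kind: str
    window: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("filter values must be finite and >= 0")

    @property
    def padded_len(self) -> int:
        return self.values.size

    def __mul__(self, other: "SpectralFilter") -> "SpectralFilter":
        if self.padded_len != other.padded_len:
            raise ValueError("filter length mismatch")
        window = other.window if self.window == "none" else self.window
        return SpectralFilter(self.values * other.values, self.kind, window)


def _check_even(padded_len: int) -> None:
    if padded_len < 2 or padded_len % 2:
        raise ValueError("padded_len must be an even integer >= 2")


def ramp_filter(padded_len: int) -> SpectralFilter:
    """Ideal ramp |omega| sampled at the padded FFT frequencies k/P."""
    _check_even(padded_len)
    return SpectralFilter(np.abs(np.fft.fftfreq(padded_len)), "ramp")


def bandlimited_impulse_response(n) -> np.ndarray:
    """Impulse response h(n) of the band-limited ramp at integer offsets."""
    n = np.asarray(n)
    odd = n % 2 != 0
    h = np.zeros(n.shape, dtype=float)
    h[odd] = -1.0 / (np.pi**2 * n[odd].astype(float) ** 2)
    h[n == 0] = 0.25
    return h if h.shape else float(h)


def bandlimited_ramp_filter(padded_len: int) -> SpectralFilter:
    """DFT of the truncated, circularly arranged impulse response h(n)."""
    _check_even(padded_len)
    n = np.fft.fftfreq(padded_len) * padded_len  # 0..P/2-1, -P/2..-1
    h = bandlimited_impulse_response(n.astype(int))
    values = np.fft.fft(h).real
    # h is even, so the DFT is real; clamp away negative rounding noise
    return SpectralFilter(np.clip(values, 0.0, None), "bandlimited")


def smoothing_window(kind: str, padded_len: int) -> SpectralFilter:
    """Parzen or Lanczos apodization over the detector band |f| <= 0.5.

    Parzen is the standard piecewise-cubic window, reaching 0 at the band
    edge; Lanczos is the one-lobe sinc window sinc(f / 0.5).
    """
    _check_even(padded_len)
    f = np.fft.fftfreq(padded_len)
    if kind == "parzen":
        q = np.abs(f) / 0.5
        w = np.where(
            q <= 0.5, 1.0 - 6.0 * q**2 * (1.0 - q), 2.0 * (1.0 - q) ** 3
        )
        w = np.clip(w, 0.0, None)
    elif kind == "lanczos":
        w = np.abs(np.sinc(2.0 * f))
    elif kind == "none":
        w = np.ones(padded_len)
    else:
        raise ValueError(
            f"unknown window {kind!r}; expected one of {WINDOW_KINDS}"
        )
    return SpectralFilter(w, "window", kind)


def make_filter(kind: str, window: str, padded_len: int) -> SpectralFilter:
    """Reconstruction kernel times smoothing window, FFT order."""
    if kind == "ramp":
        filt = ramp_filter(padded_len)
    elif kind == "bandlimited":
        filt = bandlimited_ramp_filter(padded_len)
    else:
        raise ValueError(f"unknown filter {kind!r}; expected one of {FILTER_KINDS}")
    if window != "none":
        filt = filt * smoothing_window(window, padded_len)
    return filt


def pad_sinogram(sino: Sinogram, zp: float) -> Sinogram:
    """Append zp*N zeros on each side of every projection.

    ZP = 0.5 extends each side by half the original field of view; the
    rotation-axis metadata shifts with the left padding.  ZP = 0 is the
    identity.
    """
    if zp < 0:
        raise ValueError("zero-padding fraction must be >= 0")
    n = sino.n_bins
    pad = int(round(zp * n))
    if pad == 0:
        return Sinogram(sino.data.copy(), angles=sino.angles.copy(), center=sino.center)
    data = np.zeros((sino.n_angles, n + 2 * pad))
    data[:, pad : pad + n] = sino.data
    return Sinogram(data, angles=sino.angles.copy(), center=sino.center + pad)
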