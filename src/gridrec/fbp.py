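"""Reference filtered back-projection.

Shares the padding/filter machinery with the gridding reconstructor so
that comparisons between the two isolate the inversion step: each padded
projection is filtered in the Fourier domain, inverse-transformed, and
smeared back across the image with linear interpolation at
t = x cos(phi) + y sin(phi), accumulated with angular weight pi / M.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from ._accel import backproject
from .config import ReconConfig
from .containers import Sinogram, Slice
from .filters import make_filter, pad_sinogram

__all__ = ["reconstruct_fbp"]

log = logging.getLogger(__name__)


def filter_projections(padded: Sinogram, filt) -> np.ndarray:
    """Real filtered projections q_m(t) on the padded detector grid."""
    spec = np.fft.fft(padded.data, axis=1) * filt.values
    return np.fft.ifft(spec, axis=1).real


def reconstruct_fbp(sino: Sinogram, config: ReconConfig = None) -> Slice:
    """Filtered back-projection of one sinogram."""
    config = config or ReconConfig(method="fbp")
    out_size = config.out_size or sino.n_bins
    t0 = time.perf_counter()
    padded = pad_sinogram(sino, config.zeropad)
    filt = make_filter(config.filter, config.window, padded.n_bins)
    q = filter_projections(padded, filt)
    t1 = time.perf_counter()
    c = (out_size - 1) / 2.0 if config.origin == "pixel-center" else float(out_size // 2)
    pixels = backproject(
        q, np.ascontiguousarray(padded.angles), float(padded.center), int(out_size), c
    )
    if config.mask_outside_circle:
        xs = np.arange(out_size) - c
        yy, xx = np.meshgrid(xs, xs, indexing="ij")
        pixels[xx**2 + yy**2 > ((out_size - 1) / 2.0) ** 2] = 0.0
    log.info(
        "fbp: filter %.3fs, back-projection %.3fs (P=%d)",
        t1 - t0,
        time.perf_counter() - t1,
        padded.n_bins,
    )
    return Slice(pixels, center=c)
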