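"""Core data containers shared across the reconstruction pipeline.

Conventions
-----------
* Images are square ``size x size`` arrays indexed ``[row, col]``.  The
  image-centre convention is pixel-centre based: the rotation axis / image
  origin sits at pixel coordinate ``(size - 1) / 2`` on both axes, the x
  axis runs along columns (increasing right) and the y axis along rows
  (increasing *up*, i.e. ``y = center - row``).
* Sinograms store one projection per row (``n_angles x n_bins``).  The
  detector bin size is the unit of length; projection angles are measured
  from the +x axis and cover ``[0, pi)`` on an equispaced grid starting
  at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomImage", "Sinogram", "Slice"]


@dataclass
class PhantomImage:
    """Rasterized phantom: square array of grey values on [-1, 1]^2."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("phantom image must be a square 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("phantom image contains non-finite grey values")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def uniform_angles(n_angles: int) -> np.ndarray:
    """Equispaced projection angles over [0, pi), first angle 0."""
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    return np.arange(n_angles) * (np.pi / n_angles)


@dataclass
class Sinogram:
    """Parallel-beam line integrals p(t, phi), one projection per row.

    Attributes
    ----------
    data : (n_angles, n_bins) array
    angles : (n_angles,) array, strictly increasing, equispaced, angles[0]=0
    center : rotation-axis position in bin units (defaults to (n_bins-1)/2)
    """

    data: np.ndarray
    angles: np.ndarray = None
    center: float = None
    bin_spacing: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2D (angles x bins)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")
        if self.angles is None:
            self.angles = uniform_angles(self.data.shape[0])
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (self.data.shape[0],):
            raise ValueError("angles length must match number of projections")
        if self.angles.size > 1:
            steps = np.diff(self.angles)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("angles must be strictly increasing and equispaced")
        if abs(float(self.angles[0])) > 1e-12:
            raise ValueError("first projection angle must be 0")
        if self.center is None:
            self.center = (self.data.shape[1] - 1) / 2.0
        self.center = float(self.center)

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


@dataclass
class Slice:
    """Reconstructed 2D slice f(x, y) on a Cartesian grid."""

    pixels: np.ndarray
    center: float = None
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("slice must be a square 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite values")
        if self.center is None:
            self.center = (self.pixels.shape[0] - 1) / 2.0

    @property
    def size(self) -> int:
        return self.pixels.shape[0]
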