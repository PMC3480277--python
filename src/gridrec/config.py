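"""Reconstruction configuration with validation."""

from __future__ import annotations

from dataclasses import dataclass, asdict

from . import pswf
from .filters import FILTER_KINDS, WINDOW_KINDS

__all__ = ["ReconConfig"]

METHODS = ("gridrec", "fbp")
ORIGINS = ("pixel-center", "fft")


@dataclass
class ReconConfig:
    """All knobs of a reconstruction run.

    ``zeropad`` is the fraction of the original field of view appended
    on *each* side of every projection; ``oversample`` is the Cartesian
    Fourier grid size relative to the padded projection length.
    ``out_size`` defaults to the sinogram bin count.

    ``origin`` selects the image-grid convention: ``"pixel-center"``
    places the rotation axis at pixel coordinate (N-1)/2 (sub-pixel
    exact for even sizes), while ``"fft"`` is the convention of the
    classic FFT-based implementations, with the axis at pixel N//2 —
    half a pixel away for even sizes.  The conventions coincide for odd
    sizes.
    """

    method: str = "gridrec"
    filter: str = "bandlimited"
    window: str = "none"
    zeropad: float = 1.5
    oversample: float = 2.0
    kernel_c: float = pswf.DEFAULT_C
    kernel_half_width: int = pswf.DEFAULT_HALF_WIDTH
    kernel_table_density: int = pswf.DEFAULT_TABLE_DENSITY
    out_size: int = None
    origin: str = "pixel-center"
    mask_outside_circle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected {METHODS}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}; expected {ORIGINS}")
        if self.filter not in FILTER_KINDS:
            raise ValueError(
                f"unknown filter {self.filter!r}; expected {FILTER_KINDS}"
            )
        if self.window not in WINDOW_KINDS:
            raise ValueError(
                f"unknown window {self.window!r}; expected {WINDOW_KINDS}"
            )
        if self.zeropad < 0:
            raise ValueError("zeropad must be >= 0")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")
        if self.kernel_c <= 0 or self.kernel_half_width < 1:
            raise ValueError("invalid kernel parameters")
        if self.kernel_table_density < 256:
            raise ValueError("kernel_table_density must be >= 256")
        if self.out_size is not None and self.out_size < 1:
            raise ValueError("out_size must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ReconConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)
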