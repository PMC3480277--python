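"""Analytic test phantoms: Shepp-Logan ellipse models and a point pattern.

The phantoms are defined as additive collections of ellipses on the unit
square [-1, 1]^2.  Two canonical ten-ellipse tables are provided: the
original head phantom of Shepp & Logan (1974), whose outer "skull" shell
rasterizes to grey value 2.0, and the widespread low-contrast ("modified")
variant whose shell rasterizes to 1.0.  A third kind of phantom is a
resolution test pattern of 162 unit point sources laid out on concentric
circles, used to sample the reconstruction point-spread function across
the field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import PhantomImage, Sinogram

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "shepp_logan_spec",
    "make_shepp_logan",
    "make_point_pattern",
    "rasterize",
    "add_noise",
    "save_spec",
    "load_spec",
]

VARIANTS = ("standard", "modified")


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse: dimensionless coordinates in [-1, 1]."""

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation_deg: float
    intensity: float

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        r = math.hypot(self.center_x, self.center_y)
        if r + max(self.semi_axis_a, self.semi_axis_b) > 1.0 + 1e-9:
            raise ValueError("ellipse must lie inside the unit circle")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        a = math.radians(self.rotation_deg)
        dx = x - self.center_x
        dy = y - self.center_y
        u = dx * math.cos(a) + dy * math.sin(a)
        v = -dx * math.sin(a) + dy * math.cos(a)
        return (u / self.semi_axis_a) ** 2 + (v / self.semi_axis_b) ** 2 <= 1.0


# Canonical ten-ellipse tables (x0, y0, a, b, angle_deg, grey value).  The
# first column below is the grey value of the original 1974 head phantom;
# the second that of the low-contrast variant shipped with e.g. Matlab.
_GEOMETRY = [
    # x0,      y0,      a,      b,     angle
    (0.0, 0.0, 0.69, 0.92, 0.0),
    (0.0, -0.0184, 0.6624, 0.8740, 0.0),
    (0.22, 0.0, 0.1100, 0.3100, -18.0),
    (-0.22, 0.0, 0.1600, 0.4100, 18.0),
    (0.0, 0.35, 0.2100, 0.2500, 0.0),
    (0.0, 0.1, 0.0460, 0.0460, 0.0),
    (0.0, -0.1, 0.0460, 0.0460, 0.0),
    (-0.08, -0.605, 0.0460, 0.0230, 0.0),
    (0.0, -0.606, 0.0230, 0.0230, 0.0),
    (0.06, -0.605, 0.0230, 0.0460, 0.0),
]
_GREY = {
    "standard": (2.0, -0.98, -0.02, -0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01),
    "modified": (1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1),
}


@dataclass
class PhantomSpec:
    """Ordered ellipse list and/or point sources defining a phantom."""

    ellipses: tuple = ()
    variant: str = "standard"
    point_sources: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS + ("points",):
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of "
                f"{VARIANTS + ('points',)}"
            )
        self.ellipses = tuple(self.ellipses)
        self.point_sources = tuple(
            (float(x), float(y), float(a)) for x, y, a in self.point_sources
        )
        if self.variant == "points" and not self.point_sources:
            raise ValueError("points variant requires point_sources")


def shepp_logan_spec(variant: str = "standard") -> PhantomSpec:
    """Ellipse table of the standard (1974) or modified Shepp-Logan phantom."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    grey = _GREY[variant]
    ellipses = tuple(
        Ellipse(x0, y0, a, b, ang, g)
        for (x0, y0, a, b, ang), g in zip(_GEOMETRY, grey)
    )
    return PhantomSpec(ellipses=ellipses, variant=variant)


def pixel_coords(size: int) -> np.ndarray:
    """Pixel-centre coordinates on [-1, 1] for a size-pixel axis."""
    return (2.0 * np.arange(size) + 1.0) / size - 1.0


def rasterize(spec: PhantomSpec, size: int) -> PhantomImage:
    """Sample the additive model at pixel centres (no anti-aliasing).

    Point sources are deposited into the single pixel containing them.
    Row 0 is the top of the image (y decreases with row index).
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    xs = pixel_coords(size)
    x, y = np.meshgrid(xs, xs[::-1])
    img = np.zeros((size, size))
    for e in spec.ellipses:
        img[e.contains(x, y)] += e.intensity
    # additive grey values may cancel (e.g. 1 - 0.8 - 0.2); snap the
    # floating-point residue so exact table values survive
    img[np.abs(img) < 1e-12] = 0.0
    half = size / 2.0
    c = (size - 1) / 2.0
    for px, py, amp in spec.point_sources:
        col = int(round(px * half + c))
        row = int(round(c - py * half))
        img[row, col] += amp
    return PhantomImage(img)


def make_shepp_logan(size: int, variant: str = "standard") -> PhantomImage:
    """Rasterize the standard or modified Shepp-Logan phantom."""
    return rasterize(shepp_logan_spec(variant), size)


def make_point_pattern(
    size: int,
    n_rings: int = 9,
    n_points: int = 162,
    radius_max: float = 0.85,
    amplitude: float = 1.0,
) -> PhantomSpec:
    """Point-source resolution pattern on concentric circles.

    ``n_points`` unit point sources are spread over ``n_rings`` equally
    spaced radii, with ring populations proportional to radius (uniform
    areal density), apportioned by largest remainder so the total is
    exact.  Each ring is rotated by a fixed per-ring offset so points on
    different rings are not radially aligned.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if n_rings < 1 or n_points < n_rings:
        raise ValueError("need at least one point per ring")
    radii = radius_max * np.arange(1, n_rings + 1) / n_rings
    quota = n_points * radii / radii.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(remainder)[::-1][: n_points - counts.sum()]:
        counts[i] += 1
    pts = []
    for ring, (r, m) in enumerate(zip(radii, counts)):
        theta = 2 * np.pi * np.arange(m) / m + 0.4 * ring
        pts.extend((r * math.cos(t), r * math.sin(t), amplitude) for t in theta)
    spec = PhantomSpec(variant="points", point_sources=tuple(pts))
    # every point must land in its own pixel of the target grid
    half, c = size / 2.0, (size - 1) / 2.0
    cells = {
        (int(round(c - y * half)), int(round(x * half + c)))
        for x, y, _ in spec.point_sources
    }
    if len(cells) != len(spec.point_sources):
        raise ValueError(f"size {size} too small to separate {n_points} points")
    return spec


def add_noise(sino: Sinogram, sigma: float, seed: int) -> Sinogram:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        data = sino.data.copy()
    else:
        rng = np.random.default_rng(seed)
        data = sino.data + rng.normal(0.0, sigma, size=sino.data.shape)
    return Sinogram(data, angles=sino.angles.copy(), center=sino.center)


def save_spec(spec: PhantomSpec, path) -> None:
    """Write a phantom spec as plain text, one primitive per line."""
    lines = [f"# variant: {spec.variant}"]
    for e in spec.ellipses:
        lines.append(
            f"ellipse {e.center_x} {e.center_y} {e.semi_axis_a} "
            f"{e.semi_axis_b} {e.rotation_deg} {e.intensity}"
        )
    for x, y, a in spec.point_sources:
        lines.append(f"point {x} {y} {a}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_spec(path) -> PhantomSpec:
    """Read a phantom spec written by :func:`save_spec`."""
    variant = "standard"
    ellipses, points = [], []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            if "variant:" in ln:
                variant = ln.split("variant:")[1].strip()
            continue
        kind, *vals = ln.split()
        vals = [float(v) for v in vals]
        if kind == "ellipse":
            ellipses.append(Ellipse(*vals))
        elif kind == "point":
            points.append(tuple(vals))
        else:
            raise ValueError(f"unknown record {kind!r} in {path}")
    return PhantomSpec(
        ellipses=tuple(ellipses), variant=variant, point_sources=tuple(points)
    )
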