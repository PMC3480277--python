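"""Accuracy instruments: line profiles, regional histograms, background
offset and the point-spread-function / FWHM resolution procedure."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PhantomImage, Slice
from .phantoms import PhantomSpec

__all__ = [
    "ProfileResult",
    "PSFSummary",
    "line_profile",
    "grey_histogram",
    "background_offset",
    "background_mask",
    "measure_psf_fwhm",
]


@dataclass
class ProfileResult:
    positions: np.ndarray
    values: np.ndarray


@dataclass
class PSFSummary:
    """Averaged point-spread summary over a point test pattern."""

    n_points: int
    radii: np.ndarray
    mean_curve: np.ndarray
    fwhm: float


def _pixels(img) -> np.ndarray:
    if isinstance(img, (Slice, PhantomImage)):
        return img.pixels
    return np.asarray(img)


def line_profile(img, row: int) -> ProfileResult:
    """Pixel values along one image row."""
    pix = _pixels(img)
    if not 0 <= row < pix.shape[0]:
        raise ValueError(f"row {row} outside image of size {pix.shape[0]}")
    return ProfileResult(np.arange(pix.shape[1]), pix[row].copy())


def grey_histogram(img, region, n_bins: int = 256):
    """Histogram of grey values over a rectangular region.

    ``region`` is (row0, row1, col0, col1), half-open.  Bins are equal
    width over the region's value range; counts sum to the region area.
    """
    pix = _pixels(img)
    r0, r1, c0, c1 = region
    if not (0 <= r0 < r1 <= pix.shape[0] and 0 <= c0 < c1 <= pix.shape[1]):
        raise ValueError("region empty or outside image")
    sub = pix[r0:r1, c0:c1].ravel()
    lo, hi = sub.min(), sub.max()
    if hi == lo:
        hi = lo + 1.0  # uniform region: single occupied bin
    counts, edges = np.histogram(sub, bins=n_bins, range=(lo, hi))
    return counts, edges


def background_mask(spec: PhantomSpec, size: int, margin: float = 0.05) -> np.ndarray:
    """Pure-background pixels: outside every (inflated) ellipse, inside
    the field-of-view circle shrunk by ``margin``."""
    xs = (2.0 * np.arange(size) + 1.0) / size - 1.0
    x, y = np.meshgrid(xs, xs[::-1])
    mask = x**2 + y**2 <= (1.0 - margin) ** 2
    for e in spec.ellipses:
        grown = type(e)(
            e.center_x,
            e.center_y,
            min(e.semi_axis_a + margin, 1.0),
            min(e.semi_axis_b + margin, 1.0),
            e.rotation_deg,
            e.intensity,
        )
        mask &= ~grown.contains(x, y)
    return mask


def background_offset(img, truth, mask: np.ndarray) -> float:
    """Mean of (reconstruction - truth) over a pure-background mask."""
    pix, ref = _pixels(img), _pixels(truth)
    if pix.shape != ref.shape or mask.shape != pix.shape:
        raise ValueError("image, truth and mask shapes must match")
    if not mask.any():
        raise ValueError("background mask is empty")
    if np.any(ref[mask] != 0):
        raise ValueError("mask touches nonzero ground-truth pixels")
    return float(np.mean(pix[mask] - ref[mask]))


def _point_pixels(spec: PhantomSpec, size: int) -> np.ndarray:
    c, half = (size - 1) / 2.0, size / 2.0
    return np.array(
        [
            (int(round(c - y * half)), int(round(x * half + c)))
            for x, y, _ in spec.point_sources
        ],
        dtype=int,
    )


def measure_psf_fwhm(
    img, spec: PhantomSpec, window_half: int = 8
) -> PSFSummary:
    """Average the recovered point structures and measure their FWHM.

    For each known point location a (2w+1)^2 window is extracted and
    checked for a bell shape (single dominant maximum near the centre);
    all windows are averaged, radially binned (unit-width annuli, using
    each annulus' mean radius), and the full width at half of
    (peak - baseline) is found by linear interpolation.  The baseline is
    the median of the window rim.
    """
    pix = _pixels(img)
    size = pix.shape[0]
    if spec.variant != "points" or not spec.point_sources:
        raise ValueError("spec must be a points-variant phantom")
    centers = _point_pixels(spec, size)
    d = centers[:, None, :] - centers[None, :, :]
    sep = np.abs(d).max(axis=2) + np.eye(len(centers)) * size
    if sep.min() <= 2 * window_half:
        raise ValueError("point windows overlap; reduce window_half")
    w = window_half
    stack = []
    for r, c in centers:
        if not (w <= r < size - w and w <= c < size - w):
            raise ValueError("point window crosses the image border")
        win = pix[r - w : r + w + 1, c - w : c + w + 1]
        pr, pc = np.unravel_index(np.argmax(win), win.shape)
        if max(abs(pr - w), abs(pc - w)) > 2:
            raise ValueError(
                f"structure at ({r}, {c}) is not a centred bell "
                f"(max at offset ({pr - w}, {pc - w}))"
            )
        stack.append(win)
    mean_win = np.mean(stack, axis=0)
    yy, xx = np.mgrid[-w : w + 1, -w : w + 1]
    rad = np.hypot(yy, xx)
    rim = mean_win[rad >= w]
    baseline = float(np.median(rim))
    # half-pixel annuli, each represented by its exact mean radius,
    # keep the linear interpolation of the half-maximum crossing tight
    nbin = np.round(2.0 * rad).astype(int)
    radii, curve = [], []
    for b in range(2 * w + 1):
        sel = nbin == b
        if sel.any():
            radii.append(rad[sel].mean())
            curve.append(mean_win[sel].mean())
    radii, curve = np.array(radii), np.array(curve)
    peak = curve[0]
    half_level = baseline + 0.5 * (peak - baseline)
    below = np.nonzero(curve <= half_level)[0]
    if peak <= baseline or below.size == 0:
        raise ValueError("no half-maximum crossing found")
    i = below[0]
    r_half = radii[i - 1] + (radii[i] - radii[i - 1]) * (
        curve[i - 1] - half_level
    ) / (curve[i - 1] - curve[i])
    return PSFSummary(
        n_points=len(centers), radii=radii, mean_curve=curve, fwhm=float(2 * r_half)
    )


def per_point_fwhm(img, spec: PhantomSpec, window_half: int = 8) -> np.ndarray:
    """FWHM of each individual point structure (spatial-invariance check)."""
    pix = _pixels(img)
    out = []
    for x, y, a in spec.point_sources:
        single = PhantomSpec(variant="points", point_sources=((x, y, a),))
        out.append(measure_psf_fwhm(pix, single, window_half).fwhm)
    return np.array(out)
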