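"""Forward projection: analytic ellipse/point sinograms and a discrete Radon
transform for arbitrary rasterized images.

Line integrals are expressed in detector-bin units: the detector spans the
phantom's [-1, 1] field of view with ``n_bins`` bins of size 1, so a disc
of radius ``r`` (unit coordinates) and grey value ``mu`` projects to a
central value ``2 * (r * n_bins / 2) * mu``.  With this scale a
reconstruction on the same grid recovers grey values directly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import PhantomImage, Sinogram, uniform_angles
from .phantoms import PhantomSpec

__all__ = ["project_ellipses", "project_image", "ellipse_projection"]


def ellipse_projection(ellipse, angles: np.ndarray, t_unit: np.ndarray) -> np.ndarray:
    """Exact chord-length integrals of one ellipse, unit-coordinate scale.

    Returns an (n_angles, n_t) array of line integrals of the indicator
    of the ellipse times its grey value, for detector coordinate ``t``
    (unit coords) at each angle.
    """
    a = np.radians(ellipse.rotation_deg)
    phi = angles[:, None] - a
    asq = (ellipse.semi_axis_a * np.cos(phi)) ** 2 + (
        ellipse.semi_axis_b * np.sin(phi)
    ) ** 2
    t0 = ellipse.center_x * np.cos(angles)[:, None] + ellipse.center_y * np.sin(
        angles
    )[:, None]
    d2 = asq - (t_unit[None, :] - t0) ** 2
    p = (
        2.0
        * ellipse.intensity
        * ellipse.semi_axis_a
        * ellipse.semi_axis_b
        / asq
        * np.sqrt(np.clip(d2, 0.0, None))
    )
    return p


def project_ellipses(spec: PhantomSpec, n_angles: int, n_bins: int) -> Sinogram:
    """Analytic sinogram of an additive ellipse (or point) phantom.

    Ellipse entries are exact chord integrals; point sources deposit
    their amplitude into the bin containing the signed projection
    coordinate ``t0 = x cos(phi) + y sin(phi)``.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    angles = uniform_angles(n_angles)
    center = (n_bins - 1) / 2.0
    t_unit = (np.arange(n_bins) - center) * (2.0 / n_bins)
    data = np.zeros((n_angles, n_bins))
    for e in spec.ellipses:
        data += ellipse_projection(e, angles, t_unit)
    data *= n_bins / 2.0  # unit length -> bin units
    half = n_bins / 2.0
    for x, y, amp in spec.point_sources:
        t0 = (x * np.cos(angles) + y * np.sin(angles)) * half + center
        bins = np.round(t0).astype(int)
        ok = (bins >= 0) & (bins < n_bins)
        data[np.arange(n_angles)[ok], bins[ok]] += amp
    return Sinogram(data, angles=angles, center=center)


def project_image(img: PhantomImage, n_angles: int) -> Sinogram:
    """Discrete Radon transform of a rasterized image.

    The image is rotated (bilinear resampling) so that the projection
    direction aligns with image rows, then summed along rows; the number
    of detector bins equals the image size.
    """
    pixels = np.asarray(img.pixels if isinstance(img, PhantomImage) else img)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("image must be square")
    n = pixels.shape[0]
    angles = uniform_angles(n_angles)
    data = np.empty((n_angles, n))
    for m, phi in enumerate(angles):
        # rotating the *image content* by -phi maps the projection
        # direction onto columns; with row 0 at the top (y = c - row),
        # ndimage.rotate's positive angle turns content clockwise in
        # (x, y), so the angle below is chosen to match the analytic
        # projector's convention t = x cos(phi) + y sin(phi).
        rot = ndimage.rotate(
            pixels, np.degrees(phi), reshape=False, order=1, prefilter=False
        )
        data[m] = rot.sum(axis=0)
    return Sinogram(data, angles=angles, center=(n - 1) / 2.0)
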