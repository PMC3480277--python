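"""Numba-compiled inner loops: Fourier-grid scatter and back-projection."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _deposit(grid, table, table_density, half_width, u, v, val):
    g = grid.shape[0]
    tmax = table.size - 2
    # epsilon margin keeps cells at exactly half_width distance inside
    # the footprint under ~1e-15 rounding of the sample position
    i0 = int(np.ceil(u - half_width - 1e-9))
    i1 = int(np.floor(u + half_width + 1e-9))
    j0 = int(np.ceil(v - half_width - 1e-9))
    j1 = int(np.floor(v + half_width + 1e-9))
    for i in range(i0, i1 + 1):
        pos = abs(i - u) * table_density
        idx = int(pos)
        if idx > tmax:
            idx = tmax
        fr = pos - idx
        wi = table[idx] * (1.0 - fr) + table[idx + 1] * fr
        ii = i % g
        for j in range(j0, j1 + 1):
            pos = abs(j - v) * table_density
            idx = int(pos)
            if idx > tmax:
                idx = tmax
            fr = pos - idx
            wj = table[idx] * (1.0 - fr) + table[idx + 1] * fr
            grid[ii, j % g] += val * (wi * wj)


@njit(cache=True)
def scatter_polar(spectrum, angles, grid, table, table_density, half_width, shift):
    """Accumulate weighted polar Fourier samples onto a Cartesian grid.

    spectrum : (M, P) complex, per-angle FFT rows in wrap-around order,
        already scaled by the filter and the measure factors.
    grid : (G, G) complex, modified in place; axis 0 = u, axis 1 = v, in
        wrap-around (FFT) frequency order.
    table : kernel lookup on [0, half_width] cells, table_density per cell.
    shift : fractional image-coordinate offset applied as a linear phase
        at each sample's *continuous* frequency, so that the later 2D
        inverse FFT is evaluated at integer grid positions (which keeps
        kernel footprints that wrap across the Nyquist boundary exact).
    """
    n_angles, p_len = spectrum.shape
    g = grid.shape[0]
    os_eff = g / p_len  # radial sample spacing in grid cells
    half = p_len // 2
    for m in range(n_angles):
        cphi = np.cos(angles[m])
        sphi = np.sin(angles[m])
        for kidx in range(p_len):
            if kidx == half:
                # The unpaired Nyquist bin of the even-length FFT is
                # split half/half between +-P/2 to keep the gridded
                # spectrum Hermitian.  The stored bin carries the
                # rotation-axis phase evaluated at -1/2 cycles/bin; for
                # real projections the +P/2 copy is its conjugate.
                for sgn in (-1.0, 1.0):
                    u = sgn * half * os_eff * cphi
                    v = sgn * half * os_eff * sphi
                    base = spectrum[m, kidx] if sgn < 0 else np.conj(spectrum[m, kidx])
                    val = 0.5 * base * np.exp(-2j * np.pi * (u + v) * shift / g)
                    _deposit(grid, table, table_density, half_width, u, v, val)
                continue
            k = kidx if kidx < half else kidx - p_len
            u = k * os_eff * cphi
            v = k * os_eff * sphi
            val = spectrum[m, kidx] * np.exp(-2j * np.pi * (u + v) * shift / g)
            _deposit(grid, table, table_density, half_width, u, v, val)


@njit(cache=True)
def backproject(filtered, angles, center, out_size, out_center):
    """Linear-interpolation back-projection of filtered projections.

    filtered : (M, P) real filtered projections; center is the rotation
    axis position within the padded row, out_center the axis position in
    the output image.  Returns the (out_size, out_size) accumulation
    (the pi/M angular measure is applied here).
    """
    n_angles, p_len = filtered.shape
    out = np.zeros((out_size, out_size))
    c = out_center
    for m in range(n_angles):
        cphi = np.cos(angles[m])
        sphi = np.sin(angles[m])
        for i in range(out_size):
            y = c - i
            base = y * sphi + center
            for j in range(out_size):
                t = (j - c) * cphi + base
                n0 = int(np.floor(t))
                if 0 <= n0 < p_len - 1:
                    fr = t - n0
                    out[i, j] += filtered[m, n0] * (1.0 - fr) + filtered[m, n0 + 1] * fr
    return out * (np.pi / n_angles)
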