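"""Independent slow oracles used to validate the FFT-based implementation."""

import numpy as np


def rayleigh_sommerfeld_scattered(mask, pitch, distance, wavelength):
    """Direct Rayleigh-Sommerfeld (first kind) sum of the field scattered by
    an aperture-function ``mask``, evaluated on the same grid.

    O(N_source * N_grid): only nonzero mask pixels contribute, so keep the
    silhouette small.  Serves as the independent diffraction oracle for the
    angular-spectrum renderer.
    """
    ys, xs = np.nonzero(mask > 0)
    weights = mask[ys, xs]
    ny, nx = mask.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    k = 2.0 * np.pi / wavelength
    out = np.zeros(mask.shape, dtype=complex)
    for y0, x0, w in zip(ys, xs, weights):
        dx = (xx - x0) * pitch
        dy = (yy - y0) * pitch
        rho = np.sqrt(distance**2 + dx * dx + dy * dy)
        out += w * (distance / rho) * np.exp(1j * k * rho) / (1j * wavelength * rho)
    return out * pitch**2


def truncated_power_law_cdf(d, slope, d_min, d_max):
    """Closed-form CDF of a truncated power law n(d) ~ d**slope."""
    p = slope + 1.0
    return (d**p - d_min**p) / (d_max**p - d_min**p)


def frustum_volume_fraction(z, boundary):
    """Analytic fraction of frustum volume below axial distance z."""
    slope = (boundary.r1 - boundary.r2) / (boundary.z_max - boundary.z_min)

    def integral(zz):
        r = boundary.r2 + slope * (zz - boundary.z_min)
        if slope == 0:
            return boundary.r2**2 * (zz - boundary.z_min)
        return (r**3 - boundary.r2**3) / (3.0 * slope)

    return integral(z) / integral(boundary.z_max)
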