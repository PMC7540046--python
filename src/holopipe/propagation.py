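"""Scalar wavefield propagation for point-source holography.

Point-source (spherical-wave) geometry is reduced to an equivalent
collimated problem via the Fresnel scaling theorem: an object at distance z
from the source, imaged on a sensor at distance L, produces the same
intensity pattern as the same object magnified by M = L/z and propagated a
distance

    D(z) = z_eff * M^2 = L * (L - z) / z

in collimated light, sampled directly on the sensor grid.  Propagation over
D is done with the band-limited angular spectrum method: exact for
propagating waves, with the transfer function truncated at the local-frequency
limit (Matsushima & Shimobaba) to suppress FFT wrap-around aliasing.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "angular_spectrum_propagate",
    "band_limit_mask",
    "effective_distance",
]


def effective_distance(z: float, source_camera_distance: float) -> float:
    """Equivalent collimated propagation distance D(z) = L (L - z) / z for an
    object at z in point-source geometry, expressed on the sensor grid."""
    L = source_camera_distance
    if not (0 < z < L):
        raise ValueError("object distance must lie strictly between 0 and L")
    return L * (L - z) / z


def _frequency_grids(shape, pitch):
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    return np.meshgrid(fy, fx, indexing="ij")


def band_limit_mask(shape, pitch, distance, wavelength):
    """Frequency-domain mask for band-limited angular-spectrum propagation.

    Evanescent components are always removed; for |distance| > 0 the band is
    further limited so the transfer-function phase stays sampled below the
    Nyquist rate of the frequency grid.
    """
    fy, fx = _frequency_grids(shape, pitch)
    mask = (fx**2 + fy**2) < (1.0 / wavelength) ** 2
    if distance != 0:
        dfy = 1.0 / (shape[0] * pitch)
        dfx = 1.0 / (shape[1] * pitch)
        fy_lim = 1.0 / (wavelength * np.sqrt((2.0 * abs(distance) * dfy) ** 2 + 1.0))
        fx_lim = 1.0 / (wavelength * np.sqrt((2.0 * abs(distance) * dfx) ** 2 + 1.0))
        mask &= (np.abs(fy) <= fy_lim) & (np.abs(fx) <= fx_lim)
    return mask


def angular_spectrum_propagate(field, pitch, distance, wavelength):
    """Propagate a complex field sampled at `pitch` (um) over `distance` (um).

    Positive distances propagate away from the source (toward the camera),
    negative distances refocus back toward it.  Propagation restricted to the
    non-aliased propagating band is unitary, so a band-limited field
    round-trips (+D then -D) to machine precision.
    """
    field = np.asarray(field, dtype=np.complex128)
    fy, fx = _frequency_grids(field.shape, pitch)
    mask = band_limit_mask(field.shape, pitch, distance, wavelength)
    fz2 = (1.0 / wavelength) ** 2 - fx**2 - fy**2
    fz = np.sqrt(np.maximum(fz2, 0.0))
    transfer = np.exp(2j * np.pi * distance * fz) * mask
    return np.fft.ifft2(np.fft.fft2(field) * transfer)
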