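"""Instrument geometry shared by the simulator and the reconstruction code.

The instrument is a lensless, point-source inline holographic microscope: a
laser behind a sub-micron pinhole emits a diverging spherical wave; particles
in the cone between source and camera cast magnified diffraction patterns
onto the sensor.  All distances are measured in micrometres from the point
source, with +z along the optical axis toward the camera and x, y transverse.

Two geometric objects matter downstream:

``OpticsConfig``
    wavelength, source-camera distance L, sensor pitch/shape, and the axial
    range over which holograms are numerically refocused.  The transverse
    magnification of an object at distance z is M = L / z.

``BeamBoundary``
    the conical-frustum envelope within which particles are actually sampled
    and detected.  Its radii describe the *effective* detection envelope
    drawn around observed particle positions, which is much narrower than
    the geometric illumination cone, so the default taper is gentle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "OpticsConfig",
    "BeamBoundary",
    "default_beam_boundary",
    "frustum_volume_ml",
    "sweet_spot_fraction",
    "UL_PER_ML",
    "UM3_PER_ML",
    "DEFAULT_WORKING_VOLUME_ML",
    "ABSTRACT_WORKING_VOLUME_ML",
    "SWEET_SPOT_VOLUME_ML",
]

UM3_PER_ML = 1.0e12  # 1 mL = 1 cm^3 = 1e12 um^3
UL_PER_ML = 1000.0

#: Working imaging volume computed from the beam geometry (default preset).
DEFAULT_WORKING_VOLUME_ML = 0.063
#: Alternative nominal per-image volume quoted for this instrument class.
ABSTRACT_WORKING_VOLUME_ML = 0.1
#: Volume of the "sweet spot" of maximal illumination and image quality.
SWEET_SPOT_VOLUME_ML = 0.030


@dataclass(frozen=True)
class OpticsConfig:
    """Point-source DIHM geometry and illumination parameters.

    Parameters
    ----------
    wavelength : float
        Laser wavelength in um (386 nm source -> 0.386).
    source_camera_distance : float
        Path length L from pinhole to sensor in um (10 cm -> 100,000).
    pixel_pitch : float
        Sensor pixel pitch in um.
    sensor_shape : tuple of int
        (rows, cols) of the sensor.
    reconstruction_z_range : tuple of float
        (z_min, z_max) in um from the source over which focal planes are
        computed; spans the 18 mm viewable focal depth by default.
    frame_rate : float
        Acquisition rate in frames per second (metadata only).
    """

    wavelength: float = 0.386
    source_camera_distance: float = 100_000.0
    pixel_pitch: float = 7.4
    sensor_shape: tuple[int, int] = (2056, 2060)
    reconstruction_z_range: tuple[float, float] = (1_000.0, 19_000.0)
    frame_rate: float = 16.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        zlo, zhi = self.reconstruction_z_range
        if not (0 < zlo < zhi < self.source_camera_distance):
            raise ValueError(
                "reconstruction_z_range must satisfy 0 < z_min < z_max < L"
            )
        if any(n <= 0 for n in self.sensor_shape):
            raise ValueError("sensor_shape must be positive")

    def magnification(self, z: float) -> float:
        """Transverse magnification M = L / z of an object at distance z."""
        if z <= 0:
            raise ValueError("z must be positive")
        return self.source_camera_distance / z


class InvalidGeometryError(ValueError):
    """Raised for degenerate beam boundaries."""


@dataclass(frozen=True)
class BeamBoundary:
    """Conical-frustum sampling envelope.

    ``r2`` is the radius at the near (source-side, ``z_min``) end and ``r1``
    the radius at the far (camera-side, ``z_max``) end, following the
    convention that the beam widens toward the camera (r1 = r2 gives a
    cylindrical envelope).

    ``working_volume_override`` (mL), when set, is what volume bookkeeping
    reports instead of the geometric frustum volume; it defaults to the
    instrument's calibrated 0.063 mL working volume.
    """

    r1: float
    r2: float
    z_min: float
    z_max: float
    working_volume_override: float | None = DEFAULT_WORKING_VOLUME_ML

    def __post_init__(self) -> None:
        if not (0 < self.z_min < self.z_max):
            raise InvalidGeometryError("need 0 < z_min < z_max")
        if not (self.r1 >= self.r2 >= 0) or self.r1 <= 0:
            raise InvalidGeometryError("need r1 >= r2 >= 0 with r1 > 0")
        if self.working_volume_override is not None and (
            self.working_volume_override <= 0
        ):
            raise InvalidGeometryError("working volume override must be > 0")

    def radius_at(self, z):
        """Beam radius at axial distance z (linear interpolation)."""
        frac = (z - self.z_min) / (self.z_max - self.z_min)
        return self.r2 + frac * (self.r1 - self.r2)

    def contains(self, x, y, z) -> bool:
        import numpy as np

        r = np.hypot(x, y)
        inside_z = (z >= self.z_min) & (z <= self.z_max)
        return bool(np.all(inside_z & (r <= self.radius_at(z))))

    @property
    def geometric_volume_ml(self) -> float:
        h = self.z_max - self.z_min
        return (
            math.pi
            * h
            / 3.0
            * (self.r1**2 + self.r1 * self.r2 + self.r2**2)
            / UM3_PER_ML
        )


def frustum_volume_ml(boundary: BeamBoundary) -> float:
    """Geometric frustum volume in mL, ignoring any override."""
    return boundary.geometric_volume_ml


def default_beam_boundary(
    z_min: float = 1_000.0,
    z_max: float = 19_000.0,
    taper: float = 1.3,
    volume_ml: float = DEFAULT_WORKING_VOLUME_ML,
) -> BeamBoundary:
    """Default detection envelope: a gently tapering frustum spanning the
    viewable focal depth, with radii scaled so its geometric volume equals
    the calibrated working volume.

    The taper ratio r1/r2 = 1.3 reflects an empirically drawn detection
    envelope rather than the geometric light cone: detected-particle clouds
    are far narrower than the illumination cone because image quality decays
    off-axis.
    """
    if taper <= 1:
        raise InvalidGeometryError("taper ratio must exceed 1")
    h = z_max - z_min
    # V = pi h/3 (r1^2 + r1 r2 + r2^2) with r1 = taper * r2
    quad = taper**2 + taper + 1.0
    r2 = math.sqrt(volume_ml * UM3_PER_ML * 3.0 / (math.pi * h * quad))
    return BeamBoundary(
        r1=taper * r2, r2=r2, z_min=z_min, z_max=z_max,
        working_volume_override=volume_ml,
    )


def sweet_spot_fraction(
    sweet_volume_ml: float = SWEET_SPOT_VOLUME_ML,
    working_volume_ml: float = DEFAULT_WORKING_VOLUME_ML,
) -> float:
    """Percentage of the sampling volume occupied by the sweet spot.

    The sweet spot is the central sub-volume of maximal illumination and
    image quality, located along the optical axis roughly midway between
    source and detector.
    """
    if sweet_volume_ml <= 0 or working_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    return 100.0 * sweet_volume_ml / working_volume_ml
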