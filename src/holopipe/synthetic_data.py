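"""Ground-truthed synthetic scenes and holograms.

Every downstream stage (refocusing, detection, corrections, statistics) is
validated against scenes generated here, so no recorded hologram data is
needed.  The simulator emulates the point-source instrument: opaque
particles in the conical beam cast magnified diffraction patterns onto the
sensor.  Each particle's scattered field is computed by Babinet's principle
from its magnified silhouette, propagated over the Fresnel-scaled distance
D(z) = L (L - z) / z with the band-limited angular-spectrum method, and the
scattered fields of all particles are superposed on the unit reference wave
(accurate for the sparse scenes simulated here).  Additive Gaussian sensor
noise, clipped at zero, models shot/readout noise on the normalized
intensity.

Particle populations follow the study conditions: positions uniform per unit
volume in the beam frustum (well-mixed suspension), diameters from a
truncated power law (Junge-type spectrum), and optional thinning by the
separable Gaussian detection-probability model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corrections import DetectionProbabilityModel, scaling_coefficient
from .optics import BeamBoundary, OpticsConfig
from .propagation import angular_spectrum_propagate, effective_distance
from .reconstruction import Hologram

__all__ = [
    "GroundTruthParticle",
    "SyntheticScene",
    "sample_beam_positions",
    "sample_junge_diameters",
    "thin_by_detection_probability",
    "render_hologram",
    "render_sequence",
]


@dataclass(frozen=True)
class GroundTruthParticle:
    """One simulated particle: position (um from the source, +z toward the
    camera), equivalent spherical diameter (um), and silhouette shape."""

    center: tuple[float, float, float]
    diameter: float
    shape: str = "disk"
    aspect_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.shape not in ("disk", "ellipse"):
            raise ValueError("shape must be 'disk' or 'ellipse'")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect ratio must be >= 1")


@dataclass
class SyntheticScene:
    """A particle population plus optics and a sensor-noise level.

    Identical seed and parameters reproduce the rendered hologram
    bit-for-bit.
    """

    particles: list[GroundTruthParticle] = field(default_factory=list)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    noise_sd: float = 0.01
    seed: int = 0


def sample_beam_positions(n: int, boundary: BeamBoundary, seed: int):
    """Uniform-per-volume positions inside the conical frustum.

    The axial coordinate is drawn by inverse-CDF sampling of the frustum
    cross-section R(z)^2 (the cube of the local radius is uniform for a
    linearly tapering beam), the radial coordinate as R(z) * sqrt(U) with a
    uniform azimuth.  Returns an (n, 3) array of (x, y, z) in um.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 3))
    slope = (boundary.r1 - boundary.r2) / (boundary.z_max - boundary.z_min)
    u = rng.random(n)
    if slope > 0:
        rz = np.cbrt(boundary.r2**3 + u * (boundary.r1**3 - boundary.r2**3))
        z = boundary.z_min + (rz - boundary.r2) / slope
    else:  # cylinder
        rz = np.full(n, boundary.r1)
        z = boundary.z_min + u * (boundary.z_max - boundary.z_min)
    r = rz * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def sample_junge_diameters(
    n: int, spectral_slope: float, d_min: float, d_max: float, seed: int
):
    """Diameters (um) from a truncated power law n(d) proportional to
    d**spectral_slope on [d_min, d_max], by inverse-CDF sampling.

    ``spectral_slope`` is the log-log slope of the binwidth-normalized size
    spectrum (e.g. -4 for the steep oceanic surface-layer case); slopes
    >= -1 are rejected as they do not correspond to a normalizable
    decreasing spectrum under this convention.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not d_min < d_max:
        raise ValueError("need d_min < d_max")
    if spectral_slope >= -1:
        raise ValueError("spectral slope must be < -1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    p = spectral_slope + 1.0
    return (d_min**p + u * (d_max**p - d_min**p)) ** (1.0 / p)


def thin_by_detection_probability(
    positions, model: DetectionProbabilityModel, seed: int
):
    """Keep each position independently with probability C(x, y, z).

    Emulates nonuniform detection: particles far off-axis or far from the
    axial detection peak are dropped most often.  Returns the accepted
    subset as an (m, 3) array.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] == 0:
        return pos.reshape(0, 3)
    rng = np.random.default_rng(seed)
    c = scaling_coefficient(pos, model)
    keep = rng.random(pos.shape[0]) < c
    return pos[keep]


def _silhouette(particle: GroundTruthParticle, optics: OpticsConfig):
    """Anti-aliased magnified silhouette of the particle on the sensor grid."""
    x, y, z = particle.center
    m = optics.magnification(z)
    pitch = optics.pixel_pitch
    ny, nx = optics.sensor_shape
    # ESD-preserving ellipse semi-axes (um, object plane)
    q = np.sqrt(particle.aspect_ratio)
    ax_ = 0.5 * particle.diameter * q
    ay_ = 0.5 * particle.diameter / q
    # magnified semi-axes in sensor pixels
    ax_px = ax_ * m / pitch
    ay_px = ay_ * m / pitch
    col0 = (nx - 1) / 2.0 + x * m / pitch
    row0 = (ny - 1) / 2.0 + y * m / pitch
    rows = np.arange(ny)[:, None] - row0
    cols = np.arange(nx)[None, :] - col0
    rho = np.sqrt((cols / ax_px) ** 2 + (rows / ay_px) ** 2)
    # ~1 px wide anti-aliased edge
    return np.clip((1.0 - rho) * min(ax_px, ay_px) + 0.5, 0.0, 1.0)


def render_hologram(scene: SyntheticScene) -> Hologram:
    """Render the interference intensity of a scene on the sensor.

    An empty, noise-free scene yields a uniform unit field.  Particles whose
    axial position lies outside the configured refocusing range are rendered
    anyway with a warning ("ghost particles": they contribute fringes but no
    recoverable in-focus image).
    """
    optics = scene.optics
    L = optics.source_camera_distance
    zlo, zhi = optics.reconstruction_z_range
    scattered = np.zeros(optics.sensor_shape, dtype=np.complex128)
    for particle in scene.particles:
        z = particle.center[2]
        if not (0 < z < L):
            raise ValueError(f"particle at z={z} um lies outside (0, L)")
        m = optics.magnification(z)
        if particle.diameter * m < 2.0 * optics.pixel_pitch:
            raise ValueError(
                f"particle of {particle.diameter} um at z={z} um is not "
                "resolvable (magnified image below 2 pixels)"
            )
        if not (zlo <= z <= zhi):
            warnings.warn(
                f"particle at z={z} um is outside the reconstruction range "
                f"[{zlo}, {zhi}] um and will appear as a ghost",
                stacklevel=2,
            )
        mask = _silhouette(particle, optics)
        scattered += angular_spectrum_propagate(
            mask, optics.pixel_pitch, effective_distance(z, L),
            optics.wavelength,
        )
    intensity = np.abs(1.0 - scattered) ** 2
    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        level = float(intensity.mean())
        intensity = intensity + rng.normal(
            0.0, scene.noise_sd * level, size=intensity.shape
        )
        intensity = np.clip(intensity, 0.0, None)
    return Hologram(intensity=intensity, frame_index=0, optics=optics)


def render_sequence(
    scenes: list[SyntheticScene],
    stuck_particle: GroundTruthParticle | None = None,
) -> list[Hologram]:
    """Render an ordered frame sequence, optionally with a stationary
    "stuck" particle repeated identically in every frame (emulating debris
    adhered to an instrument window, which median background correction
    should remove)."""
    frames = []
    for i, scene in enumerate(scenes):
        if stuck_particle is not None:
            scene = SyntheticScene(
                particles=list(scene.particles) + [stuck_particle],
                optics=scene.optics,
                noise_sd=scene.noise_sd,
                seed=scene.seed,
            )
        holo = render_hologram(scene)
        holo.frame_index = i
        frames.append(holo)
    return frames
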