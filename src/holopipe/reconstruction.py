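"""Background correction and numerical refocusing of point-source holograms.

A hologram records the 2D interference intensity of the diverging reference
wave with light scattered by particles in the cone.  Refocusing propagates
the hologram's contrast field back toward the source; at the distance z
where a particle sat, its silhouette reappears as a compact region of high
contrast magnitude whose object-plane size is recovered by dividing sensor
coordinates by the magnification M = L / z.

Background correction uses the running pixel-wise median of neighbouring
frames (three before and three after), which removes stationary patterns
such as particles stuck to the instrument windows; by default the frame is
*divided* by the median (standard inline-holography normalization), with
plain subtraction available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .optics import OpticsConfig
from .propagation import angular_spectrum_propagate, effective_distance

__all__ = [
    "Hologram",
    "FocalPlane",
    "InvalidDistanceError",
    "subtract_background",
    "reconstruct_plane",
    "reconstruct_stack",
]

logger = logging.getLogger(__name__)


class InvalidDistanceError(ValueError):
    """Reconstruction distance outside (0, L)."""


@dataclass
class Hologram:
    """Recorded interference intensity pattern for one frame."""

    intensity: np.ndarray
    frame_index: int
    optics: OpticsConfig

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2D array")
        if tuple(self.intensity.shape) != tuple(self.optics.sensor_shape):
            raise ValueError(
                f"hologram shape {self.intensity.shape} does not match "
                f"sensor shape {self.optics.sensor_shape}"
            )
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")


@dataclass
class FocalPlane:
    """Refocused contrast-amplitude image at source distance z (um).

    ``amplitude`` is the magnitude of the back-propagated scattered field,
    sampled on the sensor grid (near zero in clear water, near one over an
    in-focus opaque particle); one sensor pixel spans
    ``optics.pixel_pitch / magnification`` um in the object plane.
    """

    amplitude: np.ndarray
    z: float
    magnification: float
    optics: OpticsConfig | None = None

    @property
    def object_pixel_size(self) -> float:
        if self.optics is None:
            raise ValueError("focal plane has no optics attached")
        return self.optics.pixel_pitch / self.magnification


def subtract_background(
    frames: list[Hologram],
    index: int,
    mode: str = "divide",
    window: int = 3,
    min_neighbors: int = 3,
) -> Hologram:
    """Remove the static background from ``frames[index]``.

    The background is the pixel-wise median of up to ``window`` preceding and
    ``window`` following frames (the frame itself excluded).  With fewer than
    ``min_neighbors`` neighbours available the frame is returned unchanged
    with a logged warning.

    mode="divide" normalizes by the median (output ~1 in clear regions);
    mode="subtract" subtracts it and re-offsets to be non-negative.
    """
    if not frames:
        raise ValueError("frame list is empty")
    if not 0 <= index < len(frames):
        raise IndexError("frame index out of range")
    if mode not in ("divide", "subtract"):
        raise ValueError("mode must be 'divide' or 'subtract'")

    target = frames[index]
    lo, hi = max(0, index - window), min(len(frames), index + window + 1)
    neighbors = [frames[i].intensity for i in range(lo, hi) if i != index]
    if len(neighbors) < min_neighbors:
        logger.warning(
            "frame %d: only %d neighbour frame(s) available for background "
            "estimation (need %d); returning frame unchanged",
            index, len(neighbors), min_neighbors,
        )
        return Hologram(target.intensity.copy(), target.frame_index, target.optics)

    background = np.median(np.stack(neighbors), axis=0)
    if mode == "divide":
        floor = max(1e-6, 1e-3 * float(np.median(background)))
        corrected = target.intensity / np.maximum(background, floor)
    else:
        corrected = target.intensity - background
        low = corrected.min()
        if low < 0:
            corrected = corrected - low
    return Hologram(corrected, target.frame_index, target.optics)


def reconstruct_plane(h: Hologram, z: float) -> FocalPlane:
    """Refocus hologram ``h`` to source distance ``z`` (um).

    The hologram is normalized by its median (so a clean background sits at
    unity), the unit reference is removed, and the residual contrast field
    is propagated back over the Fresnel-scaled distance D(z) = L (L - z) / z.
    The returned amplitude is the *contrast magnitude* |U_back|: ~0 in empty
    regions and ~1 over an in-focus opaque particle.  Using the scattered
    field's modulus rather than re-adding the reference keeps the particle
    image stable against the rapid reference/image phase rotation with
    defocus that inline geometries exhibit at low Fresnel number.
    """
    L = h.optics.source_camera_distance
    if not (0 < z < L):
        raise InvalidDistanceError(
            f"reconstruction distance {z} um outside (0, {L}) um"
        )
    scale = float(np.median(h.intensity))
    if scale <= 0:
        scale = max(float(h.intensity.mean()), 1e-12)
    contrast = h.intensity / scale - 1.0
    back = angular_spectrum_propagate(
        contrast, h.optics.pixel_pitch, -effective_distance(z, L),
        h.optics.wavelength,
    )
    amplitude = np.abs(back)
    return FocalPlane(
        amplitude=amplitude, z=z, magnification=h.optics.magnification(z),
        optics=h.optics,
    )


def reconstruct_stack(
    h: Hologram, z_start: float, z_stop: float, z_step: float
) -> list[FocalPlane]:
    """Refocus to evenly spaced planes z_start, z_start + z_step, ...

    The number of planes is floor((z_stop - z_start) / z_step) + 1, so
    z_start == z_stop yields a single plane.
    """
    if z_stop < z_start:
        raise ValueError("z_stop must be >= z_start")
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    n = int(np.floor((z_stop - z_start) / z_step + 1e-9)) + 1
    return [reconstruct_plane(h, z_start + i * z_step) for i in range(n)]
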