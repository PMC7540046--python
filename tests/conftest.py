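import numpy as np
import pytest

from holopipe import (
    GroundTruthParticle,
    OpticsConfig,
    SyntheticScene,
    default_beam_boundary,
    render_hologram,
)


@pytest.fixture(scope="session")
def small_optics() -> OpticsConfig:
    """Reduced 256x256 sensor crop with the instrument's optical constants."""
    return OpticsConfig(
        sensor_shape=(256, 256), reconstruction_z_range=(11_000.0, 19_000.0)
    )


@pytest.fixture(scope="session")
def crop_optics() -> OpticsConfig:
    """512x512 sensor crop used for multi-particle scenes."""
    return OpticsConfig(
        sensor_shape=(512, 512), reconstruction_z_range=(11_000.0, 19_000.0)
    )


@pytest.fixture(scope="session")
def boundary():
    return default_beam_boundary()


@pytest.fixture(scope="session")
def single_disk_scene(crop_optics):
    """One 50 um opaque disk at a known off-axis position, mild noise.

    Rendered on the 512 px crop: the fringe halo of a mid-depth particle
    spans a few hundred pixels, and focus scoring needs most of it."""
    particle = GroundTruthParticle(center=(20.0, -15.0, 15_000.0), diameter=50.0)
    return SyntheticScene(
        particles=[particle], optics=crop_optics, noise_sd=0.01, seed=7
    )


@pytest.fixture(scope="session")
def single_disk_hologram(single_disk_scene):
    return render_hologram(single_disk_scene)


def make_sparse_scene(optics, rng, n, diameter_range=(25.0, 55.0),
                      z_range=(12_000.0, 18_000.0), min_sep_px=150.0,
                      noise_sd=0.01, seed=0, diameter=None):
    """Scene with n particles whose sensor-plane projections do not overlap."""
    ny, nx = optics.sensor_shape
    margin = 0.33 * min(ny, nx)
    parts, sensor_pos = [], []
    while len(parts) < n:
        z = rng.uniform(*z_range)
        d = diameter if diameter is not None else rng.uniform(*diameter_range)
        m = optics.magnification(z)
        x, y = rng.uniform(-130, 130, 2)
        px, py = x * m / optics.pixel_pitch, y * m / optics.pixel_pitch
        if abs(px) > margin or abs(py) > margin:
            continue
        if all(np.hypot(px - a, py - b) > min_sep_px for a, b in sensor_pos):
            parts.append(GroundTruthParticle(center=(x, y, z), diameter=d))
            sensor_pos.append((px, py))
    return SyntheticScene(particles=parts, optics=optics, noise_sd=noise_sd,
                          seed=seed)
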