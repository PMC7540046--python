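"""Formats, configuration and orchestration binding the stages together.

The fixed processing order is: record -> background correction ->
refocusing -> detection -> artifact removal -> size correction ->
concentration correction -> statistics.  Concentration scaling never runs
before artifact removal, since replicating an artifact would multiply its
bias.

Frames are plain TIFF/PNG images read in lexicographic order; detections
travel as CSV with a fixed schema so every intermediate stays inspectable;
configuration is strict-schema YAML; each run emits a manifest with input
hashes, the config snapshot and per-stage particle accounting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .corrections import (
    DetectionProbabilityModel,
    SizeCalibration,
    apply_concentration_correction,
    apply_size_correction,
)
from .detection import (
    DEFAULT_MIN_PIXELS,
    DEFAULT_SEGMENT_FLOOR,
    DEFAULT_SHARPNESS_FLOOR,
    Detection,
    deduplicate,
    extract_contour,
    max_projection,
    remove_artifacts,
    segment_field,
)
from .optics import BeamBoundary, OpticsConfig, default_beam_boundary
from .particle_stats import beam_volume, overall_concentration
from .reconstruction import Hologram, reconstruct_stack, subtract_background

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_frames",
    "write_frames",
    "write_detections",
    "read_detections",
    "run_pipeline",
    "DETECTION_COLUMNS",
]

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = [
    "frame", "x_um", "y_um", "z_um", "area_um2", "esd_raw_um",
    "esd_corrected_um", "sharpness", "multiplicity",
]

_OPTICS_KEYS = {
    "wavelength_um", "source_camera_distance_um", "pixel_pitch_um",
    "sensor_shape", "z_min_um", "z_max_um", "frame_rate",
}
_BOUNDARY_KEYS = {"r1_um", "r2_um", "z_min_um", "z_max_um",
                  "working_volume_ml"}
_DETECT_KEYS = {"threshold", "segment_floor", "sharpness_floor", "min_pixels",
                "z_step_um", "background_mode", "adaptive"}
_TOP_KEYS = {"optics", "boundary", "detect", "calibration", "model", "seed"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in '{where}' "
            f"(allowed: {sorted(allowed)})"
        )


def optics_from_dict(d: dict) -> OpticsConfig:
    _check_keys(d, _OPTICS_KEYS, "optics")
    kwargs = {}
    if "wavelength_um" in d:
        kwargs["wavelength"] = float(d["wavelength_um"])
    if "source_camera_distance_um" in d:
        kwargs["source_camera_distance"] = float(d["source_camera_distance_um"])
    if "pixel_pitch_um" in d:
        kwargs["pixel_pitch"] = float(d["pixel_pitch_um"])
    if "sensor_shape" in d:
        kwargs["sensor_shape"] = tuple(int(v) for v in d["sensor_shape"])
    if "z_min_um" in d or "z_max_um" in d:
        kwargs["reconstruction_z_range"] = (
            float(d.get("z_min_um", 1000.0)), float(d.get("z_max_um", 19000.0))
        )
    if "frame_rate" in d:
        kwargs["frame_rate"] = float(d["frame_rate"])
    return OpticsConfig(**kwargs)


def boundary_from_dict(d: dict) -> BeamBoundary:
    _check_keys(d, _BOUNDARY_KEYS, "boundary")
    if not d:
        return default_beam_boundary()
    return BeamBoundary(
        r1=float(d["r1_um"]),
        r2=float(d["r2_um"]),
        z_min=float(d["z_min_um"]),
        z_max=float(d["z_max_um"]),
        working_volume_override=(
            float(d["working_volume_ml"]) if "working_volume_ml" in d else None
        ),
    )


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    boundary: BeamBoundary = field(default_factory=default_beam_boundary)
    threshold: float = 0.95
    segment_floor: float = DEFAULT_SEGMENT_FLOOR
    sharpness_floor: float = DEFAULT_SHARPNESS_FLOOR
    min_pixels: int = DEFAULT_MIN_PIXELS
    z_step: float = 250.0
    background_mode: str = "divide"
    adaptive: bool = False
    calibration: SizeCalibration | None = None
    model: DetectionProbabilityModel | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        _check_keys(raw, _TOP_KEYS, "pipeline config")
        kwargs: dict = {}
        if "optics" in raw:
            kwargs["optics"] = optics_from_dict(raw["optics"] or {})
        if "boundary" in raw:
            kwargs["boundary"] = boundary_from_dict(raw["boundary"] or {})
        det = raw.get("detect") or {}
        _check_keys(det, _DETECT_KEYS, "detect")
        if "threshold" in det:
            kwargs["threshold"] = float(det["threshold"])
        if "segment_floor" in det:
            kwargs["segment_floor"] = float(det["segment_floor"])
        if "sharpness_floor" in det:
            kwargs["sharpness_floor"] = float(det["sharpness_floor"])
        if "min_pixels" in det:
            kwargs["min_pixels"] = int(det["min_pixels"])
        if "z_step_um" in det:
            kwargs["z_step"] = float(det["z_step_um"])
        if "background_mode" in det:
            kwargs["background_mode"] = str(det["background_mode"])
        if "adaptive" in det:
            kwargs["adaptive"] = bool(det["adaptive"])
        if raw.get("calibration"):
            c = raw["calibration"]
            kwargs["calibration"] = SizeCalibration(
                a=float(c["a"]), b=float(c["b"]),
                r_squared=float(c.get("r_squared", float("nan"))),
            )
        if raw.get("model"):
            m = raw["model"]
            kwargs["model"] = DetectionProbabilityModel(
                z_o=float(m["z_o_um"]), g_r=float(m["g_r_um"]),
                g_z=float(m["g_z_um"]),
            )
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_snapshot: dict
    input_hashes: dict
    software_version: str
    counts: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def read_frames(path, optics: OpticsConfig) -> list[Hologram]:
    """Read a directory of TIFF/PNG frames in lexicographic order.

    All frames must share one shape and one bit depth; intensities are
    returned as recorded, without rescaling.
    """
    directory = Path(path)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    if not files:
        logger.warning("no frame files found in %s", directory)
        return []
    frames, ref_shape, ref_dtype = [], None, None
    for i, f in enumerate(files):
        if f.suffix.lower() == ".png":
            import imageio.v3 as iio

            arr = iio.imread(f)
        else:
            arr = tifffile.imread(f)
        if ref_shape is None:
            ref_shape, ref_dtype = arr.shape, arr.dtype
        elif arr.shape != ref_shape:
            raise ValueError(f"frame {f.name} has shape {arr.shape}, "
                             f"expected {ref_shape}")
        elif arr.dtype != ref_dtype:
            raise ValueError(f"frame {f.name} has dtype {arr.dtype}, "
                             f"expected {ref_dtype}")
        frames.append(Hologram(arr.astype(np.float64), i, optics))
    return frames


def write_frames(frames: list[Hologram], path, scale: float = 10_000.0) -> list[Path]:
    """Write holograms as 16-bit TIFFs (intensity times `scale`, clipped)."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for holo in frames:
        data = np.clip(holo.intensity * scale, 0, 65535).astype(np.uint16)
        out = directory / f"frame_{holo.frame_index:05d}.tiff"
        tifffile.imwrite(out, data)
        written.append(out)
    return written


def write_detections(detections, path) -> None:
    """Write detections to CSV with the standard schema."""
    rows = []
    for det in detections:
        x, y, z = det.position
        rows.append({
            "frame": det.frame_index, "x_um": x, "y_um": y, "z_um": z,
            "area_um2": det.area, "esd_raw_um": det.esd_raw,
            "esd_corrected_um": det.esd_corrected,
            "sharpness": det.sharpness, "multiplicity": det.multiplicity,
        })
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections(path, reduced: bool = False):
    """Read a detection CSV.

    Full schema requires every standard column; ``reduced=True`` accepts
    external-instrument tables that carry only an ESD column (for
    intercomparison)."""
    df = pd.read_csv(path)
    required = ["esd_um"] if reduced else DETECTION_COLUMNS
    if reduced and "esd_um" not in df.columns and "esd_corrected_um" in df.columns:
        required = ["esd_corrected_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"detection table {path} lacks column(s) {missing}")
    return df


def detections_from_frame(
    holo: Hologram, config: PipelineConfig, background: Hologram | None = None
) -> tuple[list[Detection], int]:
    """Reconstruct, score and contour one background-corrected frame.

    Returns (detections, raw segment count)."""
    zlo, zhi = holo.optics.reconstruction_z_range
    stack = reconstruct_stack(holo, zlo, zhi, config.z_step)
    sharp_field = max_projection(stack)
    segments = segment_field(
        sharp_field, background, threshold=config.threshold,
        min_pixels=config.min_pixels,
        sharpness_floor=config.segment_floor, stack=stack,
        adaptive=config.adaptive,
    )
    by_z = {p.z: p for p in stack}
    detections = []
    for seg in segments:
        det = extract_contour(by_z[seg.focus_z], seg)
        if det is not None:
            det.frame_index = holo.frame_index
            detections.append(det)
    return deduplicate(detections), len(segments)


def correct_detections(detections, config: PipelineConfig) -> list[Detection]:
    """Apply size correction (Eq-style power law, mm units) and
    concentration replication weights, in that order."""
    out = list(detections)
    if config.calibration is not None:
        corrected = []
        for det in out:
            s_corr_mm = apply_size_correction(
                det.esd_raw / 1000.0, det.position[2] / 1000.0,
                config.calibration,
            )
            corrected.append(
                dataclasses.replace(det, esd_corrected=s_corr_mm * 1000.0)
            )
        out = corrected
    if config.model is not None:
        out = apply_concentration_correction(out, config.model)
    return out


def run_pipeline(config: PipelineConfig, frames_dir, out_dir) -> RunManifest:
    """Execute the full chain on a directory of frames and write the
    detection table plus a manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = read_frames(frames_dir, config.optics)
    if not frames:
        raise FileNotFoundError(f"no frames found in {frames_dir}")
    input_hashes = {
        f"frame_{h.frame_index:05d}": _hash_bytes(h.intensity.tobytes())
        for h in frames
    }

    all_detections: list[Detection] = []
    raw_segments = 0
    for i, _ in enumerate(frames):
        try:
            corrected = subtract_background(frames, i,
                                            mode=config.background_mode)
            dets, n_seg = detections_from_frame(corrected, config)
        except Exception as exc:  # noqa: BLE001 - annotate stage and frame
            raise RuntimeError(
                f"pipeline stage failed on frame {i}: {exc}"
            ) from exc
        raw_segments += n_seg
        all_detections.extend(dets)

    filtered = remove_artifacts(all_detections, config.sharpness_floor)
    final = correct_detections(filtered, config)
    write_detections(final, out / "detections.csv")

    volume_ml = beam_volume(config.boundary)
    conc = overall_concentration(final, len(frames), volume_ml)
    counts = {
        "n_frames": len(frames),
        "raw_segments": raw_segments,
        "detections": len(all_detections),
        "post_artifact": len(filtered),
        "weighted_count": conc.weighted_count,
        "concentration_per_ml": conc.concentration,
        "detections_hash": _hash_bytes(
            (out / "detections.csv").read_bytes()
        ),
    }
    snapshot = {
        "threshold": config.threshold,
        "segment_floor": config.segment_floor,
        "sharpness_floor": config.sharpness_floor,
        "min_pixels": config.min_pixels,
        "z_step_um": config.z_step,
        "background_mode": config.background_mode,
        "seed": config.seed,
        "volume_ml": volume_ml,
    }
    manifest = RunManifest(
        config_snapshot=snapshot,
        input_hashes=input_hashes,
        software_version=__version__,
        counts=counts,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
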