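"""Particle detection from refocused stacks: per-pixel sharpness, segment
grouping, per-segment focus refinement, seeded contour extraction, and
artifact removal.

The stages mirror the classic unsupervised hologram-processing chain:

1. a sharpness score (Tenengrad: Gaussian-smoothed squared intensity-gradient
   magnitude) is computed for every pixel of every focal plane and the
   per-pixel maximum over planes is kept, together with the plane where it
   occurred;
2. foreground pixels (strong refocused contrast and sharp enough) are
   grouped into 8-connected segments, split between contrast cores by a
   watershed;
3. each segment's focus distance is refined by maximizing the *summed*
   sharpness of its pixels over planes;
4. the particle contour is extracted at the focus plane by a seeded
   graph-based segmentation (random walker) initialized from the dilated
   segment bounding box, after an edge-sharpening convolution, and reduced
   to a single hole-filled connected component;
5. detections below a sharpness floor are discarded as reconstruction
   artifacts.

Ties in any argmax over planes are broken toward smaller z so the whole
chain is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.segmentation import random_walker, watershed

from .reconstruction import FocalPlane, Hologram

__all__ = [
    "SharpnessField",
    "Segment",
    "Detection",
    "compute_sharpness",
    "max_projection",
    "segment_field",
    "refine_focus",
    "extract_contour",
    "remove_artifacts",
    "deduplicate",
    "DEFAULT_SHARPNESS_FLOOR",
    "DEFAULT_CONTRAST_FLOOR",
    "DEFAULT_SEGMENT_FLOOR",
    "DEFAULT_MIN_PIXELS",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_PIXELS = 4
#: Sharpness floor for a pixel to be foreground-eligible during segmentation.
DEFAULT_SEGMENT_FLOOR = 0.02
#: Minimum region sharpness for a detection to be considered real.
DEFAULT_SHARPNESS_FLOOR = 0.07
#: Minimum in-focus peak contrast (relative to background) for a detection:
#: a refocused opaque particle reaches the background level, defocused
#: fringe ghosts stay well below it.  Both floors and this threshold were
#: calibrated on labelled synthetic scenes (see docs/methods.md).
DEFAULT_CONTRAST_FLOOR = 0.7


@dataclass
class SharpnessField:
    """Per-pixel maximum sharpness over a focal stack and its location.

    ``max_contrast`` (per-pixel maximum contrast amplitude over the stack)
    is carried along: an opaque particle lights up the contrast image near
    its focus, which drives the foreground threshold rule.
    """

    max_score: np.ndarray
    argmax_z: np.ndarray
    max_contrast: np.ndarray
    z_values: np.ndarray


@dataclass
class Segment:
    """A connected group of in-focus pixels belonging to one object."""

    rows: np.ndarray
    cols: np.ndarray
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max) incl.
    focus_z: float
    segment_score: float


@dataclass
class Detection:
    """One extracted particle.

    ``mask`` is the binary contour mask cropped to ``mask_origin`` (top-left
    row/col on the sensor); ``area`` is object-plane um^2 (sensor pixel area
    divided by M^2); ``position`` is (x, y, z) in um from the source with
    x, y taken from the magnified centroid.
    """

    mask: np.ndarray
    mask_origin: tuple[int, int]
    area: float
    esd_raw: float
    position: tuple[float, float, float]
    sharpness: float
    esd_corrected: float = float("nan")
    multiplicity: int = 1
    frame_index: int = 0
    contrast: float = float("nan")


def compute_sharpness(plane: FocalPlane, sigma: float = 3.0) -> np.ndarray:
    """Tenengrad sharpness: squared Sobel gradient magnitude of the
    amplitude, smoothed with a Gaussian window (default 3 px)."""
    amp = plane.amplitude
    gy = ndimage.sobel(amp, axis=0, mode="nearest")
    gx = ndimage.sobel(amp, axis=1, mode="nearest")
    return ndimage.gaussian_filter(gx * gx + gy * gy, sigma, mode="nearest")


def max_projection(stack: list[FocalPlane], sigma: float = 3.0) -> SharpnessField:
    """Per-pixel maximum sharpness over the stack and the z where it occurs.

    The stack is processed in order of increasing z and ties keep the first
    (smaller-z) plane.  Also records the per-pixel maximum contrast.
    """
    if not stack:
        raise ValueError("stack is empty")
    order = np.argsort([p.z for p in stack], kind="stable")
    planes = [stack[i] for i in order]
    zs = np.array([p.z for p in planes])
    best = compute_sharpness(planes[0], sigma)
    arg = np.zeros(best.shape, dtype=np.intp)
    max_con = planes[0].amplitude.copy()
    for i, plane in enumerate(planes[1:], start=1):
        score = compute_sharpness(plane, sigma)
        better = score > best  # strict: ties stay at the smaller z
        best = np.where(better, score, best)
        arg[better] = i
        np.maximum(max_con, plane.amplitude, out=max_con)
    return SharpnessField(
        max_score=best, argmax_z=zs[arg], max_contrast=max_con, z_values=zs
    )


def segment_field(
    sharpness_field: SharpnessField,
    background: Hologram | None = None,
    threshold: float = 0.95,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    sharpness_floor: float = DEFAULT_SEGMENT_FLOOR,
    stack: list[FocalPlane] | None = None,
    adaptive: bool = False,
    adaptive_sigma: float = 64.0,
    core_fraction: float = 0.45,
) -> list[Segment]:
    """Group foreground pixels into connected segments.

    The foreground threshold keeps the printed instrument semantics: a pixel
    is foreground-eligible when the transmission implied by its peak contrast
    falls below ``threshold`` (0.95) times the local background level -- i.e.
    its stack-maximum contrast amplitude exceeds (1 - threshold) of the
    background -- *and* its maximum sharpness reaches the sharpness floor.
    With ``adaptive=True`` the background level varies smoothly across the
    sensor (local-adaptive thresholding); by default a single global level
    is used.  Components smaller than ``min_pixels`` are discarded.  When
    the focal ``stack`` is given, each segment's focus is refined over the
    whole region (``refine_focus``); otherwise the median per-pixel
    argmax-z is used.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if background is not None:
        bg_int = background.intensity
        bg_amp = np.sqrt(bg_int / max(float(np.median(bg_int)), 1e-12))
    else:
        bg_amp = np.ones_like(sharpness_field.max_contrast)
    if adaptive:
        level = ndimage.gaussian_filter(bg_amp, adaptive_sigma, mode="nearest")
    else:
        level = np.full_like(bg_amp, float(np.median(bg_amp)))

    foreground = (
        sharpness_field.max_contrast > (1.0 - threshold) * level
    ) & (sharpness_field.max_score >= sharpness_floor)
    # In-focus particle bodies reach contrast near the background level,
    # far above any out-of-focus fringe; use them as watershed markers so
    # (a) halo-only components are discarded and (b) overlapping halos of
    # neighbouring particles are split between their cores rather than
    # merged into one segment.
    cores = foreground & (
        sharpness_field.max_contrast > core_fraction * level
    )
    # close small gaps so contrast ripples inside one particle do not seed
    # several competing markers
    cores = ndimage.binary_closing(cores, iterations=2)
    markers = cc_label(cores, connectivity=2)
    labels = watershed(-sharpness_field.max_contrast, markers,
                       mask=foreground)

    sharpness_maps = None
    if stack is not None:
        order = np.argsort([p.z for p in stack], kind="stable")
        stack = [stack[i] for i in order]
        sharpness_maps = [compute_sharpness(p) for p in stack]

    segments: list[Segment] = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_pixels:
            continue
        bbox = (rows.min(), cols.min(), rows.max(), cols.max())
        score = float(sharpness_field.max_score[rows, cols].mean())
        seg = Segment(rows=rows, cols=cols, bbox=bbox, focus_z=np.nan,
                      segment_score=score)
        if stack is not None:
            seg.focus_z = refine_focus(seg, stack, sharpness_maps)
        else:
            seg.focus_z = float(np.median(sharpness_field.argmax_z[rows, cols]))
        segments.append(seg)
    return segments


def refine_focus(
    segment: Segment,
    stack: list[FocalPlane],
    sharpness_maps: list[np.ndarray] | None = None,
) -> float:
    """Focus distance maximizing the summed sharpness over the segment's
    pixels; ties go to the smaller z.

    When two objects at different depths were merged into one segment this
    returns the depth of the higher-scoring one (logged at debug level).
    """
    if not stack:
        raise ValueError("stack is empty")
    order = np.argsort([p.z for p in stack], kind="stable")
    planes = [stack[i] for i in order]
    if sharpness_maps is None:
        sharpness_maps = [compute_sharpness(p) for p in planes]
    totals = np.array(
        [m[segment.rows, segment.cols].sum() for m in sharpness_maps]
    )
    best = int(np.argmax(totals))  # first maximum -> smaller z
    peaks = np.sum(
        (totals > np.roll(totals, 1)) & (totals > np.roll(totals, -1))
    )
    if peaks > 1:
        logger.debug(
            "segment sharpness profile has %d local maxima; choosing the "
            "highest-scoring depth %.0f um", peaks, planes[best].z
        )
    return float(planes[best].z)


def extract_contour(
    plane: FocalPlane,
    segment: Segment,
    unsharp_strength: float = 0.5,
    beta: float = 50.0,
) -> Detection | None:
    """Extract the particle contour at the segment's focus plane.

    An edge-sharpening (unsharp mask) convolution is applied to the contrast
    amplitude, then the contour is found by seeded graph-based segmentation
    (random walker): sure-foreground seeds are an eroded half-level core
    (the connected bright region around the segment's brightest pixel,
    thresholded midway between the local background and the core peak),
    sure-background seeds lie outside its dilation, and the walker resolves
    the edge band in between.  The result is reduced to a single hole-filled
    connected component; its pixel area is converted to object-plane um^2
    through the plane magnification.  Returns None (with a logged reason) if
    no foreground survives.
    """
    amp = plane.amplitude
    ny, nx = amp.shape
    r0, c0, r1, c1 = segment.bbox
    pad = max(6, int(0.4 * max(r1 - r0 + 1, c1 - c0 + 1)))
    margin = pad + max(6, pad // 2)
    cr0, cc0 = max(0, r0 - margin), max(0, c0 - margin)
    cr1, cc1 = min(ny, r1 + margin + 1), min(nx, c1 + margin + 1)
    crop = amp[cr0:cr1, cc0:cc1]

    # 3x3 unsharp mask, strength 0.5 by default
    blurred = ndimage.uniform_filter(crop, size=3, mode="nearest")
    sharp = crop + unsharp_strength * (crop - blurred)

    inner = np.zeros(crop.shape, dtype=bool)
    inner[max(0, r0 - pad - cr0) : min(crop.shape[0], r1 + pad + 1 - cr0),
          max(0, c0 - pad - cc0) : min(crop.shape[1], c1 + pad + 1 - cc0)] = True
    outside = ~inner
    if outside.sum() < 8:
        logger.info("segment at bbox %s touches the border; dropped",
                    segment.bbox)
        return None
    bg_level = float(np.median(sharp[outside]))

    # brightest segment pixel anchors the core
    seg_vals = sharp[segment.rows - cr0, segment.cols - cc0]
    k = int(np.argmax(seg_vals))
    anchor = (segment.rows[k] - cr0, segment.cols[k] - cc0)
    vmax = float(seg_vals[k])
    height = vmax - bg_level
    if height <= 0:
        logger.info("segment at bbox %s has no contrast core; dropped",
                    segment.bbox)
        return None

    half = bg_level + 0.5 * height
    comps = cc_label(sharp > half, connectivity=2)
    core = comps == comps[anchor]
    if not core.any():
        logger.info("segment at bbox %s produced no core; dropped",
                    segment.bbox)
        return None
    core = ndimage.binary_fill_holes(core)

    fg = ndimage.binary_erosion(core, iterations=2)
    if not fg.any():
        fg = core
    bg = ~ndimage.binary_dilation(core, iterations=3)
    if not bg.any():
        logger.info("segment at bbox %s fills the crop; dropped", segment.bbox)
        return None
    seeds = np.zeros(crop.shape, dtype=np.uint8)
    seeds[fg] = 1
    seeds[bg] = 2
    labels = random_walker(sharp, seeds, beta=beta, mode="cg_j")
    mask = labels == 1
    if not mask.any():
        logger.info("segment at bbox %s: empty foreground after seeded "
                    "segmentation; dropped", segment.bbox)
        return None

    comps = cc_label(mask, connectivity=2)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    mask = comps == sizes.argmax()
    mask = ndimage.binary_fill_holes(mask)

    area_px = int(mask.sum())
    obj_px = plane.optics.pixel_pitch / plane.magnification
    area_um2 = area_px * obj_px**2
    esd_raw = 2.0 * np.sqrt(area_um2 / np.pi)

    rows, cols = np.nonzero(mask)
    row_c = rows.mean() + cr0
    col_c = cols.mean() + cc0
    x_um = (col_c - (nx - 1) / 2.0) * obj_px
    y_um = (row_c - (ny - 1) / 2.0) * obj_px
    return Detection(
        mask=mask,
        mask_origin=(cr0, cc0),
        area=area_um2,
        esd_raw=esd_raw,
        position=(x_um, y_um, segment.focus_z),
        sharpness=segment.segment_score,
        contrast=float(crop[mask].max()),
    )


def remove_artifacts(
    detections: list[Detection],
    min_sharpness: float = DEFAULT_SHARPNESS_FLOOR,
    min_contrast: float | None = DEFAULT_CONTRAST_FLOOR,
) -> list[Detection]:
    """Drop detections that look like reconstruction artifacts.

    Two criteria, both calibrated on labelled synthetic scenes: the region
    sharpness floor (twin-image fringes and noise blobs focus poorly), and
    an in-focus peak-contrast floor (an opaque particle's refocused
    contrast reaches the background level; defocused fringe ghosts stay
    well below it).  Detections without a recorded contrast (NaN) are
    judged on sharpness alone.  Ordering is preserved.
    """
    if min_sharpness < 0:
        raise ValueError("min_sharpness must be >= 0")
    kept = [d for d in detections if d.sharpness >= min_sharpness]
    if min_contrast is not None:
        kept = [
            d for d in kept
            if not np.isfinite(d.contrast) or d.contrast >= min_contrast
        ]
    return kept


def deduplicate(detections: list[Detection]) -> list[Detection]:
    """Suppress duplicate detections of one object.

    Fragmented segments and first-order fringe rings can yield several
    contours for the same particle; keep the sharpest of any group whose
    transverse centroids overlap (distance below 60% of the summed radii or
    inside 1.8x the larger radius): the genuine in-focus contour scores
    highest on region sharpness."""
    order = sorted(range(len(detections)),
                   key=lambda i: detections[i].sharpness, reverse=True)
    kept: list[int] = []
    for i in order:
        di = detections[i]
        ri = di.esd_raw / 2.0
        dup = False
        for j in kept:
            dj = detections[j]
            dist = np.hypot(di.position[0] - dj.position[0],
                            di.position[1] - dj.position[1])
            rj = dj.esd_raw / 2.0
            if dist < max(0.6 * (ri + rj), 1.8 * max(ri, rj)):
                dup = True
                break
        if not dup:
            kept.append(i)
    kept.sort()
    return [detections[i] for i in kept]
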