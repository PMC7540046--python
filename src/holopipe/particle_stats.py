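"""Size and concentration statistics.

Sizes are equivalent spherical diameters, ESD = 2 sqrt(SA / pi) for a
contour of projected area SA.  Binned spectra report *size-specific
concentration*: replication-weighted counts per bin divided by sample
volume and bin width, in particles (mL um)^-1, so a Junge-type power-law
population appears as a straight line in log-log space whose slope is the
spectral slope.

Instrument intercomparison statistics follow standard practice: ordinary
least squares (Model I) where the predictor is effectively error-free,
geometric-mean / reduced-major-axis regression (Model II) where both
variables carry error, a log-log regression forced through the origin
(y = x * 10**m) for concentration cross-prediction, and paired
mean-percent-difference tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .optics import BeamBoundary, UM3_PER_ML

__all__ = [
    "SizeSpectrum",
    "ConcentrationEstimate",
    "RegressionResult",
    "esd_from_area",
    "make_size_bins",
    "size_spectrum",
    "spectral_slope",
    "overall_concentration",
    "beam_volume",
    "model_ii_regression",
    "loglog_origin_fit",
    "mean_difference",
]

logger = logging.getLogger(__name__)


@dataclass
class SizeSpectrum:
    """Binned size-specific concentration, particles (mL um)^-1."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    ssc: np.ndarray
    total_volume: float  # mL
    mode: str  # "linear" or "log"

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.ssc < 0):
            raise ValueError("size-specific concentration must be >= 0")
        if len(self.ssc) != len(self.bin_centers) != len(self.bin_edges) - 1:
            raise ValueError("inconsistent bin arrays")


@dataclass(frozen=True)
class ConcentrationEstimate:
    weighted_count: float
    volume: float  # mL
    concentration: float  # particles / mL


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    model: str  # "model_I" | "model_II" | "loglog_through_origin"


def esd_from_area(area):
    """ESD = 2 sqrt(area / pi); area in um^2, result in um."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    out = 2.0 * np.sqrt(area / np.pi)
    return float(out) if out.ndim == 0 else out


def make_size_bins(
    mode: str = "linear",
    min_center: float = 3.5,
    width: float = 3.0,
    max_esd: float = 120.0,
    n_log_bins: int = 12,
    log_min: float = 10.0,
) -> np.ndarray:
    """Bin edges for size spectra.

    linear mode: contiguous bins of constant ``width`` (3 um, set by the
    coarsest instrument resolution) whose first centre is ``min_center``
    (3.5 um), extended until ``max_esd`` is covered — used for microspheres
    and monocultures.  log mode: ``n_log_bins`` logarithmically spaced bins
    between ``log_min`` (10 um) and ``max_esd`` (120 um) — used for
    environmental samples.
    """
    if width <= 0 or max_esd <= 0 or min_center <= 0:
        raise ValueError("bin parameters must be positive")
    if mode == "linear":
        first_edge = min_center - width / 2.0
        n = int(math.ceil((max_esd - first_edge) / width))
        return first_edge + width * np.arange(n + 1)
    if mode == "log":
        if not 0 < log_min < max_esd:
            raise ValueError("need 0 < log_min < max_esd")
        return np.geomspace(log_min, max_esd, n_log_bins + 1)
    raise ValueError("mode must be 'linear' or 'log'")


def _bin_centers(edges: np.ndarray, mode: str) -> np.ndarray:
    if mode == "log":
        return np.sqrt(edges[:-1] * edges[1:])  # geometric centres
    return 0.5 * (edges[:-1] + edges[1:])


def size_spectrum(detections, volume: float, bins, mode: str = "linear",
                  use_corrected: bool = True) -> SizeSpectrum:
    """Replication-weighted, binwidth-normalized size spectrum.

    Each detection contributes its integer multiplicity to the half-open
    bin [edge_i, edge_{i+1}) containing its ESD (corrected ESD when
    available, else raw).  Also accepts plain ESD arrays (each with weight
    1).  Detections outside the bin range are tallied and logged but not
    counted.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    edges = np.asarray(bins, dtype=float)
    esd, weight = [], []
    for det in detections:
        if hasattr(det, "esd_raw"):
            e = det.esd_corrected if use_corrected else det.esd_raw
            if not np.isfinite(e):
                e = det.esd_raw
            esd.append(e)
            weight.append(det.multiplicity)
        else:
            esd.append(float(det))
            weight.append(1.0)
    esd = np.asarray(esd, dtype=float)
    weight = np.asarray(weight, dtype=float)
    inside = (esd >= edges[0]) & (esd < edges[-1])
    dropped = int((~inside).sum())
    if dropped:
        logger.info("%d detection(s) outside the bin range were not counted",
                    dropped)
    idx = np.searchsorted(edges, esd[inside], side="right") - 1
    counts = np.bincount(idx, weights=weight[inside], minlength=len(edges) - 1)
    widths = np.diff(edges)
    return SizeSpectrum(
        bin_edges=edges,
        bin_centers=_bin_centers(edges, mode),
        ssc=counts / (volume * widths),
        total_volume=volume,
        mode=mode,
    )


def spectral_slope(spectrum: SizeSpectrum) -> RegressionResult:
    """Model I (OLS) log10-log10 fit of size-specific concentration against
    bin centre; empty bins are excluded.  The slope is the Junge spectral
    slope."""
    keep = spectrum.ssc > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 non-empty bins for a slope fit")
    x = np.log10(spectrum.bin_centers[keep])
    y = np.log10(spectrum.ssc[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return RegressionResult(float(slope), float(intercept), r2, "model_I")


def overall_concentration(
    detections, n_holograms: int, per_hologram_volume: float
) -> ConcentrationEstimate:
    """Weighted count divided by total sampled volume (n_holograms times the
    per-hologram volume, mL)."""
    if n_holograms < 1:
        raise ValueError("need at least one hologram")
    if per_hologram_volume <= 0:
        raise ValueError("per-hologram volume must be positive")
    weighted = float(sum(getattr(d, "multiplicity", 1) for d in detections))
    volume = n_holograms * per_hologram_volume
    return ConcentrationEstimate(weighted, volume, weighted / volume)


def beam_volume(boundary: BeamBoundary) -> float:
    """Sampled volume per hologram in mL.

    Uses the conical-frustum volume (pi h / 3)(r1^2 + r1 r2 + r2^2) unless
    the boundary carries a working-volume override (the instrument's
    calibrated 0.063 mL by default), which then takes precedence."""
    if boundary.working_volume_override is not None:
        logger.info(
            "using working-volume override %.4g mL instead of the geometric "
            "frustum volume %.4g mL",
            boundary.working_volume_override, boundary.geometric_volume_ml,
        )
        return boundary.working_volume_override
    return boundary.geometric_volume_ml


def model_ii_regression(x, y) -> RegressionResult:
    """Geometric-mean (reduced major axis) Model II regression.

    slope = sign(corr) * sd(y) / sd(x), intercept through the means,
    r^2 = corr^2.  Appropriate when both variables carry comparable error,
    as in instrument-instrument concentration comparisons.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    corr = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, corr if corr != 0 else 1.0)
    intercept = float(y.mean() - slope * x.mean())
    return RegressionResult(float(slope), intercept, corr**2, "model_II")


def loglog_origin_fit(x, y) -> RegressionResult:
    """Least-squares fit of log10 y = log10 x + m (slope 1 forced, offset m),
    i.e. y = x * 10**m: the cross-prediction model between instruments.

    r^2 is computed against the constrained model's residuals in log space.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("concentrations must be positive")
    lx, ly = np.log10(x), np.log10(y)
    m = float(np.mean(ly - lx))
    resid = ly - (lx + m)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return RegressionResult(m, 0.0, r2, "loglog_through_origin")


def mean_difference(a, b):
    """Mean and SD of the paired percent difference 100 (a - b) / a.

    Elements with a == 0 are excluded (count logged).  Note the statistic is
    not antisymmetric: swapping the instruments changes the normalizer.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    keep = a != 0
    if not np.all(keep):
        logger.info("excluded %d pair(s) with zero reference value",
                    int((~keep).sum()))
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no valid pairs")
    diff = 100.0 * (a - b) / a
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return float(diff.mean()), sd
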