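"""Size-vs-distance calibration and detection-probability concentration scaling.

Two instrument-specific corrections are applied to raw detections:

**Size correction.**  In point-source geometry the reconstructed contour size
carries a residual distance dependence, calibrated against microspheres of
known diameter as a power law in the source distance D_m (mm):

    S_corr = a * S_m * D_m**b          (sizes in mm)

with instrument coefficients a = 0.121 and b = 0.76 for the reference
system.  ``fit_size_calibration`` recovers (a, b) by ordinary least squares
of log(S_true / S_m) on log(D_m).

**Concentration correction.**  Detection probability is nonuniform across the
beam: highest on-axis near a preferred depth, decaying as a separable
Gaussian in radial distance r = sqrt(x^2 + y^2) and axial distance z,

    C(x, y, z) = exp(-0.5 * [(r / g_r)**2 + ((z - z_o) / g_z)**2])

with reference coefficients z_o = 8000 um, g_r = 466 um, g_z = 6400 um.
Each detection is replicated by the integer weight m = floor(1 / C), clamped
to at most 8 effective copies (7 added replicas), which rescales counts
without distorting the shape of the particle size distribution.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .optics import BeamBoundary

__all__ = [
    "SizeCalibration",
    "DetectionProbabilityModel",
    "FitError",
    "apply_size_correction",
    "fit_size_calibration",
    "scaling_coefficient",
    "fit_detection_model",
    "multiplicity_from_coefficient",
    "apply_concentration_correction",
    "MIN_POSITIONS_FOR_FIT",
    "MAX_MULTIPLICITY",
]

logger = logging.getLogger(__name__)

MIN_POSITIONS_FOR_FIT = 1000
MAX_MULTIPLICITY = 8  # one original + at most seven replicas


class FitError(RuntimeError):
    """A calibration or model fit could not be performed."""


@dataclass(frozen=True)
class SizeCalibration:
    """Power-law size-vs-distance calibration S_corr = a * S_m * D_m**b."""

    a: float = 0.121
    b: float = 0.76
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("coefficient a must be positive")
        if not (-2 < self.b < 2):
            raise ValueError("exponent b must lie in (-2, 2)")
        if self.b <= 0:
            logger.info(
                "fitted size-correction exponent b=%.3f <= 0: the measured "
                "size shows no positive distance dependence", self.b,
            )


@dataclass(frozen=True)
class DetectionProbabilityModel:
    """Separable Gaussian detection-probability model (all lengths in um)."""

    z_o: float = 8000.0
    g_r: float = 466.0
    g_z: float = 6400.0

    def __post_init__(self) -> None:
        if min(self.z_o, self.g_r, self.g_z) <= 0:
            raise ValueError("all model coefficients must be positive")


def apply_size_correction(s_m, d_m, cal: SizeCalibration = SizeCalibration()):
    """Corrected size S_corr = a * S_m * D_m**b, sizes and distances in mm."""
    s_m = np.asarray(s_m, dtype=float)
    d_m = np.asarray(d_m, dtype=float)
    if np.any(s_m <= 0) or np.any(d_m <= 0):
        raise ValueError("measured size and distance must be positive")
    out = cal.a * s_m * d_m**cal.b
    return float(out) if out.ndim == 0 else out


def fit_size_calibration(records) -> SizeCalibration:
    """Fit (a, b) from (s_true, s_m, d_m) triples, all in mm.

    Least squares of log(s_true / s_m) = log a + b log d_m.  Requires at
    least 3 records spanning at least 2 distinct distances.
    """
    rec = np.asarray(list(records), dtype=float)
    if rec.ndim != 2 or rec.shape[1] != 3 or rec.shape[0] < 3:
        raise FitError("need at least 3 (s_true, s_m, d_m) records")
    s_true, s_m, d_m = rec.T
    if np.any(rec <= 0):
        raise FitError("all record values must be positive")
    if np.unique(d_m).size < 2:
        raise FitError("records must span at least 2 distinct distances")
    x = np.log(d_m)
    y = np.log(s_true / s_m)
    b, log_a = np.polyfit(x, y, 1)
    resid = y - (log_a + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return SizeCalibration(a=float(np.exp(log_a)), b=float(b), r_squared=r2)


def scaling_coefficient(position, model: DetectionProbabilityModel):
    """Detection probability C(x, y, z) at one position or an (n, 3) array."""
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    if pos.shape[1] != 3:
        raise ValueError("positions must be (x, y, z) triples in um")
    r2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
    c = np.exp(
        -0.5 * (r2 / model.g_r**2 + ((pos[:, 2] - model.z_o) / model.g_z) ** 2)
    )
    return float(c[0]) if single else c


def _column_depth(x, y, boundary: BeamBoundary):
    """Axial extent of the beam frustum above each (x, y) point (um)."""
    r = np.hypot(x, y)
    taper = boundary.r1 - boundary.r2
    z_enter = np.where(
        r <= boundary.r2,
        boundary.z_min,
        boundary.z_min
        + (r - boundary.r2)
        * (boundary.z_max - boundary.z_min)
        / max(taper, 1e-12),
    )
    depth = boundary.z_max - z_enter
    return np.where(r <= boundary.r1, depth, 0.0)


def _weighted_column_depth(x, y, boundary: BeamBoundary, z_o: float, g_z: float):
    """Column depth weighted by the axial Gaussian detection profile.

    Integral of exp(-0.5 ((z - z_o)/g_z)^2) over the in-beam part of the
    axial column above each (x, y)."""
    from scipy.special import erf

    r = np.hypot(x, y)
    taper = boundary.r1 - boundary.r2
    z_enter = np.where(
        r <= boundary.r2,
        boundary.z_min,
        boundary.z_min
        + (r - boundary.r2)
        * (boundary.z_max - boundary.z_min)
        / max(taper, 1e-12),
    )
    s = np.sqrt(2.0) * g_z

    def cdf(zz):
        return 0.5 * (1.0 + erf((zz - z_o) / s))

    weight = np.sqrt(2.0 * np.pi) * g_z * (cdf(boundary.z_max) - cdf(z_enter))
    return np.where(r <= boundary.r1, np.maximum(weight, 0.0), 0.0)


def _zbin_weight(edges, boundary: BeamBoundary, g_r: float):
    """Expected accepted-count baseline per z bin for a radially Gaussian
    detection profile of width g_r in a uniform particle field.

    Proportional to the integral over the bin of the detection-weighted
    cross-section 1 - exp(-R(z)^2 / (2 g_r^2)); computed by fine midpoint
    quadrature.  Zero outside the frustum."""
    lo = np.clip(edges[:-1], boundary.z_min, boundary.z_max)
    hi = np.clip(edges[1:], boundary.z_min, boundary.z_max)
    out = np.zeros(len(lo))
    for i, (a, b) in enumerate(zip(lo, hi)):
        if b <= a:
            continue
        z = np.linspace(a, b, 33)[:-1] + (b - a) / 64.0
        rz = boundary.radius_at(z)
        out[i] = np.mean(1.0 - np.exp(-0.5 * (rz / g_r) ** 2)) * (b - a)
    return out


def fit_detection_model(
    positions,
    xy_bin_width: float = 50.0,
    z_bin_width: float = 500.0,
    boundary: BeamBoundary | None = None,
    return_diagnostics: bool = False,
):
    """Fit the separable Gaussian detection model from detected positions.

    The radial width g_r comes from an isotropic 2D Gaussian fit to the XY
    histogram with all depths collapsed; z_o and g_z come from a 1D Gaussian
    fit to the z histogram.  When the sampling ``boundary`` is supplied, each
    histogram is first normalized by the count expected from a uniform
    particle field in that geometry (column depth for XY bins, weighted
    cross-section for z bins), so the fit estimates detection *probability*
    rather than raw detection frequency; without this the frustum geometry
    itself (cross-section growing with z, radial truncation) leaks into the
    fitted coefficients.  Because the z baseline depends on the radial width
    and the XY baseline on the axial profile, one refinement pass is run:
    g_r against plain column depths, z_o/g_z against the g_r-weighted axial
    baseline, then g_r again against axially weighted column depths.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] < MIN_POSITIONS_FOR_FIT:
        raise FitError(
            f"detection-model fit requires at least {MIN_POSITIONS_FOR_FIT} "
            f"positions, got {pos.shape[0]}"
        )
    x, y, z = pos.T

    def edges_for(v, w):
        lo = np.floor(v.min() / w) * w
        hi = np.ceil(v.max() / w) * w + 0.5 * w
        return np.arange(lo, hi + w, w)

    def gauss2d(coords, amp, x0, y0, sigma):
        xx, yy = coords
        return amp * np.exp(-0.5 * ((xx - x0) ** 2 + (yy - y0) ** 2) / sigma**2)

    def gauss1d(zz, amp, z0, sigma):
        return amp * np.exp(-0.5 * ((zz - z0) / sigma) ** 2)

    ex, ey = edges_for(x, xy_bin_width), edges_for(y, xy_bin_width)
    counts_xy, ex, ey = np.histogram2d(x, y, bins=(ex, ey))
    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    gx, gy = np.meshgrid(cx, cy, indexing="ij")

    def fit_xy(axial: tuple[float, float] | None):
        """Isotropic 2D Gaussian fit to the normalized XY histogram.

        ``axial``: optionally (z_o, g_z) to weight each column's depth by
        the axial detection profile."""
        if boundary is not None:
            if axial is None:
                depth = _column_depth(gx, gy, boundary)
            else:
                z_o, g_z = axial
                depth = _weighted_column_depth(gx, gy, boundary, z_o, g_z)
            valid = depth > 0.05 * depth.max()
            weight = np.where(valid, counts_xy / np.where(valid, depth, 1.0), 0.0)
        else:
            valid = np.ones_like(counts_xy, dtype=bool)
            weight = counts_xy
        w = weight[valid]
        if w.sum() <= 0:
            raise FitError("empty XY histogram")
        x0g = float((gx[valid] * w).sum() / w.sum())
        y0g = float((gy[valid] * w).sum() / w.sum())
        var = float(
            (((gx[valid] - x0g) ** 2 + (gy[valid] - y0g) ** 2) * w).sum()
            / w.sum()
        )
        sig0 = max(np.sqrt(var / 2.0), xy_bin_width)
        try:
            popt, _ = curve_fit(
                gauss2d, (gx[valid], gy[valid]), w,
                p0=(w.max(), x0g, y0g, sig0), maxfev=20000,
            )
            return abs(float(popt[3]))
        except RuntimeError:
            logger.warning("XY Gaussian fit did not converge; using moment width")
            return sig0

    def fit_z(g_r: float):
        ez = edges_for(z, z_bin_width)
        counts_z, _ = np.histogram(z, bins=ez)
        cz = 0.5 * (ez[:-1] + ez[1:])
        if boundary is not None:
            base = _zbin_weight(ez, boundary, g_r)
            valid = base > 0.05 * base.max()
            weight = np.where(valid, counts_z / np.where(valid, base, 1.0), 0.0)
        else:
            valid = counts_z > 0
            weight = counts_z.astype(float)
        wz, zz = weight[valid], cz[valid]
        if wz.sum() <= 0:
            raise FitError("empty z histogram")
        z0g = float((zz * wz).sum() / wz.sum())
        sz0 = max(
            float(np.sqrt(((zz - z0g) ** 2 * wz).sum() / wz.sum())), z_bin_width
        )
        try:
            popt, _ = curve_fit(
                gauss1d, zz, wz, p0=(wz.max(), z0g, sz0), maxfev=20000
            )
            z0, sz = float(popt[1]), abs(float(popt[2]))
            if z0 <= 0:
                # structureless data let the centre wander; fall back to the
                # (always positive here) moment estimate
                logger.warning("z Gaussian fit centre non-positive; using "
                               "moment estimates")
                return z0g, max(sz, sz0)
            return z0, sz
        except RuntimeError:
            logger.warning("z Gaussian fit did not converge; using moments")
            return z0g, sz0

    g_r = fit_xy(axial=None)
    z_o, g_z = fit_z(g_r)
    if boundary is not None:
        g_r = fit_xy(axial=(z_o, g_z))
        z_o, g_z = fit_z(g_r)

    if boundary is not None:
        if g_r > boundary.r1:
            logger.warning(
                "fitted radial width %.0f um exceeds the beam radius %.0f um; "
                "positions show no radial detection structure", g_r, boundary.r1
            )
        if g_z > (boundary.z_max - boundary.z_min):
            logger.warning(
                "fitted axial width %.0f um exceeds the beam depth; positions "
                "show no axial detection structure", g_z
            )

    model = DetectionProbabilityModel(z_o=z_o, g_r=g_r, g_z=g_z)
    if not return_diagnostics:
        return model

    # Marginal 1D widths along x and y (redundant under radial symmetry but
    # useful to confirm isotropy).
    diag = {}
    for name, v in (("x", x), ("y", y)):
        e = edges_for(v, xy_bin_width)
        c, e = np.histogram(v, bins=e)
        mid = 0.5 * (e[:-1] + e[1:])
        m0 = float((mid * c).sum() / c.sum())
        s0 = float(np.sqrt(((mid - m0) ** 2 * c).sum() / c.sum()))
        diag[f"sigma_{name}"] = s0
    return model, diag


def multiplicity_from_coefficient(c):
    """Integer replication weight m = clamp(floor(1 / C), 1, 8).

    A particle at the detection peak (C = 1) keeps weight 1 (zero replicas);
    the weight is capped at 8 effective copies (seven added replicas) at the
    beam periphery.
    """
    arr = np.asarray(c, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1.0 + 1e-12):
        raise ValueError("scaling coefficient must lie in (0, 1]")
    m = np.clip(np.floor(1.0 / arr + 1e-9), 1, MAX_MULTIPLICITY).astype(int)
    return int(m) if arr.ndim == 0 else m


def apply_concentration_correction(
    detections,
    model: DetectionProbabilityModel,
    added_replicas: bool = False,
):
    """Assign each detection its integer replication weight from its position.

    Must run *after* artifact removal.  With ``added_replicas=True`` the
    alternative reading (floor(1/C) *added* copies, total floor(1/C) + 1) is
    used; the default treats floor(1/C) as the total effective count.
    Weighting counts by position rescales the concentration while leaving
    the shape of the particle size distribution untouched.
    """
    out = []
    for det in detections:
        c = scaling_coefficient(det.position, model)
        m = multiplicity_from_coefficient(c)
        if added_replicas:
            m = min(m + 1, MAX_MULTIPLICITY)
        out.append(dataclasses.replace(det, multiplicity=int(m)))
    return out
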