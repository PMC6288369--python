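"""Meridional diffraction analysis: TN3 Gaussian peak position and spacing change.

One-dimensional intensity traces along the meridian are summed over
exposures, background-subtracted with a linear fit to the peak flanks, and
the reflection is fitted with a Gaussian restricted to +/-3 or +/-4 pixels
around the observed maximum.  Pixel radii map to axial d-spacings through
the small-angle relation d = lambda * L / (r * pixel_size); the percent
spacing change between the relaxed and activated states is the readout of
filament extension (positive = extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DetectorGeometry", "DiffractionProfile", "PeakFit", "SpacingChange",
           "sum_profiles", "subtract_background", "fit_peak",
           "pixel_to_spacing", "spacing_to_pixel", "spacing_change",
           "write_profile", "read_profile"]

_MIN_SIGMA_PX = 0.3  # narrower than this cannot be resolved on the pixel grid


@dataclass(frozen=True)
class DetectorGeometry:
    """Small-angle camera geometry."""

    wavelength: float = 0.1      # nm
    camera_length: float = 3.47  # m
    pixel_size: float = 0.05     # mm (free parameter; not a calibrated value)

    def __post_init__(self):
        if min(self.wavelength, self.camera_length, self.pixel_size) <= 0:
            raise ValueError("geometry parameters must be positive")


@dataclass
class DiffractionProfile:
    intensity: np.ndarray
    state: Literal["relaxed", "activated"]
    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    label: str = ""
    meridian_origin: float = 0.0
    background_line: tuple[float, float] | None = None  # set by subtract_background

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("intensity must be a 1D series")

    @property
    def n_pixels(self) -> int:
        return len(self.intensity)


@dataclass
class PeakFit:
    center: float                # px (fractional)
    sigma: float                 # px
    amplitude: float             # counts
    window_halfwidth: int
    background: tuple[float, float] | None
    rms_residual: float
    center_sd: float             # fit standard error of the centre
    success: bool = True
    message: str = ""


@dataclass
class SpacingChange:
    percent_change: float        # % of d-spacing, positive = extension
    center_relaxed: float
    center_activated: float
    window_halfwidth: int
    d_relaxed: float = float("nan")   # nm
    d_activated: float = float("nan")  # nm
    success: bool = True
    message: str = ""


def sum_profiles(profiles: list[DiffractionProfile]) -> DiffractionProfile:
    """Pixel-wise sum of exposures of one state; label records the count."""
    if not profiles:
        raise ValueError("no profiles to sum")
    first = profiles[0]
    for p in profiles[1:]:
        if p.n_pixels != first.n_pixels:
            raise ValueError("profiles have mixed lengths")
        if p.state != first.state:
            raise ValueError("profiles have mixed states")
        if p.geometry != first.geometry:
            raise ValueError("profiles have mixed detector geometries")
    total = np.sum([p.intensity for p in profiles], axis=0)
    return DiffractionProfile(total, first.state, first.geometry,
                              label=f"sum-of-{len(profiles)}",
                              meridian_origin=first.meridian_origin)


def subtract_background(profile: DiffractionProfile,
                        exclusion_halfwidth: int = 10) -> DiffractionProfile:
    """Fit a straight line to the flanks of the peak and subtract it everywhere.

    The peak region is ``argmax +/- exclusion_halfwidth``; at least 8
    flanking pixels must remain overall (both sides for an interior peak).
    """
    y = profile.intensity
    peak = int(np.argmax(y))
    lo, hi = peak - exclusion_halfwidth, peak + exclusion_halfwidth
    x = np.arange(len(y), dtype=float)
    flank = (x < lo) | (x > hi)
    if flank.sum() < 8:
        raise ValueError(
            f"peak at pixel {peak} with exclusion +/-{exclusion_halfwidth} leaves "
            "too few flanking pixels for a background fit")
    slope, intercept = np.polyfit(x[flank], y[flank], 1)
    out = replace(profile, intensity=y - (intercept + slope * x))
    out.background_line = (float(intercept), float(slope))
    return out


def _gauss(x, a, c, s):
    return a * np.exp(-0.5 * ((x - c) / s) ** 2)


def fit_peak(profile: DiffractionProfile, window_halfwidth: int = 4) -> PeakFit:
    """Least-squares Gaussian fit within +/-window_halfwidth px of the maximum.

    Returns a failure record (``success=False``) rather than raising when the
    fit diverges, the centre escapes the window, or the peak is narrower
    than the pixel grid can resolve.
    """
    if window_halfwidth not in (3, 4):
        raise ValueError("window_halfwidth must be 3 or 4")
    y = profile.intensity
    peak = int(np.argmax(y))
    if peak - window_halfwidth < 0 or peak + window_halfwidth >= len(y):
        return PeakFit(float("nan"), float("nan"), float("nan"), window_halfwidth,
                       profile.background_line, float("nan"), float("nan"),
                       success=False, message="observed maximum at the series edge")
    sl = slice(peak - window_halfwidth, peak + window_halfwidth + 1)
    x = np.arange(len(y), dtype=float)[sl]
    yy = y[sl]
    try:
        popt, pcov = curve_fit(
            _gauss, x, yy, p0=[float(yy.max()), float(peak), 1.5],
            bounds=([0.0, x[0] - 1.0, 1e-3], [np.inf, x[-1] + 1.0, np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return PeakFit(float("nan"), float("nan"), float("nan"), window_halfwidth,
                       profile.background_line, float("nan"), float("nan"),
                       success=False, message=f"fit divergence: {exc}")
    a, c, s = (float(v) for v in popt)
    resid = yy - _gauss(x, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    center_sd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    if not (x[0] <= c <= x[-1]):
        return PeakFit(c, s, a, window_halfwidth, profile.background_line, rms,
                       center_sd, success=False, message="fitted centre escaped the window")
    if s < _MIN_SIGMA_PX:
        return PeakFit(c, s, a, window_halfwidth, profile.background_line, rms,
                       center_sd, success=False,
                       message=f"fitted sigma {s:.3f} px below the resolvable width")
    return PeakFit(c, s, a, window_halfwidth, profile.background_line, rms, center_sd)


def pixel_to_spacing(pixel: float, geometry: DetectorGeometry,
                     meridian_origin: float = 0.0) -> float:
    """Small-angle d-spacing (nm) of a reflection at the given pixel position."""
    radius_px = abs(pixel - meridian_origin)
    if radius_px == 0:
        raise ValueError("reflection radius is zero (pixel equals the meridian origin)")
    radius_m = radius_px * geometry.pixel_size * 1e-3
    return geometry.wavelength * 1e-9 * geometry.camera_length / radius_m * 1e9


def spacing_to_pixel(d_nm: float, geometry: DetectorGeometry,
                     meridian_origin: float = 0.0) -> float:
    """Inverse of pixel_to_spacing (returns the positive-side pixel)."""
    if d_nm <= 0:
        raise ValueError("d-spacing must be positive")
    radius_m = geometry.wavelength * 1e-9 * geometry.camera_length / (d_nm * 1e-9)
    return meridian_origin + radius_m / (geometry.pixel_size * 1e-3)


def spacing_change(relaxed_fit: PeakFit, activated_fit: PeakFit,
                   geometry: DetectorGeometry,
                   meridian_origin: float = 0.0) -> SpacingChange:
    """Percent d-spacing change between states (positive = extension)."""
    if relaxed_fit.window_halfwidth != activated_fit.window_halfwidth:
        raise ValueError("fits must use the same window halfwidth")
    w = relaxed_fit.window_halfwidth
    if not (relaxed_fit.success and activated_fit.success):
        msg = "; ".join(m for m in (relaxed_fit.message, activated_fit.message) if m)
        return SpacingChange(float("nan"), relaxed_fit.center, activated_fit.center,
                             w, success=False, message=f"propagated fit failure: {msg}")
    d_rel = pixel_to_spacing(relaxed_fit.center, geometry, meridian_origin)
    d_act = pixel_to_spacing(activated_fit.center, geometry, meridian_origin)
    pct = (d_act - d_rel) / d_rel * 100.0
    return SpacingChange(pct, relaxed_fit.center, activated_fit.center, w,
                         d_relaxed=d_rel, d_activated=d_act)


# ---------------------------------------------------------------------------
# Two-column text I/O
# ---------------------------------------------------------------------------

def write_profile(profile: DiffractionProfile, path) -> None:
    """Write a profile as two-column text with a key: value header."""
    g = profile.geometry
    header = (f"state: {profile.state}\nlabel: {profile.label}\n"
              f"wavelength_nm: {g.wavelength}\ncamera_length_m: {g.camera_length}\n"
              f"pixel_size_mm: {g.pixel_size}\nmeridian_origin: {profile.meridian_origin}")
    data = np.column_stack([np.arange(profile.n_pixels), profile.intensity])
    np.savetxt(path, data, fmt=["%d", "%.6f"], header=header)


def read_profile(path) -> DiffractionProfile:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line.lstrip("# ").split(":", 1)
                meta[k.strip()] = v.strip()
    data = np.loadtxt(path)
    geometry = DetectorGeometry(
        wavelength=float(meta.get("wavelength_nm", 0.1)),
        camera_length=float(meta.get("camera_length_m", 3.47)),
        pixel_size=float(meta.get("pixel_size_mm", 0.05)))
    return DiffractionProfile(
        data[:, 1], state=meta.get("state", "relaxed"), geometry=geometry,
        label=meta.get("label", ""),
        meridian_origin=float(meta.get("meridian_origin", 0.0)))
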