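"""Filament-scale mechanics: helix fit, twist/rise, crossover and persistence length.

The filament axis is fitted per frame as a least-squares cylinder through
the subunit centres of geometry; per-subunit twist and rise follow from
azimuth/axial increments about that axis.  The crossover length — the
axial distance between successive apparent crossings of the two long-pitch
strands — is (180 deg / |wrap(2 * twist)|) * (2 * rise).  The persistence
length is estimated from the decay of tangent correlations along the
centerline, -ln<cos theta(s)> = s / Lp, with tangents taken on the
two-subunit (strand-step) scale at which the genetic twist cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core_model import FilamentFrame, FilamentEnsemble, StatValue
from . import blockstats

KB = 1.380649e-23  # J/K
DEFAULT_TEMPERATURE = 310.0  # K, physiological simulation temperature

#: Published reference values for annotation of reports (skeletal-muscle
#: actin filaments, WT vs the D286G mutant); not reproduction targets.
REFERENCE_VALUES = {
    "persistence_length_um": {"WT": (9.80, 0.14), "D286G": (17.2, 6.0)},
    "crossover_length_A": {"WT": (365.0, 15.0), "D286G": (356.85, 0.71)},
}

__all__ = ["HelixFit", "MechanicsReport", "fit_helix", "estimate_twist_rise",
           "crossover_length", "persistence_length", "flexural_rigidity",
           "mechanics_report", "compare_filaments", "REFERENCE_VALUES"]


class HelixFitError(RuntimeError):
    pass


class EstimatorError(RuntimeError):
    pass


@dataclass
class HelixFit:
    axis_point: np.ndarray
    axis_direction: np.ndarray   # unit vector
    twist_per_subunit: float     # deg, signed; wrapped to (-180, 180]
    rise_per_subunit: float      # A, > 0
    radius: float                # A
    rms_residual: float          # A, COG scatter about the fitted cylinder


@dataclass
class MechanicsReport:
    crossover_length: StatValue
    persistence_length: StatValue
    flexural_rigidity: float     # N m^2
    n_frames: int
    label: str = ""
    lp_blocks: np.ndarray = field(default_factory=lambda: np.array([]))
    crossover_blocks: np.ndarray = field(default_factory=lambda: np.array([]))


def _wrap_deg(a):
    """Map angles to (-180, 180]."""
    w = np.mod(np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


def _canonical_basis(x: np.ndarray) -> np.ndarray:
    """Data-derived orthonormal frame (columns), invariant under rigid motion.

    e3 is the principal direction oriented along increasing subunit order;
    e1 is the first point's perpendicular component.  Working in this frame
    makes the whole fit independent of the filament's pose down to input
    rounding, so the derived twist/rise/crossover are reproducible under
    arbitrary rigid motions.
    """
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    e3 = vt[0] / np.linalg.norm(vt[0])
    if (x[-1] - x[0]) @ e3 < 0:
        e3 = -e3
    p0 = x[0] - (x[0] @ e3) * e3
    n0 = np.linalg.norm(p0)
    if n0 < 1e-9:
        p0 = x[1] - (x[1] @ e3) * e3
        n0 = np.linalg.norm(p0)
        if n0 < 1e-9:
            raise HelixFitError("degenerate filament: collinear subunit centres")
    e1 = p0 / n0
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=1)


def fit_helix(frame: FilamentFrame) -> HelixFit:
    """Fit the helix axis and per-subunit twist/rise from subunit COGs.

    The axis is the least-squares cylinder axis through the centres of
    geometry; twist is the mean wrapped azimuth increment about it, rise the
    mean axial increment, with the axis oriented so the rise is positive.
    """
    if frame.n_subunits < 5:
        raise HelixFitError("need at least 5 subunits for a helix fit")
    cogs = frame.subunit_cogs()
    centroid = cogs.mean(axis=0)
    basis = _canonical_basis(cogs - centroid)
    y = (cogs - centroid) @ basis

    def _parts(p):
        px, py, ax, ay = p
        v = np.array([ax, ay, 1.0])
        nv = np.linalg.norm(v)
        d = v / nv
        rel = y - np.array([px, py, 0.0])
        z = rel @ d
        perp = rel - np.outer(z, d)
        r = np.linalg.norm(perp, axis=1)
        return d, nv, z, perp, r

    def residuals(p):
        _, _, _, _, r = _parts(p)
        return r - r.mean()

    def jacobian(p):
        _, nv, z, perp, r = _parts(p)
        u = perp / r[:, None]
        j = np.column_stack([-u[:, 0], -u[:, 1],
                             -z * u[:, 0] / nv, -z * u[:, 1] / nv])
        return j - j.mean(axis=0)

    sol = least_squares(residuals, x0=np.zeros(4), jac=jacobian,
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    p = sol.x
    # Gauss-Newton polish to machine-precision stationarity, so the fitted
    # twist (and hence crossover) does not carry optimizer path noise
    for _ in range(4):
        j = jacobian(p)
        res = residuals(p)
        step, *_ = np.linalg.lstsq(j, -res, rcond=None)
        p = p + step
        if np.max(np.abs(step)) < 1e-13:
            break
    px, py, ax, ay = p
    d_loc = np.array([ax, ay, 1.0])
    d_loc /= np.linalg.norm(d_loc)
    p_loc = np.array([px, py, 0.0])

    rel = y - p_loc
    z = rel @ d_loc                 # d_loc has positive e3 component: rise > 0
    perp = rel - np.outer(z, d_loc)
    r_per = np.linalg.norm(perp, axis=1)
    radius = float(r_per.mean())
    if radius < 1e-9:
        raise HelixFitError("degenerate filament: zero cylinder radius")
    u1 = perp[0] / r_per[0]
    u2 = np.cross(d_loc, u1)
    phi = np.degrees(np.arctan2(perp @ u2, perp @ u1))
    # circular mean of the azimuth increments: a genetic twist near -167 deg
    # sits close to the wrap point, and bending noise on a plain wrapped
    # arithmetic mean would flip individual increments across +/-180
    inc = np.radians(np.diff(phi))
    twist = float(_wrap_deg(math.degrees(
        math.atan2(float(np.sin(inc).mean()), float(np.cos(inc).mean())))))
    rise = float(np.mean(np.diff(z)))
    rms = float(np.sqrt(np.mean((r_per - radius) ** 2)))
    return HelixFit(centroid + basis @ p_loc, basis @ d_loc, twist, rise, radius, rms)


def estimate_twist_rise(frame: FilamentFrame) -> tuple[float, float]:
    """Convenience: (twist deg, rise A) from the helix fit."""
    f = fit_helix(frame)
    return f.twist_per_subunit, f.rise_per_subunit


def crossover_length(fit: HelixFit) -> float:
    """Axial distance over which a long-pitch strand's azimuth advances 180 deg.

    Returns math.inf when the strand twist wraps to exactly zero
    (perfectly untwisted long-pitch strands).
    """
    strand_twist = float(_wrap_deg(2.0 * fit.twist_per_subunit))
    if strand_twist == 0.0:
        return math.inf
    return 180.0 / abs(strand_twist) * (2.0 * fit.rise_per_subunit)


def _strand_tangents(cogs: np.ndarray) -> np.ndarray:
    """Centerline tangents on the strand-step scale for one frame.

    The centerline is sampled at the midpoints of consecutive subunit
    pairs (0,1), (2,3), ...; tangents join successive midpoints.
    """
    n_sub = cogs.shape[0]
    n_mid = n_sub // 2
    mids = 0.5 * (cogs[0:2 * n_mid:2] + cogs[1:2 * n_mid:2])
    t = np.diff(mids, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _mean_log_cos(tangents: np.ndarray, lag: int) -> float:
    dots = (tangents[:, :-lag] * tangents[:, lag:]).sum(axis=-1)
    mean_cos = float(dots.mean())
    if mean_cos <= 0:
        raise EstimatorError(
            f"<cos theta> = {mean_cos:.3f} <= 0 at separation lag {lag}; "
            "filament too flexible for the small-angle fit")
    return -math.log(mean_cos)


def _lp_from_frames(cogs: np.ndarray, seg_len: float, y_ref: np.ndarray) -> float:
    """Pooled origin-through fit of the bending part of -ln<cos theta(s)>.

    Two discretisation effects are removed before fitting.  The tangents are
    chords between centerline midpoints, so consecutive-chord correlations
    sample an effective contour separation of (lag - 1/2) segments, not lag
    segments.  And because the midpoints of subunit pairs sit slightly off
    the helix axis (the genetic twist does not cancel exactly over two
    subunits), even a perfectly rigid filament shows a deterministic,
    lag-dependent chord decorrelation; that reference signature ``y_ref``
    (computed from the frame-mean structure) is subtracted, leaving the pure
    bending decay s/Lp.

    cogs: (n_frames, n_subunits, 3). Returns Lp in Angstrom (inf if rigid).
    """
    tangents = np.stack([_strand_tangents(c) for c in cogs])  # (n_frames, n_t, 3)
    n_t = tangents.shape[1]
    s_vals, y_vals = [], []
    for lag in range(1, n_t):
        y = _mean_log_cos(tangents, lag) - y_ref[lag - 1]
        s_vals.append((lag - 0.5) * seg_len)
        y_vals.append(y)
    s = np.asarray(s_vals)
    y = np.asarray(y_vals)
    slope = float((s * y).sum() / (s * s).sum())
    # slopes below 1e-13 /A (Lp beyond ~1 km) are float noise: rigid
    if slope <= 1e-13:
        return math.inf
    return 1.0 / slope


def _reference_signature(cogs: np.ndarray) -> tuple[np.ndarray, float]:
    """Rigid-geometry chord decorrelation from the frame-mean structure."""
    mean_cogs = cogs.mean(axis=0)
    t_ref = _strand_tangents(mean_cogs)[None]
    n_t = t_ref.shape[1]
    y_ref = np.array([_mean_log_cos(t_ref, lag) for lag in range(1, n_t)])
    n_mid = mean_cogs.shape[0] // 2
    mids = 0.5 * (mean_cogs[0:2 * n_mid:2] + mean_cogs[1:2 * n_mid:2])
    seg_len = float(np.linalg.norm(np.diff(mids, axis=0), axis=1).mean())
    return y_ref, seg_len


def persistence_length(ensemble: FilamentEnsemble, n_blocks: int = 10) -> StatValue:
    """Persistence length (um) from tangent-correlation decay.

    The estimate pools <cos theta(s)> over all frames; the SD is the SD of
    per-block estimates over ``n_blocks`` contiguous frame blocks.  A rigid
    ensemble (no measurable decay) is reported as mean = inf with sd = 0,
    a lower bound rather than an estimate.
    """
    if ensemble.n_frames < 100:
        raise EstimatorError("need at least 100 frames for the Lp estimator")
    cogs = ensemble.subunit_cogs()
    if ensemble.n_subunits // 2 - 1 < 4:
        raise EstimatorError("need at least 4 centerline segments per frame")
    y_ref, seg_len = _reference_signature(cogs)
    lp_A = _lp_from_frames(cogs, seg_len, y_ref)
    if math.isinf(lp_A):
        return StatValue(math.inf, 0.0, n_effective=float(n_blocks), units="um")
    block_edges = np.linspace(0, ensemble.n_frames, n_blocks + 1).astype(int)
    blocks = []
    for lo, hi in zip(block_edges[:-1], block_edges[1:]):
        if hi - lo >= 2:
            lp_b = _lp_from_frames(cogs[lo:hi], seg_len, y_ref)
            if not math.isinf(lp_b):
                blocks.append(lp_b * 1e-4)
    sd = float(np.std(blocks, ddof=1)) if len(blocks) >= 2 else float("nan")
    sv = StatValue(lp_A * 1e-4, sd, n_effective=float(len(blocks)), units="um")
    sv.block_values = np.asarray(blocks)
    return sv


def flexural_rigidity(lp_um: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kappa = Lp * kB * T in N m^2 (Lp given in um)."""
    if lp_um <= 0:
        raise ValueError("persistence length must be positive")
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return lp_um * 1e-6 * KB * temperature


def mechanics_report(ensemble: FilamentEnsemble, n_blocks: int = 10,
                     temperature: float = DEFAULT_TEMPERATURE) -> MechanicsReport:
    """Full mechanics summary: crossover, Lp and flexural rigidity with block SDs."""
    crossovers = np.array([crossover_length(fit_helix(f)) for f in ensemble.frames()])
    finite = crossovers[np.isfinite(crossovers)]
    if len(finite) == 0:
        cross_sv = StatValue(math.inf, 0.0, 1.0, "A")
        cross_blocks = np.array([])
    else:
        br = blockstats.block_average(finite, block_size=max(1, len(finite) // n_blocks))
        cross_sv = StatValue(br.mean, br.block_sd, float(br.n_blocks), "A")
        nb = br.n_blocks
        cross_blocks = finite[: nb * br.block_size].reshape(nb, br.block_size).mean(axis=1)
    lp_sv = persistence_length(ensemble, n_blocks=n_blocks)
    kappa = (math.inf if math.isinf(lp_sv.mean)
             else flexural_rigidity(lp_sv.mean, temperature))
    return MechanicsReport(
        crossover_length=cross_sv, persistence_length=lp_sv,
        flexural_rigidity=kappa, n_frames=ensemble.n_frames,
        label=ensemble.label,
        lp_blocks=getattr(lp_sv, "block_values", np.array([])),
        crossover_blocks=cross_blocks,
    )


def compare_filaments(report_a: MechanicsReport, report_b: MechanicsReport,
                      quantity: str = "persistence_length") -> blockstats.GroupComparison:
    """Two-group comparison of per-block mechanics values (normality-gated)."""
    attr = {"persistence_length": "lp_blocks", "crossover_length": "crossover_blocks"}
    try:
        a = np.asarray(getattr(report_a, attr[quantity]))
        b = np.asarray(getattr(report_b, attr[quantity]))
    except KeyError:
        raise ValueError(f"unknown quantity {quantity!r}") from None
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 blocks per group for a comparison")
    return blockstats.compare_groups(a, b)
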