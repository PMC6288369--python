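"""Synthetic inputs with known ground truth.

Generates (i) an actin-like template monomer with the contact-pair and
subgroup residues placed plausibly, (ii) ideal double-helical filaments
(genetic helix: rise ~27.5 A, twist ~-166.7 deg per subunit), (iii)
fluctuating ensembles bent as a discrete wormlike chain of known
persistence length, (iv) stationary AR(1) scalar series for block-average
validation, and (v) paired relaxed/activated meridional diffraction
profiles with a controllable relative peak shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import FilamentFrame, FilamentEnsemble, N_RESIDUES
from .contacts import default_registry
from .diffraction import DetectorGeometry, DiffractionProfile

__all__ = [
    "HelixParams",
    "FlexParams",
    "ProfileParams",
    "build_template_monomer",
    "build_ideal_filament",
    "sample_flexible_ensemble",
    "ar1_series",
    "make_profile_pair",
]


@dataclass
class HelixParams:
    """Genetic-helix parameters of the assembled filament.

    ``radius`` is the distance of each subunit's centre of geometry from the
    filament axis.
    """

    rise_per_subunit: float = 27.5     # A
    twist_per_subunit: float = -166.7  # deg, signed (left-handed genetic helix)
    n_subunits: int = 13
    radius: float = 25.0               # A

    def __post_init__(self):
        if self.rise_per_subunit <= 0:
            raise ValueError("rise_per_subunit must be positive")
        if not 90.0 < abs(self.twist_per_subunit) < 180.0:
            raise ValueError("|twist_per_subunit| must lie in (90, 180) degrees")
        if self.n_subunits < 5:
            raise ValueError("n_subunits must be >= 5")


@dataclass
class FlexParams:
    """Bending-fluctuation parameters for the wormlike-chain ensemble."""

    persistence_length: float          # um
    n_frames: int
    residue_jitter_sd: float = 0.5     # A, per-residue thermal jitter
    seed: int = 0

    def __post_init__(self):
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.residue_jitter_sd < 0:
            raise ValueError("residue_jitter_sd must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class ProfileParams:
    """Two-state meridional profile generator parameters.

    The peak emulates the third-order troponin meridional reflection
    (TN3, d = 12.9 nm): with 0.1 nm radiation, a 3.47 m camera and
    0.05 mm pixels it sits near pixel 538 from the meridian origin.
    """

    n_pixels: int = 1000
    peak_center: float = 538.0         # px from meridian origin
    peak_sigma: float = 2.0            # px
    amplitude: float = 1e4             # counts at peak
    background: tuple[float, float] = (300.0, -0.2)  # (intercept, slope) counts
    relative_shift: float = 0.0034     # activated center = center * (1 - shift)
    n_exposures: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.peak_center < self.n_pixels:
            raise ValueError("peak_center must lie inside [0, n_pixels)")
        if self.amplitude <= 0 or self.peak_sigma <= 0:
            raise ValueError("amplitude and peak_sigma must be positive")


# ---------------------------------------------------------------------------
# Template monomer
# ---------------------------------------------------------------------------

# Semi-axes of the ellipsoid containing the monomer (A).
_ELLIPSOID = np.array([28.0, 28.0, 18.0])

# Default assembly frame used to place the inter-subunit contact residues:
# template centre sits at (radius, 0, 0) on the filament axis frame.
_DEF_RADIUS = 25.0
_DEF_RISE = 27.5
_DEF_TWIST = -166.7


def _rotz(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_template_monomer(seed: int = 0) -> dict[int, np.ndarray]:
    """Build a 375-residue single-point-per-residue template monomer.

    Residues are scattered deterministically inside an ellipsoid of
    semi-axes (28, 28, 18) A.  The four rigid subgroups occupy distinct
    lobes arranged so the coarse-grained shape parameters take actin-like
    values (bonds ~22-25 A, angles ~75/105 deg, dihedral ~10 deg).  The
    residues appearing in the contact registry are placed near the axial
    top/bottom of the monomer so that, once assembled on the default
    genetic helix, every registry pair distance falls in (5, 30) A,
    mimicking a real subunit interface.
    """
    from .cg_geometry import SUBGROUPS

    rng = np.random.default_rng(seed)
    # uniform in ellipsoid by rejection from the bounding box
    pts = np.empty((N_RESIDUES, 3))
    n = 0
    while n < N_RESIDUES:
        cand = rng.uniform(-1.0, 1.0, size=(2 * N_RESIDUES, 3))
        good = cand[(cand ** 2).sum(axis=1) < 1.0]
        take = min(len(good), N_RESIDUES - n)
        pts[n:n + take] = good[:take] * _ELLIPSOID
        n += take

    template = {rid: pts[rid - 1] for rid in range(1, N_RESIDUES + 1)}

    # subgroup lobes: actin-like R1-R4 geometry (bonds/angles/dihedral)
    lobes = {
        "SG1": np.array([-12.0, -11.0, -1.0]),
        "SG2": np.array([-17.3, 9.9, 3.1]),
        "SG3": np.array([13.0, -11.0, -1.0]),
        "SG4": np.array([6.1, 13.0, -1.0]),
    }
    for name, centre in lobes.items():
        for lo, hi in SUBGROUPS[name]:
            for rid in range(lo, hi + 1):
                template[rid] = centre + rng.normal(0.0, 4.0, size=3)

    # Place contact residues in the default assembly frame (centre at
    # (radius, 0, 0)); stored back in the template frame (centre at origin).
    centre = np.array([_DEF_RADIUS, 0.0, 0.0])
    registry = default_registry()
    acceptors = sorted({s.residue_b for s in registry if s.subunit_offset == 2})
    donors = sorted({s.residue_a for s in registry if s.subunit_offset == 2})

    placed: dict[int, np.ndarray] = {}
    for rid in acceptors:  # barbed-proximal face of the subunit
        lateral = rng.uniform(-1.5, 1.5, size=2)
        placed[rid] = centre + np.array([lateral[0], lateral[1],
                                         -15.0 + rng.uniform(-0.5, 0.5)])
    # image of the acceptor cluster in the i+2 neighbour along the strand
    r2 = _rotz(2.0 * _DEF_TWIST)
    images = np.array([r2 @ placed[rid] + np.array([0, 0, 2 * _DEF_RISE])
                       for rid in acceptors])
    img_centre = images.mean(axis=0)
    for rid in donors:  # pointed-proximal face, facing the neighbour's images
        lateral = rng.uniform(-1.5, 1.5, size=2)
        placed[rid] = np.array([img_centre[0] + lateral[0],
                                img_centre[1] + lateral[1],
                                16.0 + rng.uniform(-0.5, 0.5)])

    # lateral contact: residue 265 faces residue 374 of the i+1 subunit
    lat = [s for s in registry if s.subunit_offset == 1]
    for spec in lat:
        target = _rotz(_DEF_TWIST) @ placed[spec.residue_b] + np.array([0, 0, _DEF_RISE])
        u = target - centre
        scale = 0.95 / math.sqrt(float(((u / _ELLIPSOID) ** 2).sum()))
        placed[spec.residue_a] = centre + scale * u

    # Re-express relative to the monomer centroid and recentre the whole
    # template so the centroid is exactly at the origin with the contact
    # residues at their intended positions relative to it (the filament
    # builder recentres the template, so this keeps the interface geometry
    # exact on assembly).
    overrides = {rid: pos - centre for rid, pos in placed.items()}
    free = [rid for rid in template if rid not in overrides]
    shift = (np.sum([template[r] for r in free], axis=0)
             + np.sum(list(overrides.values()), axis=0)) / len(free)
    for rid in free:
        template[rid] = template[rid] - shift
    template.update(overrides)

    # keep every point inside the stated ellipsoid
    for rid, pos in template.items():
        r2 = float(((pos / _ELLIPSOID) ** 2).sum())
        if r2 > 1.0:
            template[rid] = pos * (0.995 / math.sqrt(r2))
    return template


def _template_arrays(template: dict[int, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    rids = np.array(sorted(template), dtype=int)
    coords = np.array([template[r] for r in rids], dtype=float)
    return rids, coords


def build_ideal_filament(template: dict[int, np.ndarray],
                         helix: HelixParams | None = None) -> FilamentFrame:
    """Assemble the template on an ideal genetic helix.

    Subunit i is the (centred) template shifted to lie at ``radius`` from
    the z axis, rotated by i * twist about z, and translated by i * rise
    along z; subunit centres of geometry fall exactly on a helix.
    """
    helix = helix or HelixParams()
    rids, base = _template_arrays(template)
    base = base - base.mean(axis=0) + np.array([helix.radius, 0.0, 0.0])
    coords = np.empty((helix.n_subunits, len(rids), 3))
    for i in range(helix.n_subunits):
        r = _rotz(i * helix.twist_per_subunit)
        coords[i] = base @ r.T + np.array([0.0, 0.0, i * helix.rise_per_subunit])
    return FilamentFrame(coords, rids)


# ---------------------------------------------------------------------------
# Wormlike-chain ensemble
# ---------------------------------------------------------------------------

_MAX_JOINT_RMS_DEG = 30.0


def _axis_angle_matrices(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices for batched unit axes (n,3) and angles (n,)."""
    n = len(angles)
    k = axes
    kx = np.zeros((n, 3, 3))
    kx[:, 0, 1] = -k[:, 2]; kx[:, 0, 2] = k[:, 1]
    kx[:, 1, 0] = k[:, 2];  kx[:, 1, 2] = -k[:, 0]
    kx[:, 2, 0] = -k[:, 1]; kx[:, 2, 1] = k[:, 0]
    eye = np.broadcast_to(np.eye(3), (n, 3, 3))
    s = np.sin(angles)[:, None, None]
    c = (1.0 - np.cos(angles))[:, None, None]
    return eye + s * kx + c * (kx @ kx)


def sample_flexible_ensemble(template: dict[int, np.ndarray],
                             helix: HelixParams | None = None,
                             flex: FlexParams | None = None,
                             frame_interval: float = 1.0,
                             label: str = "") -> FilamentEnsemble:
    """Sample a bending-fluctuation ensemble as a discrete wormlike chain.

    The ideal filament is cut into rigid segments of two subunits (one
    long-pitch strand step, length 2*rise).  At each joint a bend angle is
    drawn from the small-angle 3D WLC statistics, <theta^2> = 2 L / Lp with
    L the segment length, with uniform azimuth; bends accumulate from the
    filament base so tangent correlations decay as exp(-s/Lp).  Independent
    Gaussian jitter of sd ``residue_jitter_sd`` is added to every residue
    point.  Frames are independent given the seed.
    """
    helix = helix or HelixParams()
    if flex is None:
        raise ValueError("flex parameters are required")
    seg_len = 2.0 * helix.rise_per_subunit               # A
    lp_A = flex.persistence_length * 1e4                 # um -> A
    var_comp = seg_len / lp_A                            # per transverse component, rad^2
    rms_deg = math.degrees(math.sqrt(2.0 * var_comp))
    if rms_deg > _MAX_JOINT_RMS_DEG:
        raise ValueError(
            f"persistence length {flex.persistence_length} um gives an RMS joint bend "
            f"of {rms_deg:.1f} deg > {_MAX_JOINT_RMS_DEG} deg; small-angle regime violated")

    ideal = build_ideal_filament(template, helix)
    n_sub = helix.n_subunits
    n_res = ideal.coords.shape[1]
    n_seg = (n_sub + 1) // 2
    seg_of = np.arange(n_sub) // 2
    n_frames = flex.n_frames
    rng = np.random.default_rng(flex.seed)

    # accumulate one rigid transform (A, b) per segment: x' = A x + b
    seg_rot = np.empty((n_frames, n_seg, 3, 3))
    seg_off = np.empty((n_frames, n_seg, 3))
    a_cum = np.broadcast_to(np.eye(3), (n_frames, 3, 3)).copy()
    b_cum = np.zeros((n_frames, 3))
    seg_rot[:, 0] = a_cum
    seg_off[:, 0] = b_cum
    for k in range(1, n_seg):
        theta_xy = rng.normal(0.0, math.sqrt(var_comp), size=(n_frames, 2))
        theta = np.hypot(theta_xy[:, 0], theta_xy[:, 1])
        # local rotation axis perpendicular to the local tangent (z)
        with np.errstate(invalid="ignore"):
            ax_local = np.column_stack([theta_xy[:, 1], -theta_xy[:, 0],
                                        np.zeros(n_frames)]) / theta[:, None]
        ax_local[theta == 0] = [1.0, 0.0, 0.0]
        ax_world = np.einsum("nij,nj->ni", a_cum, ax_local)
        r_joint = _axis_angle_matrices(ax_world, theta)

        # hinge k sits on the axis between segments k-1 and k; its bent
        # position is the upstream transform of the ideal hinge point
        hinge = np.array([0.0, 0.0, (2 * k - 0.5) * helix.rise_per_subunit])
        pivot = np.einsum("nij,j->ni", a_cum, hinge) + b_cum
        a_cum = r_joint @ a_cum
        b_cum = np.einsum("nij,nj->ni", r_joint, b_cum - pivot) + pivot
        seg_rot[:, k] = a_cum
        seg_off[:, k] = b_cum

    coords = (np.einsum("nsij,srj->nsri", seg_rot[:, seg_of], ideal.coords)
              + seg_off[:, seg_of, None, :])

    if flex.residue_jitter_sd > 0:
        coords += rng.normal(0.0, flex.residue_jitter_sd, size=coords.shape)

    return FilamentEnsemble(coords, ideal.residue_ids, frame_interval=frame_interval,
                            label=label)


# ---------------------------------------------------------------------------
# Scalar AR(1) series
# ---------------------------------------------------------------------------

def ar1_series(n: int, rho: float, sigma: float, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series with lag-1 autocorrelation rho, marginal sd sigma."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    from scipy.signal import lfilter
    rng = np.random.default_rng(seed)
    innov = rng.normal(0.0, sigma * math.sqrt(1.0 - rho ** 2), size=n)
    innov[0] = rng.normal(0.0, sigma)  # stationary start
    return lfilter([1.0], [1.0, -rho], innov)


# ---------------------------------------------------------------------------
# Diffraction profile pairs
# ---------------------------------------------------------------------------

def _model_profile(p: ProfileParams, center: float) -> np.ndarray:
    x = np.arange(p.n_pixels, dtype=float)
    bg = p.background[0] + p.background[1] * x
    peak = p.amplitude * np.exp(-0.5 * ((x - center) / p.peak_sigma) ** 2)
    model = bg + peak
    if np.any(model < 0):
        raise ValueError("background model produces negative expected counts")
    return model


def make_profile_pair(p: ProfileParams,
                      geometry: DetectorGeometry | None = None,
                      noiseless: bool = False,
                      ) -> tuple[list[DiffractionProfile], list[DiffractionProfile]]:
    """Generate matched relaxed and activated exposure sets.

    The activated peak centre is ``center * (1 - relative_shift)``: a smaller
    pixel radius means a larger d-spacing, i.e. positive filament extension.
    Pixel values are Poisson-distributed about the Gaussian-plus-linear
    model unless ``noiseless``.
    """
    geometry = geometry or DetectorGeometry()
    rng = np.random.default_rng(p.seed)
    out: list[list[DiffractionProfile]] = []
    for state, center in (("relaxed", p.peak_center),
                          ("activated", p.peak_center * (1.0 - p.relative_shift))):
        model = _model_profile(p, center)
        profiles = []
        for j in range(p.n_exposures):
            counts = model.copy() if noiseless else rng.poisson(model).astype(float)
            profiles.append(DiffractionProfile(
                intensity=counts, state=state, geometry=geometry,
                label=f"{state}-{j}", meridian_origin=0.0))
        out.append(profiles)
    return out[0], out[1]
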