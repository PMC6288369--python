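"""Coarse-grained subunit geometry: subgroups SG1-SG4 and their COGs R1-R4.

Each actin subunit is reduced to the centres of geometry of four relatively
rigid residue subgroups; subunit shape is then described by three bonds
(R1-R2, R1-R3, R3-R4), two angles (R1-R3-R4, R2-R1-R3) and the signed
dihedral R2-R1-R3-R4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import Subunit, FilamentEnsemble, StatValue, N_RESIDUES
from . import blockstats

__all__ = ["SUBGROUPS", "assign_subgroup", "cg_of_subunit", "CGGeometry",
           "geometry_table", "geometry_to_frame", "PARAMETERS"]

# Inclusive residue ranges of the rigid subgroups.
SUBGROUPS: dict[str, list[tuple[int, int]]] = {
    "SG1": [(5, 33), (80, 147), (334, 349)],
    "SG2": [(34, 39), (52, 69)],
    "SG3": [(148, 179), (273, 333)],
    "SG4": [(180, 219), (252, 262)],
}

# (name, kind, units) in reporting order
PARAMETERS = [
    ("R1-R2", "bond", "A"),
    ("R1-R3", "bond", "A"),
    ("R3-R4", "bond", "A"),
    ("R1-R3-R4", "angle", "deg"),
    ("R2-R1-R3", "angle", "deg"),
    ("R2-R1-R3-R4", "dihedral", "deg"),
]

_COLLINEAR_EPS = 1e-10


def assign_subgroup(residue_id: int) -> str | None:
    """Subgroup membership of a residue id, or None for linker/loop residues."""
    if not 1 <= residue_id <= N_RESIDUES:
        raise ValueError(f"residue id {residue_id} outside 1..{N_RESIDUES}")
    for name, ranges in SUBGROUPS.items():
        for lo, hi in ranges:
            if lo <= residue_id <= hi:
                return name
    return None


def _subgroup_ids(name: str) -> np.ndarray:
    return np.concatenate([np.arange(lo, hi + 1) for lo, hi in SUBGROUPS[name]])


@dataclass
class CGGeometry:
    """R1-R4 points with derived bonds (A), angles and dihedral (deg)."""

    r1: np.ndarray
    r2: np.ndarray
    r3: np.ndarray
    r4: np.ndarray
    bonds: dict[str, float] = field(default_factory=dict)
    angles: dict[str, float] = field(default_factory=dict)
    dihedral: float = float("nan")
    dihedral_defined: bool = True

    def parameter(self, name: str) -> float:
        if name in self.bonds:
            return self.bonds[name]
        if name in self.angles:
            return self.angles[name]
        if name == "R2-R1-R3-R4":
            return self.dihedral
        raise KeyError(name)


def _angle(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    """Interior angle at q of the triple p-q-r, degrees in [0, 180]."""
    u, v = p - q, r - q
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _dihedral(p1, p2, p3, p4) -> tuple[float, bool]:
    """Signed torsion of the ordered quadruple, degrees in (-180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < _COLLINEAR_EPS or np.linalg.norm(n2) < _COLLINEAR_EPS:
        return float("nan"), False
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang, True


def cg_of_subunit(subunit: Subunit) -> CGGeometry:
    """Coarse-grain one subunit: COGs of SG1-SG4 and the six shape parameters."""
    cogs = {}
    rows = {int(r): i for i, r in enumerate(subunit.residue_ids)}
    for name in SUBGROUPS:
        idx = [rows[int(r)] for r in _subgroup_ids(name)]
        cogs[name] = subunit.coords[idx].mean(axis=0)
    r1, r2, r3, r4 = cogs["SG1"], cogs["SG2"], cogs["SG3"], cogs["SG4"]
    dih, ok = _dihedral(r2, r1, r3, r4)
    return CGGeometry(
        r1=r1, r2=r2, r3=r3, r4=r4,
        bonds={"R1-R2": float(np.linalg.norm(r1 - r2)),
               "R1-R3": float(np.linalg.norm(r1 - r3)),
               "R3-R4": float(np.linalg.norm(r3 - r4))},
        angles={"R1-R3-R4": _angle(r1, r3, r4),
                "R2-R1-R3": _angle(r2, r1, r3)},
        dihedral=dih, dihedral_defined=ok,
    )


def _parameter_series(ensemble: FilamentEnsemble) -> dict[str, np.ndarray]:
    """Per-frame subunit-averaged series for each shape parameter (vectorised)."""
    rows = {int(r): i for i, r in enumerate(ensemble.residue_ids)}
    cogs = {}
    for name in SUBGROUPS:
        idx = [rows[int(r)] for r in _subgroup_ids(name)]
        cogs[name] = ensemble.coords[:, :, idx, :].mean(axis=2)  # (n_frames, n_sub, 3)
    r1, r2, r3, r4 = cogs["SG1"], cogs["SG2"], cogs["SG3"], cogs["SG4"]

    def norm(v):
        return np.linalg.norm(v, axis=-1)

    def ang(p, q, r):
        u, v = p - q, r - q
        c = (u * v).sum(axis=-1) / (norm(u) * norm(v))
        return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

    # dihedral of the ordered quadruple (R2, R1, R3, R4)
    d1, d2, d3 = r1 - r2, r3 - r1, r4 - r3
    n1 = np.cross(d1, d2)
    n2 = np.cross(d2, d3)
    y = (np.cross(n1, n2) * d2).sum(axis=-1) / norm(d2)
    x = (n1 * n2).sum(axis=-1)
    dih = np.degrees(np.arctan2(y, x))
    dih = np.where(dih <= -180.0, dih + 360.0, dih)

    per_sub = {
        "R1-R2": norm(r1 - r2),
        "R1-R3": norm(r1 - r3),
        "R3-R4": norm(r3 - r4),
        "R1-R3-R4": ang(r1, r3, r4),
        "R2-R1-R3": ang(r2, r1, r3),
        "R2-R1-R3-R4": dih,
    }
    return {k: v.mean(axis=1) for k, v in per_sub.items()}  # subunit-averaged per frame


def geometry_table(ensemble: FilamentEnsemble,
                   block_size: int | str = "auto") -> dict[str, StatValue]:
    """Ensemble statistics of the six CG shape parameters.

    Subunits within a frame are averaged first (exchangeable replicates);
    the frame series then carries the time correlation handled by block
    averaging.
    """
    short = ensemble.n_frames < 10
    if short:
        warnings.warn(f"only {ensemble.n_frames} frames; geometry SDs reported as n/a",
                      stacklevel=2)
    series = _parameter_series(ensemble)
    out = {}
    for name, kind, units in PARAMETERS:
        s = series[name]
        if short:
            out[name] = StatValue(float(s.mean()), float("nan"),
                                  n_effective=float(len(s)), units=units)
        else:
            br = blockstats.block_average(s, block_size=block_size)
            out[name] = StatValue(br.mean, br.block_sd, float(br.n_blocks), units)
    return out


def geometry_to_frame(table: dict[str, StatValue]) -> pd.DataFrame:
    rows = [{"parameter": name, "kind": kind, "mean": table[name].mean,
             "sd": table[name].sd, "units": units}
            for name, kind, units in PARAMETERS]
    return pd.DataFrame(rows)
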