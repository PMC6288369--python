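"""Domain types and I/O for filament conformations.

A filament is represented by one point per residue (the alpha-carbon when
full-atom input is reduced; synthetic generators emit residue points
directly).  All coordinates are in Angstrom.  Ensembles are time-ordered
multi-model PDB files, one MODEL per frame, one chain per subunit.
"""

from __future__ import annotations

import string
from collections.abc import Iterator, Iterable
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

N_RESIDUES = 375  # actin numbering 1..375

__all__ = [
    "N_RESIDUES",
    "ParseError",
    "TopologyError",
    "ResiduePoint",
    "Subunit",
    "FilamentFrame",
    "FilamentEnsemble",
    "StatValue",
    "read_ensemble",
    "write_ensemble",
    "residue_cog",
]


class ParseError(ValueError):
    """Malformed coordinate record."""


class TopologyError(ValueError):
    """Inconsistent residue/subunit composition across chains or models."""


@dataclass(frozen=True)
class ResiduePoint:
    """One residue's representative point (Angstrom)."""

    residue_id: int
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"residue {self.residue_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class Subunit:
    """One actin subunit: an indexed set of residue points.

    ``strand_parity`` (index mod 2) identifies the long-pitch strand the
    subunit belongs to in the standard two-start architecture.
    """

    def __init__(self, index: int, residue_ids: np.ndarray, coords: np.ndarray):
        self.index = int(index)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.shape != (len(self.residue_ids), 3):
            raise ValueError("coords must be (n_residues, 3)")
        if len(np.unique(self.residue_ids)) != len(self.residue_ids):
            raise TopologyError(f"subunit {index}: duplicate residue ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"subunit {index}: non-finite coordinates")
        self._id_to_row = {int(r): i for i, r in enumerate(self.residue_ids)}

    @property
    def strand_parity(self) -> int:
        return self.index % 2

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def position_of(self, residue_id: int) -> np.ndarray:
        try:
            return self.coords[self._id_to_row[int(residue_id)]]
        except KeyError:
            raise KeyError(f"residue {residue_id} not present in subunit {self.index}") from None

    def __iter__(self) -> Iterator[ResiduePoint]:
        for rid, xyz in zip(self.residue_ids, self.coords):
            yield ResiduePoint(int(rid), xyz)


class FilamentFrame:
    """One filament conformation: an ordered list of subunits.

    Backed by a dense ``(n_subunits, n_residues, 3)`` array; all subunits
    share one residue-id vector.
    """

    def __init__(self, coords: np.ndarray, residue_ids: np.ndarray | None = None,
                 time: float | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must be (n_subunits, n_residues, 3)")
        if residue_ids is None:
            residue_ids = np.arange(1, coords.shape[1] + 1)
        self.coords = coords
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        if len(self.residue_ids) != coords.shape[1]:
            raise TopologyError("residue_ids length does not match coordinate array")
        self.time = time
        self._id_to_row = {int(r): i for i, r in enumerate(self.residue_ids)}

    @property
    def n_subunits(self) -> int:
        return self.coords.shape[0]

    def subunit(self, index: int) -> Subunit:
        if not 0 <= index < self.n_subunits:
            raise IndexError(f"subunit index {index} out of range 0..{self.n_subunits - 1}")
        return Subunit(index, self.residue_ids, self.coords[index])

    def subunits(self) -> Iterator[Subunit]:
        return (self.subunit(i) for i in range(self.n_subunits))

    def subunit_cogs(self) -> np.ndarray:
        """Centre of geometry of each subunit, shape (n_subunits, 3)."""
        return self.coords.mean(axis=1)

    def residue_rows(self, residue_ids: Iterable[int]) -> np.ndarray:
        rows = []
        for rid in residue_ids:
            try:
                rows.append(self._id_to_row[int(rid)])
            except KeyError:
                raise KeyError(f"residue {rid} not present in topology") from None
        return np.asarray(rows, dtype=int)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FilamentFrame":
        """Apply a rigid motion x -> R x + t."""
        new = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return FilamentFrame(new, self.residue_ids, self.time)


class FilamentEnsemble:
    """Time-ordered frames sharing one topology; the unit of all averaging."""

    def __init__(self, coords: np.ndarray, residue_ids: np.ndarray | None = None,
                 frame_interval: float = 1.0, label: str = "",
                 times: np.ndarray | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 4 or coords.shape[3] != 3:
            raise ValueError("coords must be (n_frames, n_subunits, n_residues, 3)")
        if coords.shape[0] == 0:
            raise ValueError("ensemble must contain at least one frame")
        if residue_ids is None:
            residue_ids = np.arange(1, coords.shape[2] + 1)
        self.coords = coords
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.frame_interval = float(frame_interval)
        self.label = label
        if times is None:
            times = self.frame_interval * np.arange(1, coords.shape[0] + 1)
        times = np.asarray(times, dtype=float)
        if len(times) != coords.shape[0]:
            raise ValueError("times length does not match number of frames")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_subunits(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> FilamentFrame:
        return FilamentFrame(self.coords[i], self.residue_ids, float(self.times[i]))

    def frames(self) -> Iterator[FilamentFrame]:
        return (self.frame(i) for i in range(self.n_frames))

    def subunit_cogs(self) -> np.ndarray:
        """(n_frames, n_subunits, 3) centres of geometry."""
        return self.coords.mean(axis=2)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FilamentEnsemble":
        new = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return FilamentEnsemble(new, self.residue_ids, self.frame_interval,
                                self.label, self.times)


@dataclass
class StatValue:
    """An ensemble statistic reported as mean (sd), as in the result tables."""

    mean: float
    sd: float
    n_effective: float
    units: str = ""

    def __post_init__(self):
        if np.isfinite(self.sd) and self.sd < 0:
            raise ValueError("sd must be non-negative")

    def __str__(self) -> str:
        if np.isnan(self.sd):
            return f"{self.mean:.2f} (n/a)"
        return f"{self.mean:.2f} ({self.sd:.2f})"


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (via biotite)
# ---------------------------------------------------------------------------

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _chain_id(i: int) -> str:
    if i >= len(_CHAIN_IDS):
        raise ValueError(f"more subunits ({i + 1}) than available chain ids")
    return _CHAIN_IDS[i]


def write_ensemble(ensemble: FilamentEnsemble, path) -> None:
    """Write an ensemble as multi-model PDB, one chain per subunit, CA per residue."""
    n_frames, n_sub, n_res, _ = ensemble.coords.shape
    n_atoms = n_sub * n_res
    arr = struc.AtomArray(n_atoms)
    arr.chain_id = np.repeat([_chain_id(i) for i in range(n_sub)], n_res)
    arr.res_id = np.tile(ensemble.residue_ids, n_sub)
    arr.res_name = np.full(n_atoms, "ALA")
    arr.atom_name = np.full(n_atoms, "CA")
    arr.element = np.full(n_atoms, "C")
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = ensemble.coords.reshape(n_frames, n_atoms, 3).astype(np.float32)
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


def read_ensemble(path, frame_interval: float = 1.0, label: str = "") -> FilamentEnsemble:
    """Read a multi-model PDB ensemble (one MODEL per frame, one chain per subunit).

    The representative-atom convention is enforced: one point per residue.
    Chain order in the first model fixes subunit order.
    """
    try:
        pdb_file = _pdb.PDBFile.read(path)
        stack = _pdb.get_structure(pdb_file)
    except struc.BadStructureError as exc:
        raise TopologyError(f"{path}: inconsistent atom records across models: {exc}") from exc
    except Exception as exc:  # biotite raises various errors on malformed columns
        if "model" in str(exc).lower():
            raise TopologyError(
                f"{path}: inconsistent atom records across models: {exc}") from exc
        raise ParseError(f"{path}: cannot parse PDB records: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    chain_ids = stack.chain_id
    # stable order of first appearance
    _, first_idx = np.unique(chain_ids, return_index=True)
    chains = [chain_ids[i] for i in np.sort(first_idx)]
    ref_ids = None
    per_chain_rows = []
    for ci, ch in enumerate(chains):
        mask = chain_ids == ch
        rids = stack.res_id[mask]
        if len(np.unique(rids)) != len(rids):
            raise TopologyError(
                f"{path}: chain {ch} has multiple atoms per residue; "
                "one representative point per residue is required")
        if ref_ids is None:
            ref_ids = rids
        elif not np.array_equal(np.sort(rids), np.sort(ref_ids)):
            raise TopologyError(
                f"{path}: chain {ch} residue set differs from chain {chains[0]}")
        rows = np.flatnonzero(mask)
        # order rows by the reference residue-id order
        order = np.argsort(rids)[np.argsort(np.argsort(ref_ids))]
        per_chain_rows.append(rows[order])

    n_frames = stack.stack_depth()
    n_sub = len(chains)
    n_res = len(ref_ids)
    coords = np.empty((n_frames, n_sub, n_res, 3), dtype=float)
    for ci, rows in enumerate(per_chain_rows):
        coords[:, ci, :, :] = stack.coord[:, rows, :]
    return FilamentEnsemble(coords, ref_ids, frame_interval=frame_interval, label=label)


def residue_cog(subunit: Subunit, residue_ids: Iterable[int]) -> np.ndarray:
    """Unweighted centre of geometry of the given residues' points."""
    ids = list(residue_ids)
    if not ids:
        raise ValueError("residue_ids must be non-empty")
    rows = [subunit.position_of(r) for r in ids]
    return np.mean(rows, axis=0)
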