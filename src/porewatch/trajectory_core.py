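"""Structure/trajectory loading and per-molecule centre-of-geometry tracks.

File parsing is delegated to MDAnalysis; everything downstream of this module
works on plain numpy arrays in the package's internal units (nm, ns).  The
centre of geometry is the *unweighted* mean of the member-atom coordinates —
occupancy and permeation assignments are geometric, not mass-weighted — and
molecules split across a periodic boundary are made whole by a minimum-image
displacement chain from the molecule's first atom before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    FormatError,
    SelectionError,
    TopologyError,
    ValidationError,
)

ANGSTROM_TO_NM = 0.1
PS_TO_NS = 1e-3

_STRUCTURE_DIALECTS = {"pdb", "gro"}
_TRAJECTORY_DIALECTS = {"xtc", "dcd", "xyz", "pdb"}


@dataclass
class Structure:
    """A reference structure with per-atom annotations, coordinates in nm.

    ``box`` holds orthorhombic box edge lengths (nm) or ``None`` when the
    source file carries no box record (e.g. most PDB files).
    """

    atom_names: np.ndarray  # (N,) str
    res_names: np.ndarray  # (N,) str
    res_ids: np.ndarray  # (N,) int
    chain_ids: np.ndarray  # (N,) str
    coords: np.ndarray  # (N, 3) float, nm
    box: np.ndarray | None = None  # (3,) float, nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("structure coordinates must be finite")
        if np.any(np.asarray(self.res_ids) < 0):
            raise ValidationError("residue indices must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class Trajectory:
    """An in-memory trajectory for a declared atom set.

    ``coords`` has shape (frames, atoms, 3) in nm, ``times`` is strictly
    increasing in ns, ``box`` is per-frame orthorhombic edge lengths (nm).
    """

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray  # (F, 3) nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (frames, atoms, 3)")
        if self.n_frames < 1:
            raise ValidationError("trajectory must have at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("trajectory coordinates must be finite")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")
        if self.box.shape != (self.n_frames, 3):
            raise ValidationError("box must have shape (frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class SpeciesSelection:
    """Maps atoms to molecules of one species by residue grouping.

    Atoms whose residue name is in ``resnames`` are grouped into molecules by
    (chain id, residue id, residue name); every such residue is one molecule.
    """

    label: str
    resnames: Sequence[str] = field(default_factory=list)

    def resolve(self, structure: Structure) -> list[np.ndarray]:
        """Return one atom-index array per molecule, in first-atom order."""
        wanted = set(self.resnames) if self.resnames else {self.label}
        mask = np.isin(structure.res_names, list(wanted))
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise SelectionError(
                f"selection {self.label!r} matched no atoms "
                f"(residue names {sorted(wanted)})"
            )
        keys = [
            (structure.chain_ids[i], structure.res_ids[i], structure.res_names[i])
            for i in idx
        ]
        groups: dict[tuple, list[int]] = {}
        for i, key in zip(idx, keys):
            groups.setdefault(key, []).append(int(i))
        return [np.asarray(g, dtype=int) for g in groups.values()]


@dataclass
class MoleculeTracks:
    """Per-molecule, per-frame centre-of-geometry positions for one species."""

    species: str
    positions: np.ndarray  # (F, M, 3) nm
    molecule_ids: np.ndarray  # (M,) int, stable across frames
    times: np.ndarray  # (F,) ns

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]


def _check_dialect(path: str | Path, dialect: str | None, allowed: set[str]) -> str:
    if dialect is None:
        dialect = Path(path).suffix.lstrip(".").lower()
    dialect = dialect.lower()
    if dialect not in allowed:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {sorted(allowed)}"
        )
    return dialect


def load_structure(path: str | Path, dialect: str | None = None) -> Structure:
    """Load a PDB or GRO file into a :class:`Structure` (coordinates in nm).

    ``dialect`` defaults to the file suffix.  Parse failures raise
    :class:`~porewatch.errors.FormatError` naming the file.
    """
    import MDAnalysis as mda

    dialect = _check_dialect(path, dialect, _STRUCTURE_DIALECTS)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=dialect)
        coords = u.atoms.positions.astype(float) * ANGSTROM_TO_NM
    except (OSError, ValueError, EOFError, IndexError) as exc:
        raise FormatError(f"{path}: could not parse as {dialect}: {exc}") from exc
    if len(coords) == 0:
        raise FormatError(f"{path}: no atoms parsed")
    box = None
    dims = u.dimensions
    if dims is not None and np.all(dims[:3] > 0):
        box = np.asarray(dims[:3], dtype=float) * ANGSTROM_TO_NM
    try:
        chains = u.atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        try:
            chains = u.atoms.segids
        except (AttributeError, mda.exceptions.NoDataError):
            chains = np.array([""] * len(coords))
    return Structure(
        atom_names=np.asarray(u.atoms.names, dtype=object),
        res_names=np.asarray(u.atoms.resnames, dtype=object),
        res_ids=np.asarray(u.atoms.resids, dtype=int),
        chain_ids=np.asarray(chains, dtype=object),
        coords=coords,
        box=box,
    )


def load_trajectory(
    path: str | Path,
    topology: Structure,
    dialect: str | None = None,
    stride_ns: float | None = None,
    box: np.ndarray | None = None,
    topology_path: str | Path | None = None,
) -> Trajectory:
    """Load a coordinate trajectory (XTC, DCD, multi-frame XYZ or PDB).

    Times are taken from the file when present, otherwise synthesised as
    ``frame_index * stride_ns``; formats without times require ``stride_ns``.
    Formats without box records (XYZ) require ``box`` (nm edge lengths) unless
    the topology carries one.  Atom count must match ``topology``.
    """
    import MDAnalysis as mda

    dialect = _check_dialect(path, dialect, _TRAJECTORY_DIALECTS)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if topology_path is not None:
                u = mda.Universe(str(topology_path), str(path), format=dialect)
            else:
                u = mda.Universe(str(path), format=dialect)
    except (OSError, ValueError, EOFError, IndexError) as exc:
        raise FormatError(f"{path}: could not parse as {dialect}: {exc}") from exc

    if u.atoms.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"{path}: trajectory has {u.atoms.n_atoms} atoms but topology "
            f"has {topology.n_atoms}"
        )

    file_has_times = dialect in {"xtc", "dcd"}
    if not file_has_times and stride_ns is None:
        raise ConfigurationError(
            f"{dialect} files carry no frame times; pass stride_ns"
        )

    frames, times, boxes = [], [], []
    prev_box = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ts in enumerate(u.trajectory):
            frames.append(ts.positions.astype(float) * ANGSTROM_TO_NM)
            if file_has_times:
                times.append(float(ts.time) * PS_TO_NS)
            else:
                times.append(i * stride_ns)
            dims = ts.dimensions
            if dims is not None and np.all(dims[:3] > 0):
                prev_box = np.asarray(dims[:3], dtype=float) * ANGSTROM_TO_NM
            elif prev_box is None:
                if box is not None:
                    prev_box = np.asarray(box, dtype=float)
                elif topology.box is not None:
                    prev_box = topology.box
                else:
                    raise ConfigurationError(
                        f"{path}: first frame has no box vectors and no box "
                        "was supplied"
                    )
            boxes.append(prev_box)

    coords = np.asarray(frames)
    if not np.all(np.isfinite(coords)):
        raise ValidationError(f"{path}: non-finite coordinates in trajectory")
    return Trajectory(coords=coords, times=np.asarray(times), box=np.asarray(boxes))


def make_whole(atom_coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Reassemble a molecule split across periodic boundaries.

    Each atom after the first is placed at the minimum-image position
    relative to the first atom (adequate for compact molecules a few bonds
    across).  ``atom_coords`` is (n_atoms, 3); ``box`` is (3,) edge lengths.
    """
    out = np.array(atom_coords, dtype=float)
    disp = out[1:] - out[0]
    out[1:] -= np.round(disp / box) * box
    return out


def centers_of_geometry(
    traj: Trajectory, sel: SpeciesSelection, structure: Structure
) -> MoleculeTracks:
    """Unweighted per-molecule centre-of-geometry tracks for one species.

    Molecules straddling a periodic boundary are made whole (minimum image
    about the first atom) before averaging, so a dimer at z = 9.9 and 0.1 in
    a 10 nm box has its centre at 10.0 ≡ 0.0, not 5.0.
    """
    groups = sel.resolve(structure)
    F = traj.n_frames
    M = len(groups)
    positions = np.empty((F, M, 3))
    for f in range(F):
        frame = traj.coords[f]
        box = traj.box[f]
        for m, atoms in enumerate(groups):
            if len(atoms) == 1:
                positions[f, m] = frame[atoms[0]]
            else:
                positions[f, m] = make_whole(frame[atoms], box).mean(axis=0)
    return MoleculeTracks(
        species=sel.label,
        positions=positions,
        molecule_ids=np.arange(M),
        times=traj.times.copy(),
    )


def write_tracks_tsv(tracks: MoleculeTracks, path: str | Path) -> None:
    """Write tracks as a delimited table: molecule id, frame, t, x, y, z."""
    import pandas as pd

    F, M, _ = tracks.positions.shape
    mol = np.repeat(tracks.molecule_ids, F)
    frame = np.tile(np.arange(F), M)
    t = np.tile(tracks.times, M)
    xyz = tracks.positions.transpose(1, 0, 2).reshape(-1, 3)
    df = pd.DataFrame(
        {
            "molecule_id": mol,
            "frame": frame,
            "t_ns": t,
            "x_nm": xyz[:, 0],
            "y_nm": xyz[:, 1],
            "z_nm": xyz[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_tracks_h5(tracks: MoleculeTracks, path: str | Path) -> None:
    """Write tracks to HDF5 (datasets: positions, molecule_ids, times)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["species"] = tracks.species
        h5.create_dataset("positions", data=tracks.positions)
        h5.create_dataset("molecule_ids", data=tracks.molecule_ids)
        h5.create_dataset("times", data=tracks.times)


def read_tracks_h5(path: str | Path) -> MoleculeTracks:
    """Read tracks previously written by :func:`write_tracks_h5`."""
    import h5py

    with h5py.File(path, "r") as h5:
        return MoleculeTracks(
            species=str(h5.attrs["species"]),
            positions=h5["positions"][...],
            molecule_ids=h5["molecule_ids"][...],
            times=h5["times"][...],
        )
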