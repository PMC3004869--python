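"""Trajectory and topology containers plus standard-format I/O.

Multi-model PDB files are read and written through biotite; binary DCD
files (little-endian CHARMM/NAMD dialect) through mdtraj's low-level
``DCDTrajectoryFile``, which works natively in Å. A plain TSV side-table
carries the per-atom bookkeeping (names, residue numbers, optional charges
and Lennard-Jones parameters) that DCD files do not store.

Units: coordinates Å, charges in elementary charges, LJ well depths in
kcal/mol, LJ radii (rmin/2) in Å. Residue numbers are 1-based and residue
ranges are inclusive, so "residues 1-7" means seven residues.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SelectionError

_TOPOLOGY_COLUMNS = [
    "atom_name",
    "residue_number",
    "residue_name",
    "element",
    "charge",
    "lj_epsilon",
    "lj_rmin_half",
]


@dataclass
class Topology:
    """Ordered per-atom bookkeeping shared by every frame of a trajectory.

    ``charge``/``lj_epsilon``/``lj_rmin_half`` are either present for all
    atoms or absent (None); LJ well depths are stored as positive values.
    """

    atom_names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    elements: np.ndarray
    charges: np.ndarray | None = None
    lj_epsilons: np.ndarray | None = None
    lj_rmin_halves: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        n = len(self.atom_names)
        for name in ("residue_numbers", "residue_names", "elements"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"topology field {name} has wrong length")
        if np.any(np.diff(self.residue_numbers) < 0):
            raise FormatError("residue numbers must be non-decreasing")
        params = (self.charges, self.lj_epsilons, self.lj_rmin_halves)
        present = [p is not None for p in params]
        if any(present) and not all(present):
            raise FormatError(
                "charges and LJ parameters must be present for all atoms or none"
            )
        if all(present):
            self.charges = np.asarray(self.charges, dtype=float)
            self.lj_epsilons = np.abs(np.asarray(self.lj_epsilons, dtype=float))
            self.lj_rmin_halves = np.asarray(self.lj_rmin_halves, dtype=float)
            for p in (self.charges, self.lj_epsilons, self.lj_rmin_halves):
                if len(p) != n:
                    raise FormatError("nonbonded parameter table has wrong length")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_numbers))

    @property
    def has_nonbonded_params(self) -> bool:
        return self.charges is not None

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "atom_name": self.atom_names,
                "residue_number": self.residue_numbers,
                "residue_name": self.residue_names,
                "element": self.elements,
                "charge": self.charges if self.charges is not None else np.nan,
                "lj_epsilon": self.lj_epsilons
                if self.lj_epsilons is not None
                else np.nan,
                "lj_rmin_half": self.lj_rmin_halves
                if self.lj_rmin_halves is not None
                else np.nan,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Topology":
        df = pd.read_csv(path, sep="\t")
        missing = set(_TOPOLOGY_COLUMNS[:4]) - set(df.columns)
        if missing:
            raise FormatError(f"topology TSV lacks columns: {sorted(missing)}")
        have_params = (
            {"charge", "lj_epsilon", "lj_rmin_half"} <= set(df.columns)
            and not df[["charge", "lj_epsilon", "lj_rmin_half"]].isna().any().any()
        )
        return cls(
            atom_names=df["atom_name"].to_numpy(),
            residue_numbers=df["residue_number"].to_numpy(),
            residue_names=df["residue_name"].to_numpy(),
            elements=df["element"].to_numpy(),
            charges=df["charge"].to_numpy() if have_params else None,
            lj_epsilons=df["lj_epsilon"].to_numpy() if have_params else None,
            lj_rmin_halves=df["lj_rmin_half"].to_numpy() if have_params else None,
        )


@dataclass
class SelectionSpec:
    """Atom-name set plus an inclusive 1-based residue range, e.g. CA 1-7."""

    atom_names: frozenset[str]
    residue_range: tuple[int, int]

    def __init__(self, atom_names: Iterable[str], residue_range: Sequence[int]):
        object.__setattr__(self, "atom_names", frozenset(atom_names))
        first, last = int(residue_range[0]), int(residue_range[1])
        if first > last:
            raise SelectionError(f"residue range {first}-{last} is empty")
        object.__setattr__(self, "residue_range", (first, last))

    def __repr__(self) -> str:  # e.g. "CA 1-7"
        names = "+".join(sorted(self.atom_names))
        return f"{names} {self.residue_range[0]}-{self.residue_range[1]}"


#: The selections the analyses default to: Cα of residues 1-7 for RMSD/state
#: classification, Cα of residues 2-6 for the structure-gallery alignment.
CA_CORE = SelectionSpec(["CA"], (1, 7))
CA_HELIX_WINDOW = SelectionSpec(["CA"], (2, 6))


def resolve_selection(topology: Topology, selection: SelectionSpec) -> np.ndarray:
    """Indices (in topology order) of atoms matching the selection."""
    first, last = selection.residue_range
    names_ok = np.isin(topology.atom_names.astype(str), sorted(selection.atom_names))
    res_ok = (topology.residue_numbers >= first) & (topology.residue_numbers <= last)
    idx = np.nonzero(names_ok & res_ok)[0]
    if idx.size == 0:
        raise SelectionError(f"selection {selection!r} matches no atoms")
    return idx


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates in Å with shared topology.

    ``labels`` optionally carries per-frame ground-truth state tags
    ("folded"/"unfolded") when the trajectory came from the synthetic
    generator.
    """

    topology: Topology
    coordinates: np.ndarray
    frame_interval_ps: float = 0.8
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FormatError(
                f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"coordinate array has {self.coordinates.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.coordinates.size and not np.all(np.isfinite(self.coordinates)):
            raise FormatError("coordinates contain non-finite values")
        if self.frame_interval_ps <= 0:
            raise FormatError("frame_interval_ps must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.n_frames:
                raise FormatError("labels length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def with_coordinates(self, coords: np.ndarray) -> "Trajectory":
        return replace(self, coordinates=coords)

    def slice_frames(self, frame_slice: slice) -> "Trajectory":
        labels = self.labels[frame_slice] if self.labels is not None else None
        return Trajectory(
            self.topology,
            self.coordinates[frame_slice],
            self.frame_interval_ps,
            labels,
        )


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file; one frame per MODEL block."""
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises various exceptions on bad files
        raise FormatError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"{path}: no atoms")
    topology = Topology(
        atom_names=stack.atom_name.astype(object),
        residue_numbers=stack.res_id,
        residue_names=stack.res_name.astype(object),
        elements=stack.element.astype(object),
    )
    return Trajectory(topology, np.asarray(stack.coord, dtype=float))


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write standard MODEL/ENDMDL records with 8.3 fixed-width coordinates."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = trajectory.topology
    n = top.n_atoms
    arrays = []
    for frame in trajectory.coordinates:
        arr = struc.AtomArray(n)
        arr.coord = frame.astype(np.float32)
        arr.atom_name = top.atom_names.astype("U6")
        arr.res_id = top.residue_numbers
        arr.res_name = top.residue_names.astype("U5")
        arr.element = top.elements.astype("U2")
        arr.chain_id = np.full(n, "A", dtype="U4")
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def _dcd_frame_count(path: Path) -> int | None:
    """NSET from a CHARMM DCD header, or None if the header is unreadable."""
    import struct

    try:
        with open(path, "rb") as fh:
            head = fh.read(12)
        block_len, magic, nset = struct.unpack("<i4si", head)
        if block_len == 84 and magic == b"CORD":
            return nset
    except (OSError, struct.error):
        pass
    return None


def read_dcd(path: str | Path, topology: Topology) -> Trajectory:
    """Read a CHARMM/NAMD-dialect binary DCD file (coordinates in Å)."""
    from mdtraj.formats import DCDTrajectoryFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _dcd_frame_count(path) == 0:
        # a valid header with zero frames is an empty trajectory
        return Trajectory(topology, np.empty((0, topology.n_atoms, 3)))
    try:
        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _cell_lengths, _cell_angles = fh.read()
    except Exception as exc:
        raise FormatError(f"cannot read DCD {path}: {exc}") from exc
    xyz = np.asarray(xyz)
    if xyz.size == 0:
        xyz = np.empty((0, topology.n_atoms, 3))
    if xyz.shape[1] != topology.n_atoms:
        raise FormatError(
            f"DCD has {xyz.shape[1]} atoms per frame, topology has {topology.n_atoms}"
        )
    return Trajectory(topology, xyz.astype(float))


def write_dcd(trajectory: Trajectory, path: str | Path) -> None:
    """Write a little-endian CHARMM-dialect DCD (32-bit floats, Å)."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path), "w") as fh:
        fh.write(trajectory.coordinates.astype(np.float32))


def write_labels_tsv(trajectory: Trajectory, path: str | Path) -> None:
    """Per-frame ground-truth state labels as a two-column TSV."""
    if trajectory.labels is None:
        raise ValueError("trajectory carries no labels")
    pd.DataFrame(
        {"frame": np.arange(trajectory.n_frames), "label": trajectory.labels}
    ).to_csv(path, sep="\t", index=False)
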