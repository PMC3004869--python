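"""Simplified per-residue secondary-structure assignment.

A deliberately reduced assigner producing α-helix / 3₁₀-helix / turn /
coil timelines from backbone heavy atoms: amide hydrogens are rebuilt
geometrically, hydrogen bonds are called with the Kabsch–Sander
electrostatic energy (threshold -0.5 kcal/mol), and helices from the usual
patterns — two consecutive i→i+4 bonds make an α-helix (code H), two
consecutive i→i+3 bonds a 3₁₀ helix (G), an isolated helical bond a turn
(T), everything else coil (C). H takes precedence over G over T. This is
an explicit approximation of full assigners such as STRIDE or DSSP (no
torsional propensity terms, no β-structure).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import HBOND_ENERGY_CUTOFF, KABSCH_SANDER_PREFACTOR
from .errors import SelectionError
from .trajectory_io import Topology, Trajectory

N_H_BOND_LENGTH = 1.01
CLASH_DISTANCE = 0.5
CODES = ("H", "G", "T", "C")


def _backbone_index(topology: Topology, name: str) -> np.ndarray:
    """Per-residue atom index for one backbone atom name (residues in order)."""
    residues = np.unique(topology.residue_numbers)
    idx = np.empty(len(residues), dtype=int)
    for k, r in enumerate(residues):
        hit = np.nonzero(
            (topology.residue_numbers == r)
            & (topology.atom_names.astype(str) == name)
        )[0]
        if hit.size == 0:
            raise SelectionError(f"residue {r} lacks backbone atom {name}")
        idx[k] = hit[0]
    return idx


def build_amide_hydrogens(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """Backbone amide-H positions, (n_residues, 3); NaN for the first residue.

    H is placed 1.01 Å from N along the external bisector of the
    C(i-1)-N(i) and CA(i)-N(i) bonds, i.e. in the C(i-1)-N(i)-CA(i) plane,
    trans to both heavy-atom neighbours. Works on a single structure
    (n_atoms, 3) or a stack (frames, n_atoms, 3); the frame axis is
    preserved.
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    frames = coords[None] if single else coords
    n_idx = _backbone_index(topology, "N")
    ca_idx = _backbone_index(topology, "CA")
    c_idx = _backbone_index(topology, "C")
    n_res = len(n_idx)

    h = np.full((frames.shape[0], n_res, 3), np.nan)
    n_pos = frames[:, n_idx[1:]]
    u1 = n_pos - frames[:, c_idx[:-1]]
    u2 = n_pos - frames[:, ca_idx[1:]]
    u1 /= np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 /= np.linalg.norm(u2, axis=-1, keepdims=True)
    bis = u1 + u2
    bis /= np.linalg.norm(bis, axis=-1, keepdims=True)
    h[:, 1:] = n_pos + N_H_BOND_LENGTH * bis
    return h[0] if single else h


def backbone_hbond(
    coords: np.ndarray,
    topology: Topology,
    acceptor_residue: int,
    donor_residue: int,
    hydrogens: np.ndarray | None = None,
) -> tuple[bool, float]:
    """Kabsch–Sander energy and bond call for one C=O(acceptor)···H-N(donor).

    E = 0.42*0.20*332 * [1/r(ON) + 1/r(CH) - 1/r(OH) - 1/r(CN)] kcal/mol;
    bonded iff E < -0.5 kcal/mol. Residues are 1-based. Any inter-atomic
    distance below 0.5 Å is treated as a steric clash: not bonded, energy 0.
    """
    coords = np.asarray(coords, dtype=float)
    if hydrogens is None:
        hydrogens = build_amide_hydrogens(coords, topology)
    residues = np.unique(topology.residue_numbers)
    pos = {r: k for k, r in enumerate(residues)}
    a, d = pos[acceptor_residue], pos[donor_residue]
    o = coords[_backbone_index(topology, "O")[a]]
    c = coords[_backbone_index(topology, "C")[a]]
    n = coords[_backbone_index(topology, "N")[d]]
    h = hydrogens[d]
    if np.any(np.isnan(h)):
        return False, 0.0  # first residue has no amide H
    dist = np.array(
        [
            np.linalg.norm(o - n),
            np.linalg.norm(c - h),
            np.linalg.norm(o - h),
            np.linalg.norm(c - n),
        ]
    )
    if np.any(dist < CLASH_DISTANCE):
        return False, 0.0
    energy = KABSCH_SANDER_PREFACTOR * (
        1.0 / dist[0] + 1.0 / dist[1] - 1.0 / dist[2] - 1.0 / dist[3]
    )
    return bool(energy < HBOND_ENERGY_CUTOFF), float(energy)


def _helical_bond_table(
    frames: np.ndarray, topology: Topology
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (frames, n_res) tables of i→i+4 and i→i+3 H-bonds.

    Entry [t, i] refers to acceptor residue index i (0-based) in frame t;
    entries whose donor would fall past the chain end are False.
    """
    n_idx = _backbone_index(topology, "N")
    c_idx = _backbone_index(topology, "C")
    o_idx = _backbone_index(topology, "O")
    n_res = len(n_idx)
    hydrogens = build_amide_hydrogens(frames, topology)

    tables = []
    for offset in (4, 3):
        table = np.zeros((frames.shape[0], n_res), dtype=bool)
        if n_res > offset:
            acc = np.arange(n_res - offset)
            don = acc + offset
            o = frames[:, o_idx[acc]]
            c = frames[:, c_idx[acc]]
            n = frames[:, n_idx[don]]
            h = hydrogens[:, don]
            d_on = np.linalg.norm(o - n, axis=-1)
            d_ch = np.linalg.norm(c - h, axis=-1)
            d_oh = np.linalg.norm(o - h, axis=-1)
            d_cn = np.linalg.norm(c - n, axis=-1)
            energy = KABSCH_SANDER_PREFACTOR * (
                1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn
            )
            clash = (
                (d_on < CLASH_DISTANCE)
                | (d_ch < CLASH_DISTANCE)
                | (d_oh < CLASH_DISTANCE)
                | (d_cn < CLASH_DISTANCE)
            )
            table[:, acc] = (energy < HBOND_ENERGY_CUTOFF) & ~clash
        tables.append(table)
    return tables[0], tables[1]


def _codes_from_bonds(bonds4: np.ndarray, bonds3: np.ndarray) -> np.ndarray:
    """Apply the pattern rules to one frame's acceptor-indexed bond rows."""
    n_res = bonds4.shape[0]
    codes = np.full(n_res, "C", dtype=object)
    # turns first (lowest precedence): any single helical H-bond marks the
    # residues it spans between acceptor and donor
    for offset, bonds in ((3, bonds3), (4, bonds4)):
        for i in np.nonzero(bonds)[0]:
            codes[i + 1 : i + offset] = "T"
    # 3_10: two consecutive i->i+3 bonds
    for i in np.nonzero(bonds3[:-1] & bonds3[1:])[0]:
        codes[i + 1 : i + 4] = "G"
    # alpha wins: two consecutive i->i+4 bonds
    for i in np.nonzero(bonds4[:-1] & bonds4[1:])[0]:
        codes[i + 1 : i + 5] = "H"
    return codes


def assign_frame(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """Per-residue codes over {H, G, T, C} for a single structure."""
    bonds4, bonds3 = _helical_bond_table(
        np.asarray(coords, dtype=float)[None], topology
    )
    return _codes_from_bonds(bonds4[0], bonds3[0])


@dataclass(frozen=True)
class SSTimeline:
    """Secondary-structure codes per frame and residue plus occupancies."""

    codes: np.ndarray  # (frames, residues) over {"H","G","T","C"}
    residue_numbers: np.ndarray

    def occupancy(self) -> pd.DataFrame:
        """Fraction of frames per residue spent in each code."""
        rows = {
            code: (self.codes == code).mean(axis=0) for code in CODES
        }
        return pd.DataFrame(rows, index=self.residue_numbers).rename_axis(
            "residue"
        )

    def to_strings(self) -> list[str]:
        return ["".join(row) for row in self.codes]


def timeline(trajectory: Trajectory) -> SSTimeline:
    """Assign every frame of a trajectory; rows of ``codes`` are frames."""
    bonds4, bonds3 = _helical_bond_table(trajectory.coordinates, trajectory.topology)
    codes = np.stack(
        [_codes_from_bonds(b4, b3) for b4, b3 in zip(bonds4, bonds3)]
    )
    return SSTimeline(
        codes=codes,
        residue_numbers=np.unique(trajectory.topology.residue_numbers),
    )
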