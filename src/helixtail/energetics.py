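"""Pairwise nonbonded (screened Coulomb + Lennard-Jones) interaction energy.

Quantifies the coupling between two disjoint atom sets — here the helical
core and individual tail residues — with a distance-dependent screened
Coulomb term (relative dielectric, default 20) and a CHARMM-style
Lennard-Jones term in the Rmin form with Lorentz–Berthelot-like combining:

    E_coul = Σ 332.0636 q_i q_j / (ε_r r_ij)            [kcal/mol]
    E_lj   = Σ ε_ij [ (Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6 ],
             ε_ij = sqrt(ε_i ε_j),  Rmin_ij = rmin_half_i + rmin_half_j

No distance cutoff and no 1-4 exclusions are applied: the sets are assumed
to live on different residues. Covalently bonded and 1-3 pairs (which any
force field excludes, and which otherwise diverge — e.g. the peptide bond
linking residue 7 to residue 8 when the interface splits adjacent
residues) are excluded based on standard backbone connectivity inferred
from atom names. Both terms are reported separately so a
screened-Coulomb-only reading is also recoverable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COULOMB_CONSTANT_KCAL
from .trajectory_io import Topology, Trajectory

SINGULARITY_DISTANCE = 0.01


@dataclass(frozen=True)
class NonbondedParams:
    """Relative dielectric used to screen the Coulomb term."""

    relative_dielectric: float = 20.0

    def __post_init__(self) -> None:
        if self.relative_dielectric <= 0:
            raise ValueError("relative dielectric must be positive")


def backbone_exclusion_matrix(topology: Topology) -> np.ndarray:
    """Boolean (n, n) matrix of 1-2 and 1-3 pairs on the backbone bond graph.

    Bonds are inferred from standard atom naming: N-CA, CA-C, C-O within a
    residue and C(i)-N(i+1) between consecutive residues.
    """
    n = topology.n_atoms
    adj = np.zeros((n, n), dtype=bool)
    names = topology.atom_names.astype(str)
    resnums = topology.residue_numbers

    def find(res: int, name: str) -> int | None:
        hit = np.nonzero((resnums == res) & (names == name))[0]
        return int(hit[0]) if hit.size else None

    for res in np.unique(resnums):
        atoms = {nm: find(res, nm) for nm in ("N", "CA", "C", "O")}
        for a, b in (("N", "CA"), ("CA", "C"), ("C", "O")):
            if atoms[a] is not None and atoms[b] is not None:
                adj[atoms[a], atoms[b]] = adj[atoms[b], atoms[a]] = True
        nxt = find(res + 1, "N")
        if atoms["C"] is not None and nxt is not None:
            adj[atoms["C"], nxt] = adj[nxt, atoms["C"]] = True
    return (adj @ adj) | adj


def _check_sets(topology: Topology, set_a: np.ndarray, set_b: np.ndarray):
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if np.intersect1d(set_a, set_b).size:
        raise ValueError("atom sets must be disjoint")
    if not topology.has_nonbonded_params:
        raise ValueError("topology carries no charges/LJ parameters")
    return set_a, set_b


def nonbonded_energy(
    coords: np.ndarray,
    topology: Topology,
    set_a: np.ndarray,
    set_b: np.ndarray,
    params: NonbondedParams = NonbondedParams(),
    exclusions: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(coulomb, lj, total) in kcal/mol between two disjoint atom sets.

    ``exclusions`` is an optional precomputed (n, n) boolean matrix of
    bonded/1-3 pairs (see :func:`backbone_exclusion_matrix`); it is derived
    from the topology when omitted.
    """
    set_a, set_b = _check_sets(topology, set_a, set_b)
    coords = np.asarray(coords, dtype=float)
    if exclusions is None:
        exclusions = backbone_exclusion_matrix(topology)
    include = ~exclusions[np.ix_(set_a, set_b)]
    r = np.linalg.norm(
        coords[set_a][:, None, :] - coords[set_b][None, :, :], axis=-1
    )
    if np.any(r[include] < SINGULARITY_DISTANCE):
        raise ValueError(
            f"atom pair closer than {SINGULARITY_DISTANCE} Å: singular energy"
        )
    r = np.where(include, r, np.inf)
    q = np.outer(topology.charges[set_a], topology.charges[set_b])
    coulomb = float(
        (COULOMB_CONSTANT_KCAL * q / (params.relative_dielectric * r)).sum()
    )
    eps = np.sqrt(
        np.outer(topology.lj_epsilons[set_a], topology.lj_epsilons[set_b])
    )
    rmin = (
        topology.lj_rmin_halves[set_a][:, None]
        + topology.lj_rmin_halves[set_b][None, :]
    )
    with np.errstate(divide="ignore"):
        ratio6 = (rmin / r) ** 6
    lj = float((eps * (ratio6 ** 2 - 2.0 * ratio6)).sum())
    return coulomb, lj, coulomb + lj


def interaction_energy_series(
    trajectory: Trajectory,
    set_a: np.ndarray,
    set_b: np.ndarray,
    params: NonbondedParams = NonbondedParams(),
) -> pd.DataFrame:
    """Per-frame interaction energies as a DataFrame (frame, coulomb, lj, total).

    The arithmetic means are available as ``df.mean()``.
    """
    exclusions = backbone_exclusion_matrix(trajectory.topology)
    rows = [
        nonbonded_energy(
            frame, trajectory.topology, set_a, set_b, params, exclusions
        )
        for frame in trajectory.coordinates
    ]
    df = pd.DataFrame(rows, columns=["coulomb", "lj", "total"])
    df.insert(0, "frame", np.arange(len(df)))
    return df


def residue_atom_set(topology: Topology, first: int, last: int) -> np.ndarray:
    """All atom indices of residues first..last (inclusive, 1-based)."""
    mask = (topology.residue_numbers >= first) & (topology.residue_numbers <= last)
    return np.nonzero(mask)[0]
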