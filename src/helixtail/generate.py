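"""Synthetic peptide-backbone trajectories with known two-state thermodynamics.

Every analysis stage in this package is exercised on trajectories from this
module: an idealized backbone (N, CA, C, O per residue; no side chains —
all in-scope analyses use Cα or backbone atoms only) that interconverts
between a helical folded state and fresh random-coil conformers under a
two-state Markov chain whose stationary folded fraction is set exactly.
Folded frames are the ideal helix template plus isotropic Gaussian jitter,
with an optionally hyper-mobile C-terminal tail given 5x the jitter, which
reproduces the rigid-core/floppy-tail fluctuation contrast of the system
being modelled.

Geometry: bond lengths N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, C=O
1.229 Å; angles N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°; ω fixed at
180°. Ideal torsions: α-helix (φ, ψ) = (-57°, -47°), 3₁₀ helix
(-49°, -26°), extended chain (180°, 180°).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .geometry import place_atom
from .trajectory_io import Topology, Trajectory

# backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.229
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 121.0

IDEAL_TORSIONS = {
    "alpha": (-57.0, -47.0),
    "three_ten": (-49.0, -26.0),
    "extended": (180.0, 180.0),
}

_SEQUENCES = {
    11: "INYWLAHAKAG",
    9: "INYWLAHAK",
    7: "INYWLAH",
}

_THREE_LETTER = {
    "A": "ALA", "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS",
    "L": "LEU", "N": "ASN", "W": "TRP", "Y": "TYR",
}

# Plausible CHARMM-style backbone nonbonded parameters (charge e, LJ well
# depth kcal/mol, rmin/2 Å) for the synthetic topology; enough to exercise
# the interaction-energy analyses, not a real force field.
_BACKBONE_PARAMS = {
    "N": (-0.47, 0.20, 1.85),
    "CA": (0.07, 0.02, 2.275),
    "C": (0.51, 0.11, 2.00),
    "O": (-0.51, 0.12, 1.70),
}


def internal_to_cartesian(
    bond_lengths: Sequence[float],
    bond_angles: Sequence[float],
    torsions: Sequence[float],
) -> np.ndarray:
    """Build an n-atom chain from internal coordinates (NeRF extension).

    ``bond_lengths`` has n-1 entries, ``bond_angles`` n-2 (degrees),
    ``torsions`` n-3 (degrees). The first three atoms are placed
    canonically: atom 0 at the origin, atom 1 on +x, atom 2 in the xy
    plane.
    """
    lengths = np.asarray(bond_lengths, dtype=float)
    angles = np.asarray(bond_angles, dtype=float)
    tors = np.asarray(torsions, dtype=float)
    n = len(lengths) + 1
    if len(angles) != n - 2 or len(tors) != n - 3:
        raise ValueError("inconsistent internal-coordinate array lengths")
    coords = np.zeros((n, 3))
    coords[1] = [lengths[0], 0.0, 0.0]
    if n > 2:
        theta = np.radians(angles[0])
        coords[2] = coords[1] + lengths[1] * np.array(
            [-np.cos(theta), np.sin(theta), 0.0]
        )
    for i in range(3, n):
        coords[i] = place_atom(
            coords[i - 3], coords[i - 2], coords[i - 1],
            lengths[i - 1], angles[i - 2], tors[i - 3],
        )
    return coords


def _backbone_topology(
    n_residues: int, with_nonbonded_params: bool = False
) -> Topology:
    seq = _SEQUENCES.get(n_residues, "A" * n_residues)
    names, resnums, resnames, elements = [], [], [], []
    charges, epsilons, rmins = [], [], []
    for r in range(1, n_residues + 1):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            names.append(name)
            resnums.append(r)
            resnames.append(_THREE_LETTER[seq[r - 1]])
            elements.append(element)
            q, eps, rmin = _BACKBONE_PARAMS[name]
            charges.append(q)
            epsilons.append(eps)
            rmins.append(rmin)
    return Topology(
        atom_names=np.array(names, dtype=object),
        residue_numbers=np.array(resnums),
        residue_names=np.array(resnames, dtype=object),
        elements=np.array(elements, dtype=object),
        charges=np.array(charges) if with_nonbonded_params else None,
        lj_epsilons=np.array(epsilons) if with_nonbonded_params else None,
        lj_rmin_halves=np.array(rmins) if with_nonbonded_params else None,
    )


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone coordinates (N, CA, C, O per residue) from torsion arrays.

    ``phi[0]`` is ignored (undefined for the first residue); ``psi[-1]``
    is used only to orient the final carbonyl oxygen.
    """
    n_res = len(phi)
    # main chain N-CA-C repeated, built atom by atom
    lengths, angles, tors = [], [], []
    for r in range(n_res):
        if r == 0:
            lengths += [BOND_N_CA, BOND_CA_C]
            angles += [ANGLE_N_CA_C]
        else:
            lengths += [BOND_C_N, BOND_N_CA, BOND_CA_C]
            angles += [ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_N_CA_C]
            tors += [psi[r - 1], 180.0, phi[r]]  # ψ(r-1), ω, φ(r)
    main = internal_to_cartesian(lengths, angles, tors)

    coords = np.zeros((4 * n_res, 3))
    for r in range(n_res):
        n_i, ca_i, c_i = 3 * r, 3 * r + 1, 3 * r + 2
        base = 4 * r
        coords[base] = main[n_i]
        coords[base + 1] = main[ca_i]
        coords[base + 2] = main[c_i]
        # carbonyl O anti to the following amide nitrogen
        coords[base + 3] = place_atom(
            main[n_i], main[ca_i], main[c_i],
            BOND_C_O, ANGLE_CA_C_O, psi[r] - 180.0,
        )
    return coords


def build_helix(n_residues: int, helix_type: str = "alpha") -> np.ndarray:
    """Ideal helical backbone (α or 3₁₀) as a (4*n_residues, 3) array."""
    if n_residues < 4:
        raise GenerationError("a helix needs at least 4 residues")
    if helix_type not in ("alpha", "three_ten"):
        raise ValueError(f"unknown helix_type {helix_type!r}")
    phi0, psi0 = IDEAL_TORSIONS[helix_type]
    phi = np.full(n_residues, phi0)
    psi = np.full(n_residues, psi0)
    return _build_backbone(phi, psi)


def build_extended(n_residues: int) -> np.ndarray:
    """Fully extended backbone (φ = ψ = 180°), the canonical unfolded start."""
    if n_residues < 2:
        raise GenerationError("an extended chain needs at least 2 residues")
    phi = np.full(n_residues, 180.0)
    psi = np.full(n_residues, 180.0)
    return _build_backbone(phi, psi)


def _nonbonded_pairs(n_residues: int) -> np.ndarray:
    """Index pairs with bonded-graph distance >= 3 (cached per size)."""
    if n_residues not in _nonbonded_pairs._cache:
        n_atoms = 4 * n_residues
        # adjacency of the backbone bond graph
        adj = np.zeros((n_atoms, n_atoms), dtype=bool)

        def bond(i, j):
            adj[i, j] = adj[j, i] = True

        for r in range(n_residues):
            base = 4 * r
            bond(base, base + 1)      # N-CA
            bond(base + 1, base + 2)  # CA-C
            bond(base + 2, base + 3)  # C=O
            if r + 1 < n_residues:
                bond(base + 2, base + 4)  # C-N(next)
        # exclude 1-2 and 1-3 neighbours (graph distance <= 2)
        near = (adj @ adj) | adj
        iu, ju = np.triu_indices(n_atoms, k=1)
        keep = ~near[iu, ju]
        _nonbonded_pairs._cache[n_residues] = (iu[keep], ju[keep])
    return _nonbonded_pairs._cache[n_residues]


_nonbonded_pairs._cache = {}


def _has_clash(coords: np.ndarray, n_residues: int, min_dist: float = 2.0) -> bool:
    iu, ju = _nonbonded_pairs(n_residues)
    d2 = ((coords[iu] - coords[ju]) ** 2).sum(axis=1)
    return bool(np.any(d2 < min_dist ** 2))


def build_coil(
    n_residues: int, rng: np.random.Generator, max_attempts: int = 100
) -> np.ndarray:
    """Random-coil backbone: torsions uniform outside ±30° of the eclipsed
    (0°) values, rebuilt until clash-free (no non-bonded pair < 2 Å)."""
    for _ in range(max_attempts):
        # uniform on (-180, -30] U [30, 180]
        phi = rng.uniform(30.0, 330.0, size=n_residues)
        psi = rng.uniform(30.0, 330.0, size=n_residues)
        phi = np.where(phi > 180.0, phi - 360.0, phi)
        psi = np.where(psi > 180.0, psi - 360.0, psi)
        coords = _build_backbone(phi, psi)
        if not _has_clash(coords, n_residues):
            return coords
    raise GenerationError(
        f"no clash-free coil found in {max_attempts} attempts for "
        f"{n_residues} residues"
    )


@dataclass
class TwoStateGeneratorConfig:
    """Conditions for the synthetic two-state trajectory.

    The Markov chain's transition probabilities are 1/mean_dwell out of
    each state; when ``mean_dwell_unfolded`` is None it is solved from the
    stationary condition π_folded = p_folded_target, otherwise the pair of
    dwells must already satisfy it (checked to 1e-9).
    """

    n_residues: int = 11
    p_folded_target: float = 0.80
    mean_dwell_folded: float = 200.0
    mean_dwell_unfolded: float | None = None
    jitter_sigma: float = 0.2
    helix_type: str = "alpha"
    mobile_tail_range: tuple[int, int] | None = (8, 11)
    tail_jitter_factor: float = 5.0
    frame_interval_ps: float = 0.8
    with_nonbonded_params: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_folded_target < 1.0:
            raise ValueError("p_folded_target must lie strictly in (0, 1)")
        if self.mean_dwell_folded < 1.0:
            raise ValueError("mean dwell times must be >= 1 frame")
        p = self.p_folded_target
        solved = self.mean_dwell_folded * (1.0 - p) / p
        if self.mean_dwell_unfolded is None:
            self.mean_dwell_unfolded = solved
        else:
            if self.mean_dwell_unfolded < 1.0:
                raise ValueError("mean dwell times must be >= 1 frame")
            stationary = self.mean_dwell_folded / (
                self.mean_dwell_folded + self.mean_dwell_unfolded
            )
            if abs(stationary - p) > 1e-9:
                raise ValueError(
                    f"dwell times imply stationary folded fraction "
                    f"{stationary:.6f}, target is {p}"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def sample_state_labels(
    config: TwoStateGeneratorConfig, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean folded/unfolded chain with the configured stationary law.

    The initial state is drawn from the stationary distribution so the
    chain is stationary from frame 0 (no burn-in needed).
    """
    stay_f = 1.0 - 1.0 / config.mean_dwell_folded
    stay_u = 1.0 - 1.0 / config.mean_dwell_unfolded
    u = rng.random(n_frames)
    folded = np.empty(n_frames, dtype=bool)
    folded[0] = u[0] < config.p_folded_target
    for t in range(1, n_frames):
        stay = stay_f if folded[t - 1] else stay_u
        folded[t] = folded[t - 1] if u[t] < stay else not folded[t - 1]
    return folded


def simulate_two_state(
    config: TwoStateGeneratorConfig, n_frames: int
) -> Trajectory:
    """Two-state trajectory with per-frame ground-truth labels.

    Folded frames are the ideal helix template plus isotropic Gaussian
    jitter (``jitter_sigma`` on the core, ``tail_jitter_factor`` times that
    on the mobile tail residues); unfolded frames are freshly sampled coil
    conformers with the core jitter. Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    topology = _backbone_topology(config.n_residues, config.with_nonbonded_params)
    template = build_helix(config.n_residues, config.helix_type)

    sigma = np.full((4 * config.n_residues, 1), config.jitter_sigma)
    if config.mobile_tail_range is not None:
        lo, hi = config.mobile_tail_range
        tail = (topology.residue_numbers >= lo) & (topology.residue_numbers <= hi)
        sigma[tail, 0] *= config.tail_jitter_factor

    folded = sample_state_labels(config, n_frames, rng)
    coords = np.empty((n_frames, 4 * config.n_residues, 3))
    fidx = np.nonzero(folded)[0]
    coords[fidx] = template + rng.normal(
        size=(len(fidx),) + template.shape
    ) * sigma
    for t in np.nonzero(~folded)[0]:
        coil = build_coil(config.n_residues, rng)
        coords[t] = coil + rng.normal(size=coil.shape) * config.jitter_sigma
    labels = np.where(folded, "folded", "unfolded").astype(object)
    return Trajectory(
        topology=topology,
        coordinates=coords,
        frame_interval_ps=config.frame_interval_ps,
        labels=labels,
    )
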