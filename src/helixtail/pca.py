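"""Cartesian and dihedral principal component analysis.

Cartesian PCA diagonalizes the covariance of the flattened (3n) selection
coordinates of an aligned trajectory. Dihedral PCA first maps every torsion
θ to (cos θ, sin θ) to remove angular periodicity and then runs the same
eigendecomposition on the 2m embedded variables. Projections of a
trajectory onto the first two components, histogrammed and log-transformed,
give the free-energy landscapes; the split-half eigenspace overlap serves
as the sampling-convergence diagnostic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import rt_kj
from .errors import DegenerateGeometryError, SelectionError
from .geometry import dihedral
from .trajectory_io import SelectionSpec, Trajectory, resolve_selection


@dataclass(frozen=True)
class PCAModel:
    """Eigendecomposition of a coordinate or embedded-dihedral covariance.

    Eigenvectors are orthonormal columns ordered by descending eigenvalue;
    each eigenvector's sign is fixed so its largest-magnitude element is
    positive, making projections reproducible across runs.
    """

    space_kind: str  # "cartesian" | "dihedral"
    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fraction: np.ndarray

    @property
    def n_dim(self) -> int:
        return len(self.mean)


def _fit_pca(data: np.ndarray, space_kind: str) -> PCAModel:
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("PCA needs a (frames >= 2, variables) matrix")
    mean = data.mean(axis=0)
    cov = np.cov(data, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude element of each column positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAModel(
        space_kind=space_kind,
        mean=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        variance_fraction=frac,
    )


def cartesian_pca(
    aligned_trajectory: Trajectory, selection: SelectionSpec
) -> PCAModel:
    """PCA of the flattened selection coordinates of an aligned trajectory."""
    idx = resolve_selection(aligned_trajectory.topology, selection)
    data = aligned_trajectory.coordinates[:, idx, :].reshape(
        aligned_trajectory.n_frames, -1
    )
    return _fit_pca(data, "cartesian")


def embed_dihedrals(angles_deg: np.ndarray) -> np.ndarray:
    """Map (frames, m) angles in degrees to (frames, 2m) cos/sin pairs.

    Column order is (cos θ1, sin θ1, cos θ2, sin θ2, ...).
    """
    angles = np.radians(np.asarray(angles_deg, dtype=float))
    if not np.all(np.isfinite(angles)):
        raise ValueError("dihedral series contains non-finite angles")
    out = np.empty((angles.shape[0], 2 * angles.shape[1]))
    out[:, 0::2] = np.cos(angles)
    out[:, 1::2] = np.sin(angles)
    return out


def dihedral_pca(dihedral_series_deg: np.ndarray) -> PCAModel:
    """PCA of the circular (cos, sin) embedding of a torsion-angle series."""
    return _fit_pca(embed_dihedrals(dihedral_series_deg), "dihedral")


def project(model: PCAModel, data: np.ndarray) -> np.ndarray:
    """Component scores (data - mean) @ eigenvectors.

    ``data`` must already live in the model's space: flattened aligned
    coordinates for Cartesian models, embedded cos/sin pairs for dihedral
    models.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != model.n_dim:
        raise ValueError(
            f"data has {data.shape[1]} variables, model expects {model.n_dim}"
        )
    return (data - model.mean) @ model.eigenvectors


def backbone_dihedrals(
    trajectory: Trajectory, residue_range: tuple[int, int]
) -> np.ndarray:
    """φ/ψ torsions (degrees) of a residue range for every frame.

    For residues first..last the defined torsions are φ for residues
    first+1..last and ψ for residues first..last-1 (the terminal φ/ψ need
    atoms outside the range), i.e. 2k-2 angles for k residues — 12 for a
    seven-residue window. Columns are ordered all φ (by residue) then all
    ψ (by residue).
    """
    first, last = residue_range
    top = trajectory.topology

    def atom(res: int, name: str) -> int:
        hit = np.nonzero(
            (top.residue_numbers == res) & (top.atom_names.astype(str) == name)
        )[0]
        if hit.size == 0:
            raise SelectionError(f"missing backbone atom {name} of residue {res}")
        return int(hit[0])

    coords = trajectory.coordinates
    columns = []
    # φ(r) = C(r-1)-N(r)-CA(r)-C(r) for r in first+1..last
    for r in range(first + 1, last + 1):
        quad = [atom(r - 1, "C"), atom(r, "N"), atom(r, "CA"), atom(r, "C")]
        columns.append(
            dihedral(coords[:, quad[0]], coords[:, quad[1]],
                     coords[:, quad[2]], coords[:, quad[3]])
        )
    # ψ(r) = N(r)-CA(r)-C(r)-N(r+1) for r in first..last-1
    for r in range(first, last):
        quad = [atom(r, "N"), atom(r, "CA"), atom(r, "C"), atom(r + 1, "N")]
        columns.append(
            dihedral(coords[:, quad[0]], coords[:, quad[1]],
                     coords[:, quad[2]], coords[:, quad[3]])
        )
    if not columns:
        raise SelectionError("residue range defines no torsions")
    return np.column_stack(columns)


def subspace_overlap(model_a: PCAModel, model_b: PCAModel, k: int) -> float:
    """Root-mean-square inner-product overlap of the top-k eigenspaces.

    overlap = (1/k) Σ_i Σ_j (a_i · b_j)^2 over the top-k eigenvectors of
    each model; 1 for identical spans, 0 for mutually orthogonal ones, and
    invariant to eigenvector sign and to ordering within the subspaces.
    """
    if model_a.n_dim != model_b.n_dim or model_a.space_kind != model_b.space_kind:
        raise ValueError("models live in different spaces")
    if not 1 <= k <= model_a.n_dim:
        raise ValueError(f"k={k} out of range for dimension {model_a.n_dim}")
    a = model_a.eigenvectors[:, :k]
    b = model_b.eigenvectors[:, :k]
    return float(np.sum((a.T @ b) ** 2) / k)


def split_half_convergence(
    data: np.ndarray,
    k: int,
    space_kind: str = "cartesian",
    burn_in: int = 0,
) -> tuple[float, np.ndarray]:
    """Eigenspace overlap between PCAs of two non-overlapping trajectory halves.

    ``data`` is the (frames, variables) matrix in the target space —
    flattened aligned coordinates or raw dihedral angles in degrees (the
    circular embedding is applied here for ``space_kind="dihedral"``).
    After discarding ``burn_in`` frames the remainder is split in half and
    a PCA fit on each. Returns (overlap at k, overlap curve for 1..k).
    """
    data = np.asarray(data, dtype=float)
    usable = data[burn_in:]
    half = len(usable) // 2
    if half < max(2, data.shape[1] // 3):
        raise ValueError("trajectory too short to split after burn-in")
    if space_kind == "dihedral":
        fit = dihedral_pca
    elif space_kind == "cartesian":
        def fit(x):
            return _fit_pca(x, "cartesian")
    else:
        raise ValueError(f"unknown space_kind {space_kind!r}")
    model_a = fit(usable[:half])
    model_b = fit(usable[half : 2 * half])
    curve = np.array(
        [subspace_overlap(model_a, model_b, kk) for kk in range(1, k + 1)]
    )
    return float(curve[-1]), curve


@dataclass(frozen=True)
class FreeEnergyLandscape:
    """2D free-energy surface over the first two principal components.

    F(bin) = -RT ln(n_bin / n_max) in kJ/mol, so the most occupied bin is
    exactly 0 and unoccupied bins are NaN (flagged by ``occupied``). Raw
    counts are kept so any other reference state can be recomputed.
    """

    edges_x: np.ndarray
    edges_y: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def free_energy_landscape(
    scores_2d: np.ndarray,
    bins: int = 100,
    temperature: float = 320.0,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
    pad_fraction: float = 0.05,
) -> FreeEnergyLandscape:
    """Histogram PC1/PC2 scores and convert occupancy to free energy.

    By default the grid covers the data range padded by 5% on each side;
    pass explicit ``edges`` to bin several trajectories on a common grid.
    """
    scores = np.asarray(scores_2d, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2 or scores.shape[0] == 0:
        raise ValueError("need a non-empty (frames, >=2) score matrix")
    x, y = scores[:, 0], scores[:, 1]
    if edges is None:
        def padded(v):
            lo, hi = v.min(), v.max()
            span = (hi - lo) or 1.0
            return np.linspace(lo - pad_fraction * span, hi + pad_fraction * span,
                               bins + 1)
        edges = (padded(x), padded(y))
    counts, ex, ey = np.histogram2d(x, y, bins=edges)
    counts = counts.astype(int)
    n_max = counts.max()
    if n_max == 0:
        raise ValueError("no occupied bins")
    with np.errstate(divide="ignore"):
        f = -rt_kj(temperature) * np.log(counts / n_max)
    f[counts == 0] = np.nan
    return FreeEnergyLandscape(
        edges_x=ex, edges_y=ey, counts=counts, free_energy=f,
        temperature=temperature,
    )


def basin_from_landscape(
    landscape: FreeEnergyLandscape, depth_kj: float | None = None
) -> np.ndarray:
    """Boolean bin mask of the main basin: occupied bins within ``depth_kj``
    of the landscape minimum (default 2 RT)."""
    if depth_kj is None:
        depth_kj = 2.0 * rt_kj(landscape.temperature)
    with np.errstate(invalid="ignore"):
        mask = landscape.free_energy <= depth_kj
    return np.nan_to_num(mask, nan=False).astype(bool) & landscape.occupied


def basin_delta_delta_g(
    landscape_a: FreeEnergyLandscape,
    landscape_b: FreeEnergyLandscape,
    basin_mask: np.ndarray,
    temperature: float,
) -> float:
    """ΔΔG = ΔG_B - ΔG_A from basin occupation on a common grid (kJ/mol).

    For each landscape ΔG = -RT ln(p_basin / (1 - p_basin)) with p_basin
    the fraction of frames falling inside the basin bins.
    """
    from .two_state import delta_g  # local import to avoid a cycle

    if not (
        np.array_equal(landscape_a.edges_x, landscape_b.edges_x)
        and np.array_equal(landscape_a.edges_y, landscape_b.edges_y)
    ):
        raise ValueError("landscapes are not binned on a common grid")
    basin_mask = np.asarray(basin_mask, dtype=bool)
    if basin_mask.shape != landscape_a.counts.shape:
        raise ValueError("basin mask shape does not match the landscape grid")
    in_a = landscape_a.counts[basin_mask].sum()
    in_b = landscape_b.counts[basin_mask].sum()
    if in_a == 0 and in_b == 0:
        raise ValueError("basin is empty in both landscapes")
    p_a = in_a / landscape_a.counts.sum()
    p_b = in_b / landscape_b.counts.sum()
    return delta_g(p_b, temperature) - delta_g(p_a, temperature)
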