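"""Least-squares superposition (Kabsch) and RMSD/RMSF machinery.

The fit minimizes the coordinate RMSD over proper rotations after centroid
alignment; reflections are excluded by the usual sign correction on the
smallest singular value. All pairwise RMSDs are *fitted* RMSDs (each pair
superposed independently).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError
from .trajectory_io import SelectionSpec, Trajectory, resolve_selection


@dataclass(frozen=True)
class FitResult:
    """Optimal rigid-body transform mapping mobile onto reference.

    The transform is ``x -> rotation @ (x - mobile_centroid) + reference_centroid``;
    ``translation`` is the net offset so that ``x -> rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_fit_input(mobile: np.ndarray, reference: np.ndarray) -> None:
    if mobile.shape != reference.shape:
        raise DegenerateFitError(
            f"shape mismatch: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 points of shape (n, 3)")
    centered = mobile - mobile.mean(axis=0)
    # collinear point sets leave a free rotation about the common axis
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("points are collinear; rotation is underdetermined")
    centered_ref = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(centered_ref, tol=1e-8) < 2:
        raise DegenerateFitError("reference points are collinear")


def _kabsch_batch(mobile: np.ndarray, reference: np.ndarray):
    """Vectorized Kabsch over a stack of mobile structures.

    mobile: (F, n, 3), reference: (n, 3). Returns rotations (F, 3, 3),
    mobile centroids (F, 3), reference centroid (3,), rmsds (F,).
    """
    mob_c = mobile.mean(axis=1)
    ref_c = reference.mean(axis=0)
    m = mobile - mob_c[:, None, :]
    r = reference - ref_c
    h = np.einsum("fni,nj->fij", m, r)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", u, vt))
    sign = np.ones((len(mobile), 3))
    sign[:, 2] = np.sign(det)
    # R = V diag(1,1,det) U^T; R[i,k] = sum_j V[i,j] d_j U[k,j]
    rot = np.einsum("fji,fj,fkj->fik", vt, sign, u)
    # residual-based rmsd: the singular-value formula loses precision near 0
    rotated = np.einsum("fni,fki->fnk", m, rot)
    msd = ((rotated - r) ** 2).sum(axis=2).mean(axis=1)
    return rot, mob_c, ref_c, np.sqrt(msd)


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> FitResult:
    """Optimal proper-rotation superposition of two (n, 3) point sets."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    _check_fit_input(mobile, reference)
    rot, mob_c, ref_c, rmsd = _kabsch_batch(mobile[None], reference)
    rotation = rot[0]
    translation = ref_c - rotation @ mob_c[0]
    return FitResult(rotation=rotation, translation=translation, rmsd=float(rmsd[0]))


def align_trajectory(
    trajectory: Trajectory,
    reference: np.ndarray,
    selection: SelectionSpec,
) -> Trajectory:
    """Superpose every frame onto a reference using only the selection atoms.

    ``reference`` is a full-topology (n_atoms, 3) structure; the fit is
    computed on the selection and the resulting rigid transform applied to
    all atoms of the frame.
    """
    idx = resolve_selection(trajectory.topology, selection)
    reference = np.asarray(reference, dtype=float)
    _check_fit_input(trajectory.coordinates[0][idx], reference[idx])
    rot, mob_c, ref_c, _ = _kabsch_batch(
        trajectory.coordinates[:, idx, :], reference[idx]
    )
    centered = trajectory.coordinates - mob_c[:, None, :]
    aligned = np.einsum("fni,fki->fnk", centered, rot) + ref_c
    return trajectory.with_coordinates(aligned)


def rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray,
    selection: SelectionSpec,
) -> np.ndarray:
    """Per-frame fitted RMSD (Å) of the selection atoms vs a reference structure.

    ``reference`` may be a full-topology structure or already restricted to
    the selection atoms.
    """
    idx = resolve_selection(trajectory.topology, selection)
    reference = np.asarray(reference, dtype=float)
    ref_sel = reference[idx] if reference.shape[0] == trajectory.n_atoms else reference
    _check_fit_input(trajectory.coordinates[0][idx], ref_sel)
    _, _, _, rmsds = _kabsch_batch(trajectory.coordinates[:, idx, :], ref_sel)
    return rmsds


def rmsd_matrix(
    trajectory: Trajectory, selection: SelectionSpec, stride: int = 1
) -> np.ndarray:
    """Symmetric frame-to-frame fitted RMSD matrix (Å), optionally strided."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = resolve_selection(trajectory.topology, selection)
    coords = trajectory.coordinates[::stride, idx, :]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n - 1):
        _, _, _, r = _kabsch_batch(coords[i + 1 :], coords[i])
        mat[i, i + 1 :] = r
        mat[i + 1 :, i] = r
    return mat


def average_structure(
    trajectory: Trajectory,
    selection: SelectionSpec,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[np.ndarray, bool, int]:
    """Iterative mean structure after removal of rotations/translations.

    Alternates between aligning every frame (on the selection) to the
    current average and recomputing the all-atom coordinate mean, until the
    average moves by less than ``tol`` Å RMSD. Returns (average coordinates
    for all atoms, converged flag, iterations used).
    """
    if trajectory.n_frames < 2:
        raise DegenerateFitError("average structure needs at least 2 frames")
    idx = resolve_selection(trajectory.topology, selection)
    avg = trajectory.coordinates[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = align_trajectory(trajectory, avg, selection)
        new_avg = aligned.coordinates.mean(axis=0)
        shift = np.sqrt(((new_avg[idx] - avg[idx]) ** 2).sum(axis=1).mean())
        avg = new_avg
        if shift < tol:
            converged = True
            break
    return avg, converged, iterations


def rmsf(aligned_trajectory: Trajectory, selection: SelectionSpec) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the mean position.

    The trajectory must already be superposed; no fitting is done here.
    """
    if aligned_trajectory.n_frames < 2:
        raise DegenerateFitError("rmsf needs at least 2 frames")
    idx = resolve_selection(aligned_trajectory.topology, selection)
    coords = aligned_trajectory.coordinates[:, idx, :]
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def representative_structure(
    trajectory: Trajectory,
    selection: SelectionSpec,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[int, float]:
    """Frame with the smallest fitted RMSD to the iterative average structure.

    Ties are broken toward the earliest frame. Returns (frame index,
    RMSD to the average in Å).
    """
    avg, _converged, _ = average_structure(trajectory, selection, tol, max_iter)
    series = rmsd_series(trajectory, avg, selection)
    frame = int(np.argmin(series))  # argmin returns the first minimum
    return frame, float(series[frame])
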