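"""Principal component analyses, convergence diagnostics, and free-energy
landscapes.

Cartesian PCA runs on the aligned Cα coordinates of residues 1-7; dihedral
PCA on the cos/sin-embedded twelve φ/ψ torsions of the same window.
Split-half eigenspace overlaps (top 3 Cartesian / top 6 dihedral
eigenvectors) diagnose sampling convergence; the projection of each run on
its first two dihedral PCs, histogrammed and log-transformed, gives the
free-energy landscapes exported as TSV grids.
"""
import numpy as np

from _common import RESULTS_DIR, RUNS, ensure_generated, load_run
from helixtail.export import landscape_to_tsv, series_to_tsv
from helixtail.pca import (
    backbone_dihedrals,
    cartesian_pca,
    dihedral_pca,
    embed_dihedrals,
    free_energy_landscape,
    project,
    split_half_convergence,
)
from helixtail.superposition import align_trajectory, representative_structure
from helixtail.trajectory_io import SelectionSpec, resolve_selection

TEMPERATURE = 320.0


def main() -> None:
    ensure_generated()
    out = RESULTS_DIR / "pca"
    out.mkdir(parents=True, exist_ok=True)

    for name in RUNS:
        trajectory = load_run(name)
        n_res = trajectory.topology.n_residues
        sel = SelectionSpec(["CA"], (1, min(7, n_res)))

        frame, _ = representative_structure(trajectory, sel)
        aligned = align_trajectory(trajectory, trajectory.coordinates[frame], sel)
        idx = resolve_selection(trajectory.topology, sel)
        flat = aligned.coordinates[:, idx, :].reshape(trajectory.n_frames, -1)
        cmodel = cartesian_pca(aligned, sel)
        c_overlap, _ = split_half_convergence(flat, k=3, space_kind="cartesian")

        angles = backbone_dihedrals(trajectory, (1, min(7, n_res)))
        dmodel = dihedral_pca(angles)
        d_overlap, _ = split_half_convergence(angles, k=6, space_kind="dihedral")
        scores = project(dmodel, embed_dihedrals(angles))[:, :2]
        landscape = free_energy_landscape(scores, 100, TEMPERATURE)
        landscape_to_tsv(landscape, out / f"dpca_landscape_{name}.tsv")
        series_to_tsv(scores[:, 0], out / f"dpca_pc1_{name}.tsv", "pc1")

        print(
            f"{name:>9}: cartesian PC1-3 variance "
            f"{cmodel.variance_fraction[:3].sum():.2f}, "
            f"split-half overlap (k=3) {c_overlap:.3f} | "
            f"dihedral PC1-2 variance {dmodel.variance_fraction[:2].sum():.2f}, "
            f"split-half overlap (k=6) {d_overlap:.3f}, "
            f"landscape occupies {int(landscape.occupied.sum())} bins"
        )


if __name__ == "__main__":
    main()
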