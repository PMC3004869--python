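import numpy as np
import pytest

from helixtail.constants import rt_kj
from helixtail.errors import DegenerateGeometryError
from helixtail.pca import (
    PCAModel,
    backbone_dihedrals,
    basin_delta_delta_g,
    cartesian_pca,
    dihedral_pca,
    embed_dihedrals,
    free_energy_landscape,
    project,
    split_half_convergence,
    subspace_overlap,
    _fit_pca,
)
from helixtail.trajectory_io import SelectionSpec, Trajectory


def brute_force_pca(data):
    """Independent small-d oracle: explicit covariance double loop + dense
    eigensolver (np.linalg.eig, not eigh)."""
    n, d = data.shape
    mean = data.mean(axis=0)
    cov = np.zeros((d, d))
    for x in data:
        y = x - mean
        for i in range(d):
            for j in range(d):
                cov[i, j] += y[i] * y[j]
    cov /= n - 1
    evals, evecs = np.linalg.eig(cov)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


class TestCartesianPca:
    def test_line_segment_is_rank_one(self, topology_11, helix_11):
        direction = np.zeros_like(helix_11)
        direction[5] = [1.0, 2.0, -1.0]
        coords = helix_11[None] + np.linspace(0, 1, 50)[:, None, None] * direction
        model = cartesian_pca(
            Trajectory(topology_11, coords), SelectionSpec(["CA"], (1, 11))
        )
        assert model.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalue_sum_conserves_variance(self, jittered_helix_trajectory, ca_core):
        from helixtail.trajectory_io import resolve_selection

        model = cartesian_pca(jittered_helix_trajectory, ca_core)
        idx = resolve_selection(jittered_helix_trajectory.topology, ca_core)
        data = jittered_helix_trajectory.coordinates[:, idx, :].reshape(200, -1)
        total = data.var(axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        data = rng.normal(size=(20, 12))  # 4 atoms x 3
        model = _fit_pca(data, "cartesian")
        evals, evecs = brute_force_pca(data)
        assert np.allclose(model.eigenvalues, evals, atol=1e-9)
        # eigenvectors agree up to sign
        for k in range(12):
            dot = abs(model.eigenvectors[:, k] @ evecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_orthonormal_eigenvectors(self, jittered_helix_trajectory, ca_core):
        model = cartesian_pca(jittered_helix_trajectory, ca_core)
        gram = model.eigenvectors.T @ model.eigenvectors
        assert np.allclose(gram, np.eye(model.n_dim), atol=1e-8)


class TestDihedralPca:
    def test_constant_angles_zero_variance(self):
        angles = np.full((100, 5), 42.0)
        model = dihedral_pca(angles)
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_uniform_circle_gives_half_half(self):
        r = np.random.default_rng(2)
        angles = r.uniform(-180, 180, size=(100_000, 1))
        model = dihedral_pca(angles)
        assert model.eigenvalues[0] == pytest.approx(0.5, rel=0.02)
        assert model.eigenvalues[1] == pytest.approx(0.5, rel=0.02)

    def test_embedding_convention(self):
        out = embed_dihedrals(np.array([[0.0, 90.0]]))
        assert np.allclose(out, [[1.0, 0.0, 0.0, 1.0]], atol=1e-12)

    def test_noiseless_helix_has_zero_variance(self, helix_trajectory):
        angles = backbone_dihedrals(helix_trajectory, (1, 7))
        model = dihedral_pca(angles)
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-12)


class TestBackboneDihedrals:
    def test_seven_residue_window_yields_twelve_angles(self, helix_trajectory):
        angles = backbone_dihedrals(helix_trajectory, (1, 7))
        assert angles.shape == (3, 12)

    def test_ideal_helix_angles(self, helix_trajectory):
        angles = backbone_dihedrals(helix_trajectory, (1, 11))
        phis, psis = angles[0, :10], angles[0, 10:]
        assert np.allclose(phis, -57.0, atol=1.0)
        assert np.allclose(psis, -47.0, atol=1.0)

    def test_collinear_backbone_raises(self, topology_11):
        coords = np.zeros((1, 44, 3))
        coords[0, :, 0] = np.arange(44.0)  # all atoms on the x axis
        with pytest.raises(DegenerateGeometryError):
            backbone_dihedrals(Trajectory(topology_11, coords), (1, 7))


class TestProject:
    def test_mean_projects_to_zero(self, jittered_helix_trajectory, ca_core):
        model = cartesian_pca(jittered_helix_trajectory, ca_core)
        assert np.allclose(project(model, model.mean), 0.0, atol=1e-9)

    def test_full_reconstruction_identity(self, jittered_helix_trajectory, ca_core):
        from helixtail.trajectory_io import resolve_selection

        model = cartesian_pca(jittered_helix_trajectory, ca_core)
        idx = resolve_selection(jittered_helix_trajectory.topology, ca_core)
        data = jittered_helix_trajectory.coordinates[:, idx, :].reshape(200, -1)
        scores = project(model, data)
        recon = scores @ model.eigenvectors.T + model.mean
        assert np.allclose(recon, data, atol=1e-9)

    def test_score_variance_equals_eigenvalue(self, jittered_helix_trajectory, ca_core):
        from helixtail.trajectory_io import resolve_selection

        model = cartesian_pca(jittered_helix_trajectory, ca_core)
        idx = resolve_selection(jittered_helix_trajectory.topology, ca_core)
        data = jittered_helix_trajectory.coordinates[:, idx, :].reshape(200, -1)
        scores = project(model, data)
        assert np.allclose(
            scores.var(axis=0, ddof=1)[:5], model.eigenvalues[:5], rtol=1e-9
        )


def _model_from_vectors(columns):
    d = columns.shape[0]
    k = columns.shape[1]
    vecs = np.linalg.qr(np.hstack([columns, np.eye(d)]))[0][:, :d]
    vecs[:, :k] = columns
    evals = np.linspace(1.0, 0.1, d)
    return PCAModel("cartesian", np.zeros(d), evals, vecs, evals / evals.sum())


class TestSubspaceOverlap:
    def test_identical_sets(self):
        v = np.eye(4)[:, :2]
        m = _model_from_vectors(v)
        assert subspace_overlap(m, m, 2) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_sets(self):
        a = _model_from_vectors(np.eye(4)[:, :2])
        b = _model_from_vectors(np.eye(4)[:, 2:4])
        assert subspace_overlap(a, b, 2) == pytest.approx(0.0, abs=1e-12)

    def test_45_degrees_is_half(self):
        a = _model_from_vectors(np.array([[1.0], [0.0], [0.0], [0.0]]))
        c = np.sqrt(0.5)
        b = _model_from_vectors(np.array([[c], [c], [0.0], [0.0]]))
        assert subspace_overlap(a, b, 1) == pytest.approx(0.5, abs=1e-12)

    def test_sign_and_argument_symmetry(self, rng):
        x = rng.normal(size=(200, 6))
        y = x + rng.normal(scale=0.3, size=x.shape)
        ma, mb = _fit_pca(x, "cartesian"), _fit_pca(y, "cartesian")
        flipped = PCAModel(
            mb.space_kind, mb.mean, mb.eigenvalues, -mb.eigenvectors,
            mb.variance_fraction,
        )
        assert subspace_overlap(ma, mb, 3) == pytest.approx(
            subspace_overlap(mb, ma, 3), abs=1e-12
        )
        assert subspace_overlap(ma, flipped, 3) == pytest.approx(
            subspace_overlap(ma, mb, 3), abs=1e-12
        )


class TestSplitHalfConvergence:
    def test_overlap_grows_with_sampling(self):
        """For a stationary anisotropic source the two halves agree better
        the longer the trajectory."""
        r = np.random.default_rng(8)
        scales = np.array([3.0, 2.0, 1.5, 1.0, 0.5, 0.25])
        overlaps = []
        for n in (60, 600, 6000):
            data = r.normal(size=(n, 6)) * scales
            overlap, _ = split_half_convergence(data, k=3)
            overlaps.append(overlap)
        assert overlaps[0] < overlaps[-1]
        assert overlaps[-1] > 0.99

    def test_orthogonal_halves_overlap_zero(self):
        """Halves constructed to explore orthogonal coordinate subspaces."""
        r = np.random.default_rng(4)
        n = 400
        first = np.zeros((n, 6))
        second = np.zeros((n, 6))
        first[:, :3] = r.normal(size=(n, 3)) * [3.0, 2.0, 1.0]
        second[:, 3:] = r.normal(size=(n, 3)) * [3.0, 2.0, 1.0]
        overlap, curve = split_half_convergence(np.vstack([first, second]), k=3)
        assert overlap < 0.05
        assert len(curve) == 3

    def test_burn_in_is_discarded(self):
        r = np.random.default_rng(1)
        stationary = r.normal(size=(1000, 4)) * [3.0, 2.0, 1.0, 0.5]
        transient = np.full((100, 4), 50.0)
        data = np.vstack([transient, stationary])
        overlap, _ = split_half_convergence(data, k=2, burn_in=100)
        assert overlap > 0.9


class TestFreeEnergyLandscape:
    def test_single_occupied_bin(self):
        scores = np.zeros((50, 2))
        land = free_energy_landscape(scores, bins=10, temperature=320.0)
        assert land.occupied.sum() == 1
        assert np.nanmin(land.free_energy) == 0.0

    def test_count_ratio_e_gives_rt(self):
        rt = rt_kj(320.0)
        # two bins with counts n and round(n/e): free-energy gap of ~RT
        n1, n2 = 1000, int(round(1000 / np.e))
        scores = np.vstack(
            [np.tile([0.25, 0.25], (n1, 1)), np.tile([0.75, 0.75], (n2, 1))]
        )
        land = free_energy_landscape(
            scores, temperature=320.0,
            edges=(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0])),
        )
        df = land.free_energy[1, 1] - land.free_energy[0, 0]
        expected = -rt * np.log(n2 / n1)
        assert df == pytest.approx(expected, abs=1e-9)

    def test_minimum_is_zero_and_unoccupied_nan(self, rng):
        scores = rng.normal(size=(1000, 2))
        land = free_energy_landscape(scores, bins=20, temperature=300.0)
        assert np.nanmin(land.free_energy) == 0.0
        assert np.all(np.isnan(land.free_energy[~land.occupied]))
        assert land.counts.sum() <= 1000


class TestBasinDeltaDeltaG:
    @staticmethod
    def _landscape_with_basin_fraction(p, n, edges, temperature=320.0):
        n_in = int(round(n * p))
        scores = np.vstack(
            [
                np.tile([0.25, 0.25], (n_in, 1)),
                np.tile([0.75, 0.75], (n - n_in, 1)),
            ]
        )
        return free_energy_landscape(scores, temperature=temperature, edges=edges)

    def test_worked_populations(self):
        """Basin occupancies 0.80 vs 0.15 at 320 K give the +8.3 kJ/mol
        destabilization, same arithmetic as the RMSD route."""
        edges = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        a = self._landscape_with_basin_fraction(0.80, 10_000, edges)
        b = self._landscape_with_basin_fraction(0.15, 10_000, edges)
        basin = np.zeros((2, 2), dtype=bool)
        basin[0, 0] = True
        ddg = basin_delta_delta_g(a, b, basin, 320.0)
        assert ddg == pytest.approx(8.3, abs=0.05)

    def test_identical_landscapes_give_zero_and_swap_flips_sign(self):
        edges = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        a = self._landscape_with_basin_fraction(0.80, 1000, edges)
        b = self._landscape_with_basin_fraction(0.30, 1000, edges)
        basin = np.zeros((2, 2), dtype=bool)
        basin[0, 0] = True
        assert basin_delta_delta_g(a, a, basin, 320.0) == pytest.approx(0.0)
        assert basin_delta_delta_g(a, b, basin, 320.0) == pytest.approx(
            -basin_delta_delta_g(b, a, basin, 320.0)
        )
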