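import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from helixtail.errors import DegenerateFitError
from helixtail.superposition import (
    align_trajectory,
    average_structure,
    kabsch_fit,
    representative_structure,
    rmsd_matrix,
    rmsd_series,
    rmsf,
)
from helixtail.trajectory_io import SelectionSpec, Trajectory


def grid_search_min_rmsd(mobile, reference, coarse_step_deg=10.0):
    """Independent oracle: best RMSD over rotations by Euler-grid search
    plus local refinement, after centroid alignment."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def rmsd_of(euler):
        rot = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
        return np.sqrt(((m @ rot.T - r) ** 2).sum() / len(m))

    grid = np.arange(0.0, 360.0, coarse_step_deg)
    grid_beta = np.arange(0.0, 180.0 + coarse_step_deg, coarse_step_deg)
    best, best_val = None, np.inf
    for a in grid:
        for b in grid_beta:
            for c in grid:
                v = rmsd_of((a, b, c))
                if v < best_val:
                    best, best_val = (a, b, c), v
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return min(best_val, res.fun)


class TestKabschFit:
    def test_identity_on_self(self, rng):
        pts = rng.normal(size=(6, 3))
        fit = kabsch_fit(pts, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self, rng):
        ref = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([3.0, -1.0, 2.0])
        fit = kabsch_fit(mobile, ref)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.apply(mobile), ref, atol=1e-9)

    def test_rotation_is_proper(self, rng):
        for _ in range(5):
            a, b = rng.normal(size=(2, 5, 3))
            fit = kabsch_fit(a, b)
            assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(fit.rotation @ fit.rotation.T, np.eye(3), atol=1e-9)

    def test_matches_rotation_grid_oracle(self, rng):
        """Kabsch minimum equals brute-force rotation search on 20 instances."""
        for _ in range(20):
            ref = rng.normal(size=(5, 3))
            mobile = ref + rng.normal(scale=0.5, size=ref.shape)
            fit = kabsch_fit(mobile, ref)
            oracle = grid_search_min_rmsd(mobile, ref)
            assert fit.rmsd == pytest.approx(oracle, abs=1e-4)
            assert fit.rmsd <= oracle + 1e-9  # never worse than the search

    @pytest.mark.parametrize(
        "mobile",
        [
            np.zeros((2, 3)),  # too few points
            np.outer(np.arange(5.0), [1.0, 0.0, 0.0]),  # collinear
        ],
    )
    def test_degenerate_inputs(self, mobile):
        with pytest.raises(DegenerateFitError):
            kabsch_fit(mobile, mobile + 1.0)


class TestAlignTrajectory:
    def test_rigid_copies_collapse(self, helix_11, topology_11, ca_core, rng):
        frames = []
        for _ in range(10):
            rot = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            frames.append(helix_11 @ rot.T + rng.normal(scale=5.0, size=3))
        traj = Trajectory(topology_11, np.array(frames))
        aligned = align_trajectory(traj, helix_11, ca_core)
        for frame in aligned.coordinates:
            assert np.allclose(frame, helix_11, atol=1e-6)

    def test_idempotent(self, jittered_helix_trajectory, helix_11, ca_core):
        once = align_trajectory(jittered_helix_trajectory, helix_11, ca_core)
        twice = align_trajectory(once, helix_11, ca_core)
        assert np.allclose(once.coordinates, twice.coordinates, atol=1e-9)

    def test_alignment_never_increases_selection_rmsd(
        self, topology_11, helix_11, ca_core, rng
    ):
        from helixtail.trajectory_io import resolve_selection

        idx = resolve_selection(topology_11, ca_core)
        coords = helix_11[None] + rng.normal(scale=1.0, size=(100, *helix_11.shape))
        traj = Trajectory(topology_11, coords)
        aligned = align_trajectory(traj, helix_11, ca_core)
        before = np.sqrt(
            ((coords[:, idx] - helix_11[idx]) ** 2).sum(axis=2).mean(axis=1)
        )
        after = np.sqrt(
            ((aligned.coordinates[:, idx] - helix_11[idx]) ** 2)
            .sum(axis=2)
            .mean(axis=1)
        )
        assert np.all(after <= before + 1e-9)


class TestRmsdSeries:
    def test_zero_against_own_frame(self, jittered_helix_trajectory, ca_core):
        ref = jittered_helix_trajectory.coordinates[0]
        series = rmsd_series(jittered_helix_trajectory, ref, ca_core)
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_global_rigid_motion(
        self, jittered_helix_trajectory, helix_11, ca_core
    ):
        rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        moved = jittered_helix_trajectory.with_coordinates(
            jittered_helix_trajectory.coordinates @ rot.T + np.array([5.0, 0.0, -2.0])
        )
        a = rmsd_series(jittered_helix_trajectory, helix_11, ca_core)
        b = rmsd_series(moved, helix_11, ca_core)
        assert np.allclose(a, b, atol=1e-9)

    def test_separates_generator_states(self, two_state_trajectory, ca_core):
        from helixtail.generate import build_helix

        series = rmsd_series(two_state_trajectory, build_helix(11), ca_core)
        folded = two_state_trajectory.labels == "folded"
        assert series[folded].mean() < series[~folded].mean()


class TestRmsdMatrix:
    def test_matches_pairwise_double_loop(self, two_state_trajectory, ca_core):
        from helixtail.trajectory_io import resolve_selection

        traj = two_state_trajectory.slice_frames(slice(0, 10))
        mat = rmsd_matrix(traj, ca_core)
        idx = resolve_selection(traj.topology, ca_core)
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert mat[i, j] == 0.0
                else:
                    expected = kabsch_fit(
                        traj.coordinates[i][idx], traj.coordinates[j][idx]
                    ).rmsd
                    assert mat[i, j] == pytest.approx(expected, abs=1e-9)

    def test_symmetric_zero_diagonal_triangle(self, two_state_trajectory, ca_core):
        traj = two_state_trajectory.slice_frames(slice(0, 30))
        mat = rmsd_matrix(traj, ca_core)
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j, k = rng.integers(0, 30, size=3)
            assert mat[i, j] <= mat[i, k] + mat[k, j] + 1e-9

    def test_identical_frames_give_zero_matrix(self, helix_trajectory, ca_core):
        mat = rmsd_matrix(helix_trajectory, ca_core)
        assert np.allclose(mat, 0.0, atol=1e-9)


class TestAverageStructure:
    def test_identical_frames(self, helix_trajectory, helix_11, ca_core):
        avg, converged, n_iter = average_structure(helix_trajectory, ca_core)
        assert converged
        assert np.allclose(avg, helix_11, atol=1e-9)

    def test_rigid_motions_of_one_structure(self, helix_11, topology_11, ca_core):
        rot = Rotation.from_euler("y", 120, degrees=True).as_matrix()
        frames = np.array([helix_11, helix_11 @ rot.T + 4.0])
        traj = Trajectory(topology_11, frames)
        avg, converged, _ = average_structure(traj, ca_core)
        assert converged
        assert kabsch_fit(avg, helix_11).rmsd < 1e-6

    def test_mean_of_jittered_ensemble_near_template(
        self, helix_11, topology_11, ca_core
    ):
        r = np.random.default_rng(3)
        n_frames, sigma = 2000, 0.2
        coords = helix_11[None] + r.normal(scale=sigma, size=(n_frames, *helix_11.shape))
        avg, converged, _ = average_structure(Trajectory(topology_11, coords), ca_core)
        assert converged
        fit = kabsch_fit(avg, helix_11)
        # per-atom deviation of the mean shrinks as sigma/sqrt(frames)
        assert fit.rmsd < 3 * sigma * np.sqrt(3) / np.sqrt(n_frames) * 3


class TestRmsf:
    def test_static_trajectory_zero(self, helix_trajectory, ca_core):
        assert np.allclose(rmsf(helix_trajectory, ca_core), 0.0)

    def test_isotropic_jitter_closed_form(self, helix_11, topology_11):
        """White-noise jitter of std sigma per axis gives rmsf = sigma*sqrt(3)."""
        sigma = 0.3
        r = np.random.default_rng(11)
        coords = helix_11[None] + r.normal(scale=sigma, size=(10_000, *helix_11.shape))
        # no alignment: fluctuations must match the closed form exactly
        values = rmsf(Trajectory(topology_11, coords), SelectionSpec(["CA"], (1, 11)))
        assert np.allclose(values, sigma * np.sqrt(3), rtol=0.05)

    def test_core_tail_contrast(self, ca_core):
        """Rigid core + mobile tail reproduces the order-disorder fluctuation
        split (tail rmsf > 5x core rmsf)."""
        from helixtail.generate import TwoStateGeneratorConfig, simulate_two_state
        from helixtail.superposition import align_trajectory

        config = TwoStateGeneratorConfig(
            p_folded_target=0.999, mean_dwell_folded=1e6, seed=5
        )
        traj = simulate_two_state(config, 500)
        aligned = align_trajectory(traj, traj.coordinates[0], ca_core)
        core = rmsf(aligned, SelectionSpec(["CA"], (1, 7))).mean()
        tail = rmsf(aligned, SelectionSpec(["CA"], (8, 11))).mean()
        assert tail > 3 * core


class TestRepresentativeStructure:
    def test_identical_frames_give_first(self, helix_trajectory, ca_core):
        frame, rmsd = representative_structure(helix_trajectory, ca_core)
        assert frame == 0
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_inserted_template_is_selected(self, helix_11, topology_11, ca_core):
        r = np.random.default_rng(9)
        coords = helix_11[None] + r.normal(scale=0.3, size=(100, *helix_11.shape))
        coords[57] = helix_11  # plant the exact template mid-trajectory
        frame, _ = representative_structure(Trajectory(topology_11, coords), ca_core)
        assert frame == 57

    def test_tie_breaks_to_earliest(self, helix_11, topology_11, ca_core):
        # two frames mirror-symmetric about the average: equal rmsd
        delta = np.zeros_like(helix_11)
        delta[0] = [0.5, 0.0, 0.0]
        frames = np.array([helix_11 + delta, helix_11 - delta])
        frame, _ = representative_structure(Trajectory(topology_11, frames), ca_core)
        assert frame == 0
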