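import numpy as np
import pytest

from saxsemble import (
    Conformer,
    ConformerEnsemble,
    cluster_pc_space,
    ensemble_pca,
    find_invariant_core,
    generate_mode_ensemble,
    interpolate_pc_trajectory,
    movement_similarity_matrix,
    per_residue_pc_amplitude,
    per_residue_rmsf,
    rmsf_bfactor_correlation,
)
from saxsemble.dynamics import _per_residue_ellipsoid_volumes
from conftest import random_rotation


def make_jitter_ensemble(rng, n_res=20, n_members=50, sigma=None, base_scale=12.0):
    """Ensemble with controllable per-residue isotropic jitter."""
    base = rng.normal(scale=base_scale, size=(n_res, 3))
    if sigma is None:
        sigma = np.zeros(n_res)
    members = []
    for i in range(n_members):
        noise = rng.standard_normal((n_res, 3)) * np.asarray(sigma)[:, None]
        members.append(Conformer(f"m{i}", np.arange(1, n_res + 1), base + noise))
    return ConformerEnsemble(members)


class TestRmsf:
    def test_identical_members_zero(self, rng):
        ens = make_jitter_ensemble(rng, n_members=5)
        np.testing.assert_allclose(per_residue_rmsf(ens, presuperposed=True), 0.0, atol=1e-12)

    def test_isotropic_jitter_closed_form(self, rng):
        """One residue jittered with per-axis σ = 2 → rmsf ≈ 2√3."""
        sigma = np.zeros(20)
        sigma[7] = 2.0
        ens = make_jitter_ensemble(rng, n_members=2000, sigma=sigma)
        rmsf = per_residue_rmsf(ens, presuperposed=True)
        assert rmsf[7] == pytest.approx(2 * np.sqrt(3), rel=0.05)

    def test_rigid_transform_invariance(self, rng):
        sigma = np.full(20, 0.8)
        ens = make_jitter_ensemble(rng, n_members=30, sigma=sigma)
        rmsf0 = per_residue_rmsf(ens)
        rot, shift = random_rotation(rng), np.array([5.0, -2.0, 9.0])
        moved = ConformerEnsemble(
            [Conformer(c.id, c.residue_numbers, c.coords @ rot.T + shift) for c in ens]
        )
        rmsf1 = per_residue_rmsf(moved)
        np.testing.assert_allclose(rmsf1, rmsf0, atol=1e-8)


class TestInvariantCore:
    def test_identical_conformers_prune_nothing(self, rng):
        ens = make_jitter_ensemble(rng, n_members=5)
        result = find_invariant_core(ens, volume_cutoff=150.0)
        assert len(result.core_residues) == 20
        assert result.iterations["total_volume"].iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigid_half(self, rng):
        """Residues 1–30 rigid, 31–60 jittered at σ = 5 Å: core ⊆ rigid set."""
        sigma = np.concatenate([np.zeros(30) + 0.05, np.full(30, 5.0)])
        ens = make_jitter_ensemble(rng, n_res=60, n_members=50, sigma=sigma, base_scale=20.0)
        result = find_invariant_core(ens, volume_cutoff=None)
        core = set(result.core_residues)
        rigid = set(range(1, 31))
        assert core <= rigid
        assert len(core & rigid) >= 0.9 * 30

    def test_first_removal_is_argmax_volume(self, rng):
        sigma = rng.uniform(0.5, 4.0, size=15)
        ens = make_jitter_ensemble(rng, n_res=15, n_members=40, sigma=sigma)
        sup = ens.superposed()
        vols = _per_residue_ellipsoid_volumes(sup)
        expected_first = sup.residue_numbers[np.argmax(vols)]
        result = find_invariant_core(ens, volume_cutoff=1e-6, min_core=3)
        removed = result.iterations["removed_residue"].dropna()
        assert int(removed.iloc[0]) == expected_first

    def test_pruning_trajectory_monotone(self, rng):
        sigma = rng.uniform(0.2, 3.0, size=25)
        ens = make_jitter_ensemble(rng, n_res=25, n_members=30, sigma=sigma)
        result = find_invariant_core(ens, volume_cutoff=None)
        tv = result.iterations["total_volume"].to_numpy()
        assert np.all(np.diff(tv) <= 1e-6 * (1 + tv[:-1]))
        removed = result.iterations["removed_residue"].dropna().astype(int)
        assert removed.is_unique


class TestEnsemblePCA:
    def test_rank_one_ensemble(self, rng):
        base = Conformer("b", np.arange(1, 13), rng.normal(scale=10, size=(12, 3)))
        mode = rng.normal(size=36)
        mode /= np.linalg.norm(mode)
        ens = generate_mode_ensemble(base, mode, amplitudes=rng.normal(scale=3, size=20))
        pca = ensemble_pca(ens, presuperposed=True)
        assert pca.variance_fractions[0] > 0.99
        cos = abs(pca.eigenvectors[0] @ mode)
        assert cos > 0.999

    def test_eigenvalue_sum_conserves_variance(self, rng):
        sigma = np.full(10, 1.5)
        ens = make_jitter_ensemble(rng, n_res=10, n_members=15, sigma=sigma)
        pca = ensemble_pca(ens, presuperposed=True)
        dev = ens.coordinate_array() - ens.coordinate_array().mean(axis=0)
        total = (dev**2).sum() / len(ens)
        assert pca.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_matches_bruteforce_covariance_eig(self, rng):
        """5-member, 10-residue toy vs direct 3N×3N covariance eigendecomposition."""
        ens = make_jitter_ensemble(rng, n_res=10, n_members=5, sigma=np.full(10, 2.0))
        pca = ensemble_pca(ens, presuperposed=True)
        flat = ens.coordinate_array().reshape(5, 30)
        flat = flat - flat.mean(axis=0)
        cov = flat.T @ flat / 5
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(pca.eigenvalues[:4], w[:4], rtol=1e-8)
        for k in range(4):
            assert abs(pca.eigenvectors[k] @ v[:, k]) == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_eigenvectors(self, rng):
        ens = make_jitter_ensemble(rng, n_res=8, n_members=12, sigma=np.full(8, 1.0))
        pca = ensemble_pca(ens, presuperposed=True)
        gram = pca.eigenvectors @ pca.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_reconstruction_with_all_components(self, rng):
        ens = make_jitter_ensemble(rng, n_res=9, n_members=6, sigma=np.full(9, 1.2))
        sup = ens.superposed()
        pca = ensemble_pca(sup, presuperposed=True)
        flat_mean = pca.mean_coords.reshape(-1)
        for m in range(len(sup)):
            rebuilt = flat_mean + pca.projections[m] @ pca.eigenvectors
            np.testing.assert_allclose(rebuilt, sup[m].coords.reshape(-1), atol=1e-6)


class TestPCAmplitude:
    def test_single_moving_residue(self, rng):
        base = Conformer("b", np.arange(1, 11), rng.normal(scale=10, size=(10, 3)))
        mode = np.zeros((10, 3))
        mode[6] = [1.0, 0.5, -0.2]
        mode = mode.reshape(-1) / np.linalg.norm(mode)
        ens = generate_mode_ensemble(base, mode, amplitudes=[-2, -1, 0, 1, 2])
        pca = ensemble_pca(ens, presuperposed=True)
        amp = per_residue_pc_amplitude(pca, 0)
        assert amp[6] ** 2 / (amp**2).sum() > 0.99

    def test_linearity_and_norm_identity(self, rng):
        base = Conformer("b", np.arange(1, 11), rng.normal(scale=10, size=(10, 3)))
        mode = rng.normal(size=30)
        mode /= np.linalg.norm(mode)
        amps = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        pca1 = ensemble_pca(generate_mode_ensemble(base, mode, amps), presuperposed=True)
        pca2 = ensemble_pca(generate_mode_ensemble(base, mode, 2 * amps), presuperposed=True)
        a1 = per_residue_pc_amplitude(pca1, 0)
        a2 = per_residue_pc_amplitude(pca2, 0)
        np.testing.assert_allclose(a2, 2 * a1, rtol=1e-8)
        assert (a1**2).sum() == pytest.approx(pca1.eigenvalues[0], rel=1e-10)

    def test_component_out_of_range(self, rng):
        ens = make_jitter_ensemble(rng, n_res=8, n_members=4, sigma=np.full(8, 1.0))
        pca = ensemble_pca(ens, presuperposed=True)
        with pytest.raises(IndexError):
            per_residue_pc_amplitude(pca, 99)


class TestPCTrajectory:
    def test_endpoints_and_spacing(self, rng):
        ens = make_jitter_ensemble(rng, n_res=10, n_members=20, sigma=np.full(10, 1.5))
        pca = ensemble_pca(ens, presuperposed=True)
        traj = interpolate_pc_trajectory(pca, component=0, n_frames=7)
        projections = [
            (f.coords.reshape(-1) - pca.mean_coords.reshape(-1)) @ pca.eigenvectors[0]
            for f in traj
        ]
        obs = pca.projections[:, 0]
        assert projections[0] == pytest.approx(obs.min(), abs=1e-9)
        assert projections[-1] == pytest.approx(obs.max(), abs=1e-9)
        steps = np.diff(projections)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_orthogonal_components_constant(self, rng):
        ens = make_jitter_ensemble(rng, n_res=10, n_members=20, sigma=np.full(10, 1.5))
        pca = ensemble_pca(ens, presuperposed=True)
        traj = interpolate_pc_trajectory(pca, component=0, n_frames=5)
        for k in (1, 2):
            proj_k = [
                (f.coords.reshape(-1) - pca.mean_coords.reshape(-1)) @ pca.eigenvectors[k]
                for f in traj
            ]
            np.testing.assert_allclose(proj_k, 0.0, atol=1e-9)


class TestAMSM:
    def _ensemble_with_displacements(self, rng, disp):
        """disp: (M, N, 3) deviations added to a fixed base."""
        m, n, _ = disp.shape
        base = rng.normal(scale=15, size=(n, 3))
        return ConformerEnsemble(
            [Conformer(f"m{i}", np.arange(1, n + 1), base + disp[i]) for i in range(m)]
        )

    def test_identical_motion_pair(self, rng):
        disp = np.zeros((30, 5, 3))
        common = rng.normal(size=(30, 3))
        disp[:, 1] = common
        disp[:, 3] = common
        ens = self._ensemble_with_displacements(rng, disp)
        amsm = movement_similarity_matrix(ens, presuperposed=True)
        assert amsm.values[1, 3] == pytest.approx(1.0, abs=1e-10)

    def test_opposed_motion_pair(self, rng):
        disp = np.zeros((30, 5, 3))
        common = rng.normal(size=(30, 3))
        disp[:, 1] = common
        disp[:, 3] = -common
        ens = self._ensemble_with_displacements(rng, disp)
        amsm = movement_similarity_matrix(ens, presuperposed=True)
        assert amsm.values[1, 3] == pytest.approx(-1.0, abs=1e-10)

    def test_independent_jitter_near_zero(self, rng):
        disp = rng.standard_normal((1000, 6, 3))
        ens = self._ensemble_with_displacements(rng, disp)
        amsm = movement_similarity_matrix(ens, presuperposed=True)
        off = amsm.values[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)
        np.testing.assert_allclose(np.diag(amsm.values), 1.0)

    def test_zero_fluctuation_flagged(self, rng):
        disp = np.zeros((20, 5, 3))
        disp[:, 0] = rng.normal(size=(20, 3))
        ens = self._ensemble_with_displacements(rng, disp)
        amsm = movement_similarity_matrix(ens, presuperposed=True)
        assert amsm.zero_fluctuation[2]
        assert amsm.values[2, 0] == 0.0
        assert amsm.values[2, 2] == 1.0

    def test_two_domain_hinge_block_structure(self, rng):
        """Within-domain correlations ≫ cross-domain for a rigid hinge."""
        m, n = 60, 12
        disp = np.zeros((m, n, 3))
        angles = rng.normal(scale=0.2, size=m)
        axis_a = rng.normal(size=3)
        axis_b = rng.normal(size=3)
        for i in range(m):
            disp[i, :6] = angles[i] * axis_a  # domain A moves together
            disp[i, 6:] = rng.normal(scale=0.05, size=3) + angles[i] * axis_b * 0.01
        ens = self._ensemble_with_displacements(rng, disp)
        amsm = movement_similarity_matrix(ens, presuperposed=True)
        within = amsm.values[:6, :6][~np.eye(6, dtype=bool)]
        cross = amsm.values[:6, 6:]
        assert within.min() > 0.9
        assert np.abs(cross).mean() < 0.5


class TestClusterPCSpace:
    def test_recovers_separated_clusters(self, rng):
        base = rng.normal(scale=15, size=(10, 3))
        members, truth = [], []
        for c, offset in enumerate([0.0, 40.0, 80.0]):
            mode = np.zeros((10, 3))
            mode[4] = [1.0, 0, 0]
            for i in range(8):
                coords = base + mode * (offset + rng.normal(scale=1.0))
                members.append(Conformer(f"c{c}_{i}", np.arange(1, 11), coords))
                truth.append(c)
        ens = ConformerEnsemble(members)
        pca = ensemble_pca(ens, presuperposed=True)
        labels = cluster_pc_space(pca, n_components=3, n_clusters=3)
        # exact recovery up to label permutation
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_cluster(self, rng):
        ens = make_jitter_ensemble(rng, n_res=8, n_members=6, sigma=np.full(8, 1.0))
        pca = ensemble_pca(ens, presuperposed=True)
        assert len(set(cluster_pc_space(pca, n_clusters=1))) == 1

    def test_too_many_clusters_rejected(self, rng):
        ens = make_jitter_ensemble(rng, n_res=8, n_members=4, sigma=np.full(8, 1.0))
        pca = ensemble_pca(ens, presuperposed=True)
        with pytest.raises(ValueError):
            cluster_pc_space(pca, n_clusters=10)


class TestRmsfBfactor:
    def test_self_correlation(self, rng):
        v = rng.uniform(1, 5, size=30)
        r, _, _ = rmsf_bfactor_correlation(v, v)
        assert r == pytest.approx(1.0)
        r2, _, _ = rmsf_bfactor_correlation(v, -v)
        assert r2 == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        r, _, _ = rmsf_bfactor_correlation(x, y)
        assert r == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rmsf_bfactor_correlation(np.ones(5), np.arange(5.0))
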