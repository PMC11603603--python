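"""TICA, MSM estimation, free-energy surfaces and macrostate statistics."""

import numpy as np
import pytest
import scipy.linalg

from nohcg.msm_tica_analysis import (
    FreeEnergySurface,
    cluster_kmeans,
    estimate_msm,
    featurize_ca_distances,
    free_energy_surface,
    kabsch_rmsd,
    macrostate_stats,
    project_cg,
    stationary_distribution,
    tica_fit,
    tica_transform,
)

from conftest import random_rotation


class TestFeaturize:
    def test_three_sites_give_three_columns(self, rng):
        traj = rng.standard_normal((10, 3, 3))
        assert featurize_ca_distances(traj).shape == (10, 3)

    def test_rigid_motion_invariance(self, rng):
        traj = rng.standard_normal((5, 6, 3))
        rot = random_rotation(rng)
        moved = traj @ rot.T + 4.0
        np.testing.assert_allclose(
            featurize_ca_distances(moved), featurize_ca_distances(traj), atol=1e-10
        )

    def test_matches_hand_computed_distances(self):
        traj = np.array([[[0, 0, 0], [3, 0, 0], [0, 4, 0]]], dtype=float)
        np.testing.assert_allclose(featurize_ca_distances(traj), [[3.0, 4.0, 5.0]])

    def test_ca_subset_selection(self, rng):
        traj = rng.standard_normal((4, 5, 3))
        sub = featurize_ca_distances(traj, ca_indices=[0, 2, 4])
        np.testing.assert_allclose(sub, featurize_ca_distances(traj[:, [0, 2, 4]]))

    def test_single_site_raises(self, rng):
        with pytest.raises(ValueError):
            featurize_ca_distances(rng.standard_normal((3, 1, 3)))


class TestTICA:
    def test_perfectly_persistent_signal_has_unit_eigenvalues(self, rng):
        base = rng.standard_normal((50, 3))
        feats = np.tile(base, (4, 1))  # periodic with period 50
        model = tica_fit(feats, lag=50)
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=1e-8)

    def test_slow_direction_recovered_from_ou_mixture(self):
        rng = np.random.default_rng(5)
        n = 30000
        slow = np.zeros(n)
        fast = np.zeros(n)
        for t in range(1, n):
            slow[t] = 0.995 * slow[t - 1] + 0.1 * rng.standard_normal()
            fast[t] = 0.5 * fast[t - 1] + rng.standard_normal()
        mix = np.array([[1.0, 0.7], [0.3, 1.0]])
        feats = np.stack([slow, fast], axis=1) @ mix.T
        model = tica_fit(feats, lag=10)
        proj = tica_transform(model, feats, n_components=1)[:, 0]
        assert abs(np.corrcoef(proj, slow)[0, 1]) > 0.99

    def test_matches_dense_generalized_eigensolver(self, rng):
        feats = rng.standard_normal((500, 4)) @ rng.standard_normal((4, 4))
        lag = 3
        model = tica_fit(feats, lag=lag)
        # independent dense solve on covariances assembled from scratch
        x, y = feats[:-lag], feats[lag:]
        mean = np.concatenate([x, y]).mean(axis=0)
        xc, yc = x - mean, y - mean
        m = len(x)
        c0 = (xc.T @ xc + yc.T @ yc) / (2 * m)
        ct = (xc.T @ yc + yc.T @ xc) / (2 * m)
        ev = np.sort(scipy.linalg.eigh(ct, c0, eigvals_only=True))[::-1]
        np.testing.assert_allclose(model.eigenvalues, ev, atol=1e-10)

    def test_lag_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            tica_fit(rng.standard_normal((10, 2)), lag=0)


class TestProjectCG:
    def test_identical_to_transform_on_all_atom_features(self, rng):
        feats = rng.standard_normal((200, 5))
        model = tica_fit(feats, lag=2)
        np.testing.assert_allclose(
            project_cg(model, feats, n_components=3),
            tica_transform(model, feats, n_components=3),
        )

    def test_features_at_the_mean_project_to_origin(self, rng):
        feats = rng.standard_normal((200, 5))
        model = tica_fit(feats, lag=2)
        np.testing.assert_allclose(
            project_cg(model, model.mean[None, :]), 0.0, atol=1e-10
        )

    def test_projection_is_affine_in_the_features(self, rng):
        feats = rng.standard_normal((200, 5))
        model = tica_fit(feats, lag=2)
        shift = rng.standard_normal(5)
        expected = project_cg(model, feats) + shift @ model.components[:, :3]
        np.testing.assert_allclose(project_cg(model, feats + shift), expected,
                                   atol=1e-10)

    def test_dimension_mismatch_raises(self, rng):
        model = tica_fit(rng.standard_normal((50, 4)), lag=1)
        with pytest.raises(ValueError, match="dimension"):
            project_cg(model, rng.standard_normal((10, 3)))


class TestClustering:
    def test_separated_blobs_are_split_perfectly(self, rng):
        a = rng.standard_normal((100, 2)) * 0.1
        b = rng.standard_normal((100, 2)) * 0.1 + 10.0
        labels, _ = cluster_kmeans(np.concatenate([a, b]), k=2, seed=0)
        assert len(set(labels[:100])) == 1
        assert len(set(labels[100:])) == 1
        assert labels[0] != labels[150]

    def test_k_equal_one_labels_everything_zero(self, rng):
        labels, _ = cluster_kmeans(rng.standard_normal((30, 2)), k=1, seed=0)
        assert set(labels) == {0}

    def test_seeded_repeat_is_identical(self, rng):
        data = rng.standard_normal((200, 3))
        l1, _ = cluster_kmeans(data, k=5, seed=4)
        l2, _ = cluster_kmeans(data, k=5, seed=4)
        np.testing.assert_array_equal(l1, l2)

    def test_invalid_k_raises(self, rng):
        with pytest.raises(ValueError):
            cluster_kmeans(rng.standard_normal((10, 2)), k=0)


class TestMSM:
    def test_constant_trajectory_gives_trivial_chain(self):
        msm = estimate_msm(np.zeros(100, dtype=int), lag=1,
                           frame_discard_fraction=0.0)
        np.testing.assert_allclose(msm.transition_matrix, [[1.0]])
        np.testing.assert_allclose(msm.stationary, [1.0])

    def test_two_state_telegraph_recovered_within_three_se(self):
        p01, p10 = 0.1, 0.2
        n = 200000
        rng = np.random.default_rng(7)
        u = rng.random(n)
        s = np.zeros(n, dtype=int)
        for t in range(1, n):
            s[t] = (1 if u[t] < p01 else 0) if s[t - 1] == 0 else (0 if u[t] < p10 else 1)
        msm = estimate_msm(s, lag=1, frame_discard_fraction=0.0)
        n0 = (s[:-1] == 0).sum()
        n1 = (s[:-1] == 1).sum()
        assert abs(msm.transition_matrix[0, 1] - p01) < 3 * np.sqrt(p01 * (1 - p01) / n0)
        assert abs(msm.transition_matrix[1, 0] - p10) < 3 * np.sqrt(p10 * (1 - p10) / n1)
        # stationary distribution of the analytic chain
        pi_true = np.array([p10, p01]) / (p01 + p10)
        np.testing.assert_allclose(msm.stationary, pi_true, atol=0.02)

    def test_rows_sum_to_one_and_detailed_balance(self, rng):
        labels = rng.integers(0, 5, size=5000)
        msm = estimate_msm(labels, lag=2)
        np.testing.assert_allclose(msm.transition_matrix.sum(axis=1), 1.0, atol=1e-12)
        flux = msm.stationary[:, None] * msm.transition_matrix
        np.testing.assert_allclose(flux, flux.T, atol=1e-8)

    def test_initial_fraction_is_discarded(self):
        # state 9 appears only in the first 10% and must not enter the model
        labels = np.concatenate([np.full(100, 9), np.zeros(900, dtype=int)])
        msm = estimate_msm(labels, lag=1, frame_discard_fraction=0.10)
        assert 9 not in msm.active_states

    def test_disconnected_chain_reduced_to_largest_set(self):
        # two blocks that never interconvert
        a = np.tile([0, 1], 300)
        b = np.tile([2, 3], 20)
        msm = estimate_msm([a, b], lag=1, frame_discard_fraction=0.0)
        assert sorted(msm.active_states) == [0, 1]
        assert not msm.connected

    def test_stationary_is_left_fixed_point(self, rng):
        labels = rng.integers(0, 4, size=3000)
        msm = estimate_msm(labels, lag=1)
        np.testing.assert_allclose(
            msm.stationary @ msm.transition_matrix, msm.stationary, atol=1e-10
        )


class TestFreeEnergySurface:
    def test_point_mass_occupies_single_zero_bin(self):
        proj = np.zeros((100, 2))
        surf = free_energy_surface(proj, grid=5, extent=(-1, 1, -1, 1))
        assert np.nansum(surf.free_energy == 0.0) == 1
        assert surf.populated.sum() == 1

    def test_gaussian_sample_yields_quadratic_surface(self):
        rng = np.random.default_rng(11)
        xy = rng.standard_normal((300000, 2))
        surf = free_energy_surface(xy, grid=80, temperature=350.0)
        f = surf.free_energy
        xc = 0.5 * (surf.x_edges[:-1] + surf.x_edges[1:])
        yc = 0.5 * (surf.y_edges[:-1] + surf.y_edges[1:])
        xg, yg = np.meshgrid(xc, yc, indexing="ij")
        m = surf.populated
        design = np.stack([xg[m]**2, yg[m]**2, xg[m], yg[m], xg[m] * yg[m],
                           np.ones(m.sum())], axis=1)
        w = np.exp(-0.5 * f[m])  # inverse-variance weight ~ sqrt(occupancy)
        coef, *_ = np.linalg.lstsq(design * w[:, None], f[m] * w, rcond=None)
        resid = w * (f[m] - design @ coef)
        total = w * (f[m] - np.average(f[m], weights=w**2))
        r2 = 1.0 - (resid**2).sum() / (total**2).sum()
        assert r2 > 0.95

    def test_weight_rescaling_is_neutral(self, rng):
        proj = rng.standard_normal((1000, 2))
        weights = rng.random(1000)
        a = free_energy_surface(proj, weights=weights, grid=20)
        b = free_energy_surface(proj, weights=2.0 * weights, grid=20)
        np.testing.assert_allclose(a.free_energy, b.free_energy, equal_nan=True)

    def test_minimum_is_exactly_zero(self, rng):
        surf = free_energy_surface(rng.standard_normal((5000, 2)), grid=30)
        assert np.nanmin(surf.free_energy) == 0.0


class TestRMSDAndMacrostates:
    def test_self_rmsd_is_zero(self, rng):
        coords = rng.standard_normal((10, 3))
        assert kabsch_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_gives_zero_rmsd(self, rng):
        coords = rng.standard_normal((10, 3))
        rot = random_rotation(rng)
        assert kabsch_rmsd(coords @ rot.T + 3.0, coords) == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_alignment_oracle(self, rng):
        from scipy.spatial.transform import Rotation

        p = rng.standard_normal((4, 3))
        q = rng.standard_normal((4, 3))
        ours = kabsch_rmsd(p, q)
        pc, qc = p - p.mean(0), q - q.mean(0)
        rot, rssd = Rotation.align_vectors(qc, pc)
        expected = np.sqrt(np.mean(np.sum((rot.apply(pc) - qc) ** 2, axis=1)))
        assert ours == pytest.approx(expected, rel=1e-8)

    def test_native_macrostate_found_in_two_basin_toy(self):
        rng = np.random.default_rng(3)
        # two conformational basins along x; basin A matches the reference
        ref = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], dtype=float)
        frames = []
        labels = []
        for i in range(400):
            basin = 0 if i % 2 == 0 else 1
            base = ref if basin == 0 else ref + np.array([0, 5.0, 0]) * [[0], [1], [2]]
            frames.append(base + 0.05 * rng.standard_normal((3, 3)))
            labels.append(basin)
        frames = np.array(frames)
        labels = np.array(labels)
        msm = estimate_msm(labels, lag=1, frame_discard_fraction=0.0)
        stats = macrostate_stats(msm, [frames], [labels], ref, n_macrostates=2,
                                 frame_discard_fraction=0.0)
        native = stats["native_macrostate"]
        assert stats["macrostates"][native]["min_rmsd"] < 0.2
        probs = [v["probability"] for v in stats["macrostates"].values()]
        assert sum(probs) == pytest.approx(1.0)

    def test_atom_set_mismatch_raises(self, rng):
        labels = np.zeros(10, dtype=int)
        msm = estimate_msm(labels, lag=1, frame_discard_fraction=0.0)
        with pytest.raises(ValueError, match="site"):
            macrostate_stats(msm, [rng.standard_normal((10, 4, 3))], [labels],
                             rng.standard_normal((3, 3)), n_macrostates=1,
                             frame_discard_fraction=0.0)


class TestPipelineSanity:
    def test_double_well_dimer_analysis_recovers_basin_gap(self):
        """Full TICA -> k-means -> MSM -> weights chain on analytic double-well
        dynamics reproduces the quadrature basin free-energy difference."""
        from nohcg.cg_dynamics import SimConfig, SimState, run
        from nohcg.synthetic_systems import (
            basin_free_energy_difference,
            default_dimer_spec,
            make_toy_molecule,
        )
        from nohcg.synthetic_systems import ToyForceField
        from nohcg.units import KB
        from dataclasses import replace

        spec = replace(default_dimer_spec(seed=4), h_counts=(0, 0))
        topo, frame0 = make_toy_molecule(spec)
        ff = ToyForceField(topo, spec)
        temp = 350.0
        trajs = []
        for seed in (21, 22, 23):  # independent replicas pooled for statistics
            state = SimState(coords=frame0.coords.copy(),
                             velocities=np.zeros_like(frame0.coords),
                             masses=ff.masses, bead_types=np.zeros(2, dtype=int),
                             temperature=temp)
            cfg = SimConfig(timestep=4.0, friction=1.0, temperature=temp,
                            n_steps=300000, seed=seed, output_stride=10)
            trajs.append(run(state, ff, cfg))
        feats = [featurize_ca_distances(t.coords) for t in trajs]
        model = tica_fit(feats, lag=10)
        flat = np.concatenate([tica_transform(model, f, n_components=1) for f in feats])
        labels_flat, _ = cluster_kmeans(flat, k=30, seed=0)
        labels, start = [], 0
        for f in feats:
            labels.append(labels_flat[start:start + len(f)])
            start += len(f)
        msm = estimate_msm(labels, lag=10, frame_discard_fraction=0.10)
        row = {int(s): i for i, s in enumerate(msm.active_states)}
        counts = np.bincount(labels_flat, minlength=labels_flat.max() + 1)
        weights = np.array([
            msm.stationary[row[int(l)]] / counts[l] if int(l) in row else 0.0
            for l in labels_flat
        ])
        r = np.concatenate(feats)[:, 0]
        right = weights[r > spec.bond_r0].sum()
        left = weights[r <= spec.bond_r0].sum()
        measured = -KB * temp * np.log(right / left)
        expected = basin_free_energy_difference(spec, temperature=temp)
        assert abs(measured - expected) < 0.5 * KB * temp
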