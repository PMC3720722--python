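"""Smoothing, normalization, clustering, Theta(N), Z-score, pair consistency."""

import numpy as np
import pytest

from iegdyn import simulate, timecourse
from iegdyn.timecourse import (
    Trajectory,
    average_replicas,
    build_trajectories,
    clustering_zscore,
    ddct_fold_change,
    kmeans_cluster,
    normalize_unit_interval,
    primer_consistency_pvalue,
    smooth_trajectory,
    theta_criterion,
)


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20.0, 20.0, 20.0, 20.0), 1.0),
            ((19.0, 20.0, 20.0, 20.0), 2.0),  # ddCt = -1: one extra doubling
            ((20.0, 18.0, 22.0, 18.0), 4.0),  # ddCt = -2
        ],
    )
    def test_known_values(self, cts, expected):
        assert ddct_fold_change(*cts) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(np.nan, 20, 20, 20)


class TestSmoothing:
    times = np.linspace(10, 95, 12)

    def test_linear_data_reproduced_for_any_penalty(self):
        # straight lines are in the roughness-penalty null space
        y = 0.5 + 0.04 * self.times
        for lam in (None, 0.0, 10.0, 1e5):
            traj = smooth_trajectory(self.times, y, smoothing=lam)
            np.testing.assert_allclose(traj.values, 0.5 + 0.04 * traj.grid, rtol=1e-8)

    def test_zero_penalty_interpolates(self):
        rng = np.random.default_rng(3)
        y = 1 + np.abs(rng.normal(2, 1, 12))
        traj = smooth_trajectory(self.times, y, smoothing=0.0, grid_step=0.5,
                                 grid_span=(10, 95))
        on_grid = np.isin(traj.grid, self.times)
        got = traj.values[on_grid]
        want = y[np.isin(self.times, traj.grid[on_grid])]
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_constant_data_gives_constant_curve(self):
        traj = smooth_trajectory(self.times, np.full(12, 3.3))
        np.testing.assert_allclose(traj.values, 3.3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            smooth_trajectory([10, 20, 30], [1, 2, 3], smoothing=1.0)


class TestNormalization:
    def _traj(self, vals):
        return Trajectory("g", np.arange(len(vals), dtype=float), np.asarray(vals, float))

    def test_basic_minmax(self):
        out = normalize_unit_interval(self._traj([2, 4, 6]))
        np.testing.assert_allclose(out.values, [0, 0.5, 1])

    def test_idempotent(self):
        once = normalize_unit_interval(self._traj([1.0, 3.0, 2.0, 5.0]))
        twice = normalize_unit_interval(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_affine_invariance(self):
        v = np.array([0.2, 0.9, 0.4, 0.0, 1.0])
        a = normalize_unit_interval(self._traj(v)).values
        b = normalize_unit_interval(self._traj(7.5 * v - 3.0)).values
        np.testing.assert_allclose(a, b)

    def test_constant_maps_to_half(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_unit_interval(self._traj([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(out.values, 0.5)


class TestAverageReplicas:
    def test_identical_replicas_unchanged(self):
        g = np.arange(5.0)
        t = Trajectory("g", g, np.array([0, 0.2, 0.5, 0.8, 1.0]), "r1")
        out = average_replicas([t, Trajectory("g", g, t.values, "r2")])
        np.testing.assert_allclose(out.values, t.values)

    def test_mirror_curves_average_to_half(self):
        g = np.arange(4.0)
        v = np.array([0.0, 0.3, 0.7, 1.0])
        out = average_replicas(
            [Trajectory("g", g, v, "r1"), Trajectory("g", g, 1 - v, "r2")]
        )
        np.testing.assert_allclose(out.values, 0.5)

    def test_pointwise_mean(self):
        g = np.arange(3.0)
        out = average_replicas(
            [Trajectory("g", g, np.array([0.0, 0.0, 1.0]), "r1"),
             Trajectory("g", g, np.array([0.0, 1.0, 1.0]), "r2")]
        )
        np.testing.assert_allclose(out.values, [0, 0.5, 1])

    def test_grid_mismatch_rejected(self):
        a = Trajectory("g", np.arange(3.0), np.zeros(3), "r1")
        b = Trajectory("g", np.arange(4.0), np.zeros(4), "r2")
        with pytest.raises(ValueError, match="grid"):
            average_replicas([a, b])


class TestKmeans:
    def _duplicate_groups(self, k0=3, dup=4, dim=20, seed=0):
        rng = np.random.default_rng(seed)
        protos = rng.normal(size=(k0, dim)) * 5
        X = np.repeat(protos, dup, axis=0)
        truth = np.repeat(np.arange(k0), dup)
        return X, truth

    def test_duplicates_coassigned_with_zero_inertia(self):
        X, truth = self._duplicate_groups()
        fit = kmeans_cluster(X, 3, seed=1, n_restarts=20)
        assert fit.inertia == pytest.approx(0.0, abs=1e-20)
        # same duplicates share labels
        for c in range(3):
            assert len(set(fit.assignments[truth == c])) == 1

    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 5))
        fit = kmeans_cluster(X, 1, seed=0, n_restarts=1)
        np.testing.assert_allclose(fit.centroids[0], X.mean(axis=0))
        assert set(fit.assignments) == {1}

    def test_k_out_of_range(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="out of range"):
            kmeans_cluster(X, 5, 0, 1)

    def test_best_of_restarts_inertia_non_increasing(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        inertias = [
            kmeans_cluster(X, 5, seed=3, n_restarts=r).inertia for r in (1, 5, 25)
        ]
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_gene_relabeling_equivariance(self, planted_timecourses):
        # permuting gene order permutes assignments identically
        tcs, _ = planted_timecourses
        b = build_trajectories(tcs)
        fit = kmeans_cluster(b.features, 3, seed=0, n_restarts=20)
        perm = np.random.default_rng(1).permutation(len(tcs.gene_ids))
        fit_p = kmeans_cluster(b.features[perm], 3, seed=0, n_restarts=20)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(fit.assignments[perm], fit_p.assignments) == 1.0


class TestTheta:
    def test_well_separated_duplicate_groups_recover_k0(self):
        rng = np.random.default_rng(4)
        protos = rng.normal(size=(4, 15)) * 10
        X = np.repeat(protos, 5, axis=0) + rng.normal(scale=0.01, size=(20, 15))
        theta, k_opt, _ = theta_criterion(X, range(1, 8), alpha=0.01, seed=0,
                                          n_restarts=20)
        assert k_opt == 4

    def test_first_term_non_increasing_and_penalty_increasing(self):
        rng = np.random.default_rng(6)
        for trial in range(20):
            X = rng.normal(size=(30, 8))
            alpha = 0.05
            theta, _, _ = theta_criterion(X, range(1, 7), alpha=alpha, seed=trial,
                                          n_restarts=30)
            ks = sorted(theta)
            first = [theta[k] - alpha * k for k in ks]
            assert all(a >= b - 1e-9 for a, b in zip(first, first[1:]))

    def test_invalid_alpha_and_range(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="alpha"):
            theta_criterion(X, range(1, 4), alpha=0.0)
        with pytest.raises(ValueError, match="k_range"):
            theta_criterion(np.random.default_rng(0).normal(size=(5, 2)), range(1, 9))

    def test_planted_three_patterns_recovered(self, planted_timecourses):
        tcs, labels = planted_timecourses
        b = build_trajectories(tcs)
        theta, k_opt, fits = theta_criterion(b, range(1, 9), seed=0)
        assert k_opt == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, fits[3].assignments) >= 0.9


class TestZscore:
    def test_random_labels_on_random_data_small_z(self):
        zs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 10))
            labels = rng.integers(1, 4, size=30)
            zs.append(clustering_zscore(X, labels, n_permutations=200, seed=seed))
        assert np.all(np.abs(zs) < 3.5)
        assert abs(np.mean(zs)) < 1.0

    def test_true_structure_large_z(self):
        rng = np.random.default_rng(0)
        protos = rng.normal(size=(4, 12)) * 8
        X = np.repeat(protos, 6, axis=0) + rng.normal(scale=0.1, size=(24, 12))
        labels = np.repeat(np.arange(1, 5), 6)
        z = clustering_zscore(X, labels, n_permutations=500, seed=1)
        assert z > 5

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_permutations"):
            clustering_zscore(np.zeros((4, 2)), np.array([1, 1, 2, 2]), 0)


class TestPrimerConsistency:
    def test_impossible_coclustering_gives_zero(self):
        # two items in two singleton clusters can never co-cluster
        p = primer_consistency_pvalue({"a": 1, "b": 2}, [("a", "b")])
        assert p == 0.0

    def test_single_pair_closed_form_exact_and_monte_carlo(self):
        # one pair among clusters of sizes s_i: p = sum s_i (s_i - 1) / (M (M-1))
        sizes = [5, 3, 2]
        labels = {}
        idx = 0
        for c, s in enumerate(sizes):
            for _ in range(s):
                labels[f"item{idx}"] = c
                idx += 1
        M = sum(sizes)
        closed = sum(s * (s - 1) for s in sizes) / (M * (M - 1))
        pair = [("item0", "item5")]
        exact = primer_consistency_pvalue(labels, pair)
        assert exact == pytest.approx(closed, rel=1e-12)
        mc = primer_consistency_pvalue(labels, pair, n_permutations=20000, seed=0,
                                       max_exact=0)
        se = np.sqrt(closed * (1 - closed) / 20000)
        assert abs(mc - closed) < 3 * se

    def test_exact_matches_monte_carlo_for_multiple_pairs(self):
        rng = np.random.default_rng(7)
        labels = {f"i{j}": int(c) for j, c in enumerate(rng.integers(0, 4, size=20))}
        pairs = [("i0", "i1"), ("i2", "i3"), ("i4", "i5")]
        exact = primer_consistency_pvalue(labels, pairs)
        mc = primer_consistency_pvalue(labels, pairs, n_permutations=200000, seed=1,
                                       max_exact=0)
        se = np.sqrt(max(exact, 1e-9) * (1 - exact) / 200000)
        assert abs(mc - exact) < 4 * se + 1e-4

    def test_unknown_pair_member_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            primer_consistency_pvalue({"a": 1, "b": 1}, [("a", "zzz")])


class TestPipelineEquivariance:
    def test_replica_order_invariance_of_statistics(self, planted_timecourses):
        tcs, _ = planted_timecourses
        b1 = build_trajectories(tcs)
        swapped = timecourse.TimeCourseSet(
            tcs.gene_ids, [tcs.replica_ids[i] for i in (2, 0, 1)],
            tcs.times, tcs.values[:, (2, 0, 1), :],
        )
        b2 = build_trajectories(swapped)
        # averaged curves are replica-order independent
        np.testing.assert_allclose(b1.averages, b2.averages)
        t1, k1, _ = theta_criterion(b1, range(2, 6), seed=0, n_restarts=20)
        t2, k2, _ = theta_criterion(b2, range(2, 6), seed=0, n_restarts=20)
        assert k1 == k2
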