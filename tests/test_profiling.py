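import numpy as np
import pandas as pd
import pytest

from tractanomaly import profiling
from tractanomaly.cohort import TractVoxelMatrix
from tractanomaly.synthetic import planted_pattern_profiles


def _matrix(values, label="UF_left"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    v = values.shape[1]
    idx = np.column_stack([np.arange(v), np.zeros(v, int), np.zeros(v, int)])
    return TractVoxelMatrix(label, idx, values,
                            [f"s{i}" for i in range(values.shape[0])])


class TestTractMeans:
    def test_simple_rows(self):
        means = profiling.tract_means(_matrix([[1, 2, 3], [5, 5, 5]]))
        assert means["s0"] == 2.0
        assert means["s1"] == 5.0

    def test_matches_brute_force_summation(self, rng):
        row = rng.random(50)
        means = profiling.tract_means(_matrix([row]))
        assert means["s0"] == pytest.approx(sum(row) / len(row), abs=1e-12)


class TestBootstrapTest:
    def test_identical_samples_give_zero_t_and_p_near_one(self):
        a = np.array([0.5, 0.51, 0.49, 0.52, 0.5] * 4)
        t, p = profiling.bootstrap_two_sample_test(a, a.copy(), n_boot=1000, seed=1)
        assert t == 0.0
        assert p > 0.9

    def test_fully_separated_groups_hit_the_add_one_floor(self):
        a = np.array([0.50, 0.51, 0.49, 0.50, 0.52] * 4)
        b = a + 10 * a.std(ddof=1)
        t, p = profiling.bootstrap_two_sample_test(a, b, n_boot=2000, seed=1)
        assert p == pytest.approx(1 / 2001)

    def test_zero_variance_equal_groups(self):
        t, p = profiling.bootstrap_two_sample_test([1.0, 1.0], [1.0, 1.0],
                                                   n_boot=1000, seed=0)
        assert (t, p) == (0.0, 1.0)

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            profiling.bootstrap_two_sample_test([1.0, 2.0], [1.0, 3.0],
                                                n_boot=100, seed=0)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            profiling.bootstrap_two_sample_test([1.0], [1.0, 2.0])


class TestFOISelection:
    def test_bonferroni_threshold_for_71_tracts(self):
        res = pd.DataFrame({"p_value": [0.5] * 71,
                            "t_value": 0.0, "mean_diff": 0.0})
        out = profiling.select_fois(res, alpha=0.05)
        thr = out.attrs["per_test_threshold"]
        assert thr == pytest.approx(7.042e-4, rel=1e-3)
        assert thr <= 0.001

    def test_boundary_p_value_is_not_selected(self):
        res = pd.DataFrame({"p_value": [0.05 / 10], "t_value": 0.0, "mean_diff": 0.0})
        out = profiling.select_fois(res, alpha=0.05, m=10)
        assert not out["selected"].iloc[0]

    def test_moderate_p_values_all_rejected_after_correction(self):
        res = pd.DataFrame({"p_value": [0.01] * 71, "t_value": 0.0, "mean_diff": 0.0})
        assert profiling.select_fois(res, alpha=0.05)["selected"].sum() == 0

    def test_selection_is_permutation_invariant(self, rng):
        res = pd.DataFrame({"p_value": rng.random(20) * 0.01,
                            "t_value": 0.0, "mean_diff": 0.0},
                           index=[f"t{i}" for i in range(20)])
        out1 = profiling.select_fois(res, alpha=0.05)
        shuffled = res.sample(frac=1, random_state=3)
        out2 = profiling.select_fois(shuffled, alpha=0.05)
        assert set(out1.index[out1.selected]) == set(out2.index[out2.selected])


class TestCenteredProfiles:
    def test_arithmetic(self):
        hc = pd.DataFrame({"UF_ipsi": [0.5, 0.5, 0.5]}, index=["h1", "h2", "h3"])
        pat = pd.DataFrame({"UF_ipsi": [0.42, 0.5]}, index=["p1", "p2"])
        prof = profiling.centered_profiles(hc, pat)
        assert prof.loc["UF_ipsi", "p1"] == pytest.approx(-0.08)
        assert prof.loc["UF_ipsi", "p2"] == pytest.approx(0.0)

    def test_missing_pairing_is_an_error(self):
        hc = pd.DataFrame({"A": [1.0, 2.0]})
        pat = pd.DataFrame({"A": [1.0], "B": [2.0]})
        with pytest.raises(KeyError):
            profiling.centered_profiles(hc, pat, ["A", "B"])

    def test_matches_per_tract_brute_force(self, rng):
        hc = pd.DataFrame(rng.random((8, 5)), columns=list("abcde"))
        pat = pd.DataFrame(rng.random((4, 5)), columns=list("abcde"))
        prof = profiling.centered_profiles(hc, pat)
        for tract in "abcde":
            for j in range(4):
                expected = pat[tract].iloc[j] - hc[tract].mean()
                assert prof.loc[tract].iloc[j] == pytest.approx(expected, abs=1e-12)


class TestClustering:
    def test_two_planted_groups_recovered(self, rng):
        a = np.tile([0.0, 0.0, 0.0, 0.0], (4, 1))
        b = np.tile([9.0, 9.0, 9.0, 9.0], (4, 1))
        prof = pd.DataFrame(np.vstack([a, b]), index=[f"t{i}" for i in range(8)])
        sol = profiling.hierarchical_cluster(prof, k=2)
        assert sol.assignment.iloc[:4].nunique() == 1
        assert sol.assignment.iloc[4:].nunique() == 1
        assert sol.assignment.iloc[0] != sol.assignment.iloc[-1]

    def test_duplicate_rows_always_cocluster(self, rng):
        x = rng.random((5, 6))
        prof = pd.DataFrame(np.vstack([x, x[0]]), index=[f"t{i}" for i in range(6)])
        sol = profiling.hierarchical_cluster(prof, k=3)
        assert sol.assignment.iloc[0] == sol.assignment.iloc[5]
        assert sol.linkage_tree.shape == (5, 4)  # n-1 merges

    def test_three_planted_patterns_recovered_up_to_permutation(self):
        prof, truth = planted_pattern_profiles(12, 3, 10, separation=8.0, seed=2)
        sol = profiling.hierarchical_cluster(prof, k=3)
        table = pd.crosstab(sol.assignment, truth)
        assert (table.to_numpy() > 0).sum() == 3  # one-to-one blocks

    def test_order_invariance_up_to_label_permutation(self):
        prof, _ = planted_pattern_profiles(12, 3, 10, separation=8.0, seed=4)
        sol1 = profiling.hierarchical_cluster(prof, k=3)
        shuffled = prof.sample(frac=1, random_state=9)
        sol2 = profiling.hierarchical_cluster(shuffled, k=3)
        a1 = sol1.assignment
        a2 = sol2.assignment.reindex(a1.index)
        # same partition: co-membership matrices agree
        co1 = np.equal.outer(a1.to_numpy(), a1.to_numpy())
        co2 = np.equal.outer(a2.to_numpy(), a2.to_numpy())
        assert np.array_equal(co1, co2)

    def test_k_larger_than_n_rejected(self):
        prof = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            profiling.hierarchical_cluster(prof, k=5)


class TestElbow:
    def test_knee_of_explicit_dispersion_sequence(self):
        k, flat = profiling.knee_point(np.arange(1, 7),
                                       np.array([100.0, 40, 12, 11, 10, 9]))
        assert (k, flat) == (3, False)

    def test_three_planted_patterns_give_k3(self):
        prof, _ = planted_pattern_profiles(25, 3, 18, separation=3.0, seed=7)
        assert profiling.select_k_elbow(prof, range(2, 9)) == 3

    def test_two_planted_patterns_give_k2(self):
        prof, _ = planted_pattern_profiles(20, 2, 15, separation=6.0, seed=5)
        assert profiling.select_k_elbow(prof, range(2, 9)) == 2

    def test_flat_curve_warns_and_returns_smallest(self):
        k, flat = profiling.knee_point(np.arange(1, 6),
                                       np.array([10.0, 10, 10, 10, 10]))
        assert flat and k == 1


class TestClusterValidation:
    def test_separated_identical_profile_clusters_score_one(self):
        a = np.tile([0.0] * 5, (4, 1)) + 1e-9 * np.arange(4)[:, None]
        b = a + 1e6
        prof = pd.DataFrame(np.vstack([a, b]))
        sol = profiling.hierarchical_cluster(prof, k=2)
        sil, inter = profiling.cluster_validation(sol, prof)
        assert sil == pytest.approx(1.0, abs=1e-6)

    def test_intercluster_matrix_symmetric_zero_diagonal(self):
        prof, _ = planted_pattern_profiles(12, 3, 10, separation=5.0, seed=1)
        sol = profiling.hierarchical_cluster(prof, k=3)
        _, inter = profiling.cluster_validation(sol, prof)
        assert np.allclose(inter, inter.T)
        assert np.allclose(np.diag(inter), 0)

    def test_forced_split_of_single_cluster_scores_near_zero(self, rng):
        prof = pd.DataFrame(rng.standard_normal((30, 8)))
        sol = profiling.hierarchical_cluster(prof, k=2)
        sil, _ = profiling.cluster_validation(sol, prof)
        assert abs(sil) < 0.35

    def test_singleton_cluster_flagged(self, rng):
        x = rng.standard_normal((5, 4))
        x[4] += 50  # an outlier forced into its own cluster
        prof = pd.DataFrame(x)
        sol = profiling.hierarchical_cluster(prof, k=2)
        if (np.bincount(sol.assignment.to_numpy())[1:] == 1).any():
            with pytest.warns(UserWarning, match="singleton"):
                profiling.cluster_validation(sol, prof)
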