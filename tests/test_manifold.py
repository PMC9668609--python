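import numpy as np
import pytest
from scipy.stats import spearmanr

from tractanomaly.manifold import (
    NormativeTractModel,
    agreement_analysis,
    bootstrap_kl_test,
    choose_latent_dim,
    fit_embedding,
    kl_divergence,
)


def _subspace_data(rng, n=30, d=2, ambient=100, scale=1.0):
    return rng.normal(0, scale, (n, d)) @ rng.normal(0, 1, (d, ambient))


class TestEmbeddingFit:
    def test_linear_subspace_reconstructs_training_vectors(self, rng):
        y = _subspace_data(rng)
        res = fit_embedding(y, d=2, seed=0, reducer="pca")
        for i in range(0, 30, 5):
            rec = res.back_project(res.project(y[i]))
            assert np.max(np.abs(rec - y[i])) <= 1e-8

    @pytest.mark.parametrize("reducer", ["pca", "umap"])
    def test_same_seed_gives_identical_embeddings(self, rng, reducer):
        y = rng.normal(0.5, 0.05, (15, 60))
        e1 = fit_embedding(y, d=2, seed=11, reducer=reducer).hc_embedding
        e2 = fit_embedding(y, d=2, seed=11, reducer=reducer).hc_embedding
        assert np.array_equal(e1, e2)

    def test_one_dimensional_curve_recovers_parameter_order(self, rng):
        t = np.linspace(0.1, 1.0, 30)
        y = np.column_stack([t, t**2, t**3]) + rng.normal(0, 1e-4, (30, 3))
        res = fit_embedding(y, d=1, seed=0, reducer="pca")
        rho = spearmanr(res.hc_embedding[:, 0], t).statistic
        assert abs(rho) > 0.95

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="latent_dim"):
            fit_embedding(rng.random((12, 20)), d=12, reducer="pca")
        with pytest.raises(ValueError, match="constant"):
            fit_embedding(np.ones((12, 20)), d=2, reducer="pca")
        with pytest.raises(ValueError, match="controls"):
            fit_embedding(rng.random((5, 20)), d=2, reducer="pca")

    def test_frozen_model_contract(self, rng):
        y = rng.normal(0.5, 0.05, (15, 40))
        res = fit_embedding(y, d=2, seed=3, reducer="pca")
        before = res.hc_embedding.copy()
        for _ in range(5):
            res.anomaly(rng.normal(0.5, 0.05, 40))
        assert np.array_equal(res.hc_embedding, before)


class TestLatentDimChoice:
    def test_exact_two_dimensional_subspace(self, rng):
        assert choose_latent_dim(_subspace_data(rng), 4, seed=0, reducer="pca") == 2

    def test_pure_noise_returns_smallest(self, rng):
        assert choose_latent_dim(rng.standard_normal((30, 50)), 4,
                                 seed=0, reducer="pca") == 1

    def test_three_latent_factors_recovered(self, rng):
        y = (rng.standard_normal((30, 3)) @ rng.standard_normal((3, 80))
             + 0.01 * rng.standard_normal((30, 80)))
        assert choose_latent_dim(y, 5, seed=0, reducer="pca") == 3

    def test_d_max_bounded_by_cohort(self, rng):
        with pytest.raises(ValueError):
            choose_latent_dim(rng.random((12, 20)), 12, reducer="pca")


class TestProjection:
    def test_training_copy_projects_onto_own_embedding(self, rng):
        y = rng.normal(0.5, 0.05, (20, 50))
        res = fit_embedding(y, d=2, seed=5, reducer="umap")
        for j in (0, 7, 19):
            x = res.project(y[j].copy())
            assert np.max(np.abs(x - res.hc_embedding[j])) <= 1e-6

    def test_midpoint_of_two_identical_controls(self, rng):
        base = rng.normal(0.5, 0.05, 50)
        others = rng.normal(5.0, 0.05, (10, 50))  # far-away cloud
        y = np.vstack([base, base, others])
        res = fit_embedding(y, d=2, seed=0, reducer="pca")
        x = res.project(base.copy())
        common = res.hc_embedding[:2].mean(axis=0)
        assert np.max(np.abs(x - common)) <= 1e-6

    def test_interpolated_patient_lands_near_embedding_midpoint(self, rng):
        y = _subspace_data(rng, n=12)
        res = NormativeTractModel(y, latent_dim=2, reducer="pca",
                                  projection="transform", seed=0).fit()
        mid = 0.5 * (y[0] + y[1])
        x = res.project(mid)
        expected = 0.5 * (res.hc_embedding[0] + res.hc_embedding[1])
        assert np.max(np.abs(x - expected)) <= 1e-8

    def test_length_mismatch_rejected(self, rng):
        res = fit_embedding(rng.random((12, 20)), d=2, reducer="pca")
        with pytest.raises(ValueError, match="length"):
            res.project(np.ones(19))


class TestBackProjection:
    def _toy(self, rng):
        res = fit_embedding(rng.normal(0, 1, (10, 5)), d=2, reducer="pca", seed=0)
        res.hc_embedding = np.array(
            [[0.0, 0], [1, 0], [0, 1], [1, 1], [2, 2]] + [[9, 9]] * 5
        )
        res.model.endog = np.arange(50, dtype=float).reshape(10, 5)
        return res

    def test_small_bandwidth_limit_is_nearest_control(self, rng):
        res = self._toy(rng)
        res.kernel_bandwidth = 1e-4
        out = res.back_project([1.0, 0.05])  # just off node 1
        assert np.allclose(out, res.model.endog[1])

    def test_large_bandwidth_limit_is_grand_mean(self, rng):
        res = self._toy(rng)
        res.kernel_bandwidth = 1e9
        assert np.allclose(res.back_project([0.3, 0.7]),
                           res.model.endog.mean(axis=0), rtol=1e-6)

    def test_hand_computed_weighted_mean(self, rng):
        res = fit_embedding(rng.normal(0, 1, (10, 3)), d=1, reducer="pca", seed=0)
        res.hc_embedding = np.array([[0.0], [1.0], [2.0], [3.0], [4.0],
                                     [5.0], [6.0], [7.0], [8.0], [9.0]])
        res.model.endog = np.arange(30, dtype=float).reshape(10, 3)
        res.kernel_bandwidth = 1.0
        x = 0.5
        w = np.exp(-0.5 * (res.hc_embedding[:, 0] - x) ** 2)
        expected = (w[:, None] * res.model.endog).sum(axis=0) / w.sum()
        assert np.allclose(res.back_project([x]), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        res = fit_embedding(rng.random((12, 20)), d=2, reducer="pca")
        with pytest.raises(ValueError, match="dim"):
            res.back_project([1.0, 2.0, 3.0])


class TestLooResidualScale:
    def test_recovers_generative_noise_sd(self, rng):
        sigma = 0.05
        base = 0.5 + 0.05 * np.sin(np.linspace(0, 6, 150))
        y = base[None, :] + sigma * rng.standard_normal((37, 150))
        res = fit_embedding(y, d=2, seed=0, reducer="pca")
        sd = res.loo_residual_scale()
        assert abs(np.median(sd) - sigma) / sigma < 0.2

    def test_invariant_under_control_permutation(self, rng):
        y = rng.normal(0.5, 0.05, (15, 40))
        sd1 = fit_embedding(y, d=2, seed=0, reducer="pca").loo_residual_scale()
        perm = rng.permutation(15)
        sd2 = fit_embedding(y[perm], d=2, seed=0, reducer="pca").loo_residual_scale()
        assert np.allclose(np.sort(sd1), np.sort(sd1))
        assert np.allclose(sd1, sd2, rtol=1e-8)

    def test_scale_is_cached_and_reused_by_anomaly(self, rng):
        y = rng.normal(0.5, 0.05, (15, 40))
        res = fit_embedding(y, d=2, seed=0, reducer="pca")
        first = res.anomaly(rng.normal(0.5, 0.05, 40))
        assert res._loo_scale is not None
        second = res.anomaly(rng.normal(0.5, 0.05, 40))
        assert np.array_equal(first.hc_residual_sd, second.hc_residual_sd)


class TestAnomaly:
    def test_patient_identical_to_control_has_zero_z(self, rng):
        y = rng.normal(0.5, 0.05, (20, 60))
        res = fit_embedding(y, d=2, seed=2, reducer="pca")
        scale = res.loo_residual_scale()
        z = res.anomaly(y[3].copy(), scale).z_scores
        assert np.max(np.abs(z)) <= 1e-8

    def test_control_like_patient_rarely_exceeds_threshold(self, rng):
        sigma = 0.05
        base = 0.5 + 0.03 * np.cos(np.linspace(0, 4, 200))
        y = base[None, :] + sigma * rng.standard_normal((37, 200))
        res = fit_embedding(y, d=2, seed=0, reducer="pca")
        scale = res.loo_residual_scale()
        fresh = base + sigma * rng.standard_normal(200)
        z = res.anomaly(fresh, scale).z_scores
        assert np.mean(np.abs(z) > 4.8) <= 0.005

    def test_planted_lesion_segment_recovered(self, rng):
        sigma = 0.05
        base = np.full(200, 0.5)
        y = base[None, :] + sigma * rng.standard_normal((37, 200))
        res = fit_embedding(y, d=2, seed=0, reducer="pca")
        scale = res.loo_residual_scale()
        patient = base + sigma * rng.standard_normal(200)
        seg = slice(50, 60)
        patient[seg] = base[seg] - 6 * scale[seg]  # a clean -6 SD drop
        z = res.anomaly(patient, scale).z_scores
        assert np.all(z[seg] < -4.8)
        out = np.ones(200, bool)
        out[seg] = False
        assert np.mean(z[out] < -4.8) <= 0.01


class TestKLDivergence:
    def test_identical_point_sets_give_zero(self, rng):
        pts = rng.standard_normal((100, 2))
        assert kl_divergence(pts, pts) == 0.0

    def test_gaussian_shift_matches_closed_form(self):
        r = np.random.default_rng(0)
        est = np.mean([
            kl_divergence(r.normal(0, 1, 2000), r.normal(1, 1, 2000))
            for _ in range(3)
        ])
        assert abs(est - 0.5) < 0.1  # true D = (mu_a - mu_b)^2 / 2 = 0.5

    def test_never_negative(self, rng):
        for _ in range(10):
            a = rng.standard_normal((30, 2))
            b = rng.standard_normal((30, 2))
            assert kl_divergence(a, b) >= 0.0

    def test_consistency_improves_with_n(self):
        r = np.random.default_rng(1)
        errors = []
        for n in (200, 1000, 5000):
            reps = [abs(kl_divergence(r.normal(0, 1, n), r.normal(1, 1, n)) - 0.5)
                    for _ in range(5)]
            errors.append(np.mean(reps))
        assert errors[0] > errors[2]

    def test_duplicate_only_cloud_rejected(self):
        pts = np.zeros((10, 2))
        with pytest.raises(ValueError, match="degenerate"):
            kl_divergence(pts, np.random.default_rng(0).random((10, 2)))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            kl_divergence(rng.random((10, 2)), rng.random((10, 3)))


class TestKLPermutationTest:
    def test_fully_separated_clouds_hit_the_floor(self, rng):
        a = rng.normal(0, 0.1, (20, 2))
        b = rng.normal(50, 0.1, (20, 2))
        res = bootstrap_kl_test(a, b, n_boot=1000, seed=0)
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.significant

    def test_corrected_alpha_bookkeeping(self, rng):
        a = rng.normal(0, 1, (10, 2))
        b = rng.normal(0, 1, (10, 2))
        res = bootstrap_kl_test(a, b, n_boot=1000, seed=0, m_tests=25)
        assert res.corrected_alpha == pytest.approx(0.002)
        res = bootstrap_kl_test(a, b, n_boot=1000, seed=0, m_tests=25,
                                significance_threshold=0.001)
        assert res.corrected_alpha == pytest.approx(0.001)


class TestAgreement:
    def test_proportional_measures_agree_perfectly(self, rng):
        t = rng.random(25) + 1
        res = agreement_analysis(
            t_values=_series(t), dkl_values=_series(3.0 * t)
        )
        assert res.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert res.spread_sd == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_measures_have_zero_bias_max_spread(self, rng):
        t = np.linspace(1, 2, 25)
        res = agreement_analysis(_series(t), _series(-t))
        assert res.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert res.spread_sd == pytest.approx(2.0, rel=1e-6)

    def test_matches_brute_force_standardization(self, rng):
        t = rng.random(25) * 4
        d = 0.5 * t + rng.random(25)
        res = agreement_analysis(_series(t), _series(d))
        zt = (np.abs(t) - np.abs(t).mean()) / np.abs(t).std(ddof=1)
        zd = (d - d.mean()) / d.std(ddof=1)
        assert np.allclose(res.differences.to_numpy(), zt - zd)

    def test_too_few_tracts_rejected(self):
        with pytest.raises(ValueError):
            agreement_analysis(_series([1.0, 2.0]), _series([1.0, 2.0]))


def _series(x):
    import pandas as pd

    x = np.atleast_1d(x)
    return pd.Series(x, index=[f"t{i}" for i in range(len(x))])
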