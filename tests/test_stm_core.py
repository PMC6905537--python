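import numpy as np
import pytest

from microstm.io_prep import OtuTable, build_design_matrix
from microstm.stm_core import (
    StmConfig, fit_stm, heldout_likelihood, load_fit,
    permutation_test_sample_effect, refit_theta, residual_dispersion,
    sample_theta, sample_tokens, save_fit,
)
from conftest import make_binary_dataset, match_topics


class TestFit:
    def test_rows_are_simplices(self, planted_dataset):
        _, _, fit = planted_dataset
        np.testing.assert_allclose(fit.theta.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(fit.beta.sum(axis=1), 1.0, atol=1e-8)

    def test_sigma_positive_definite(self, planted_dataset):
        _, _, fit = planted_dataset
        assert np.linalg.eigvalsh(fit.sigma).min() > 0
        np.testing.assert_allclose(fit.sigma, fit.sigma.T)

    def test_elbo_monotone_within_tolerance(self, planted_dataset):
        _, _, fit = planted_dataset
        e = np.asarray(fit.elbo_trace)
        tol = 1e-6 * np.abs(e).max()
        assert np.all(np.diff(e) >= -tol)

    def test_same_seed_bit_identical(self):
        ds, X = make_binary_dataset(40, 25, 3, effect=0.5, seed=11)
        cfg = StmConfig(K=3, seed=11)
        a = fit_stm(ds.table, X, cfg)
        b = fit_stm(ds.table, X, cfg)
        assert a.elbo_trace == b.elbo_trace
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_sample_permutation_equivariance(self):
        ds, X = make_binary_dataset(40, 25, 3, effect=0.5, seed=12)
        cfg = StmConfig(K=3, seed=12)
        fit = fit_stm(ds.table, X, cfg)
        perm = np.random.default_rng(0).permutation(40)
        tp = ds.table.subset(sample_idx=perm)
        Xp = build_design_matrix(tp.metadata, [("dx", "identity")])
        fitp = fit_stm(tp, Xp, cfg)
        np.testing.assert_allclose(fitp.theta, fit.theta[perm], atol=1e-8)
        np.testing.assert_allclose(fitp.beta, fit.beta, atol=1e-8)

    def test_beta_recovery_on_planted_data(self, planted_dataset):
        ds, _, fit = planted_dataset
        _, tv = match_topics(fit.beta, ds.beta)
        assert tv.mean() <= 0.15

    def test_k_too_large_errors(self, small_table):
        with pytest.raises(ValueError, match="K"):
            fit_stm(small_table, None, StmConfig(K=2))

    def test_rank_deficient_design_errors(self, planted_dataset):
        ds, X, _ = planted_dataset
        from microstm.io_prep import DesignMatrix
        Xbad = DesignMatrix(np.column_stack([X.X, X.X[:, 1]]),
                            X.column_spec + [("dup", "identity", "dx")],
                            X.sample_ids)
        with pytest.raises(ValueError, match="rank"):
            fit_stm(ds.table, Xbad, StmConfig(K=3))

    def test_save_load_round_trip(self, planted_dataset, tmp_path):
        _, _, fit = planted_dataset
        save_fit(fit, tmp_path / "fit.json")
        back = load_fit(tmp_path / "fit.json")
        np.testing.assert_allclose(back.theta, fit.theta)
        np.testing.assert_allclose(back.beta, fit.beta)
        assert back.config == fit.config
        assert back.vocabulary == fit.vocabulary


class TestRefitTheta:
    def test_training_table_is_fixed_point(self, planted_dataset):
        ds, X, fit = planted_dataset
        rf = refit_theta(fit, ds.table, X)
        assert np.abs(rf.theta - fit.theta).max() < 1e-6

    def test_topic_concentrated_sample(self, planted_dataset):
        ds, _, fit = planted_dataset
        # a sample made only of topic-2 top OTUs loads on topic 2
        top = np.argsort(fit.beta[2])[::-1][:10]
        counts = np.zeros((1, len(ds.table.otu_ids)))
        counts[0, top] = 200
        t_new = OtuTable(counts, ["new"], list(ds.table.otu_ids),
                         dict(ds.table.taxonomy))
        rf = refit_theta(fit, t_new)
        assert rf.theta[0].argmax() == 2

    def test_zero_overlap_errors(self, planted_dataset):
        _, _, fit = planted_dataset
        t_new = OtuTable(np.ones((1, 2)), ["n"], ["Z1", "Z2"])
        with pytest.raises(ValueError, match="overlap"):
            refit_theta(fit, t_new)

    def test_unseen_otus_dropped_with_warning(self, planted_dataset):
        ds, _, fit = planted_dataset
        counts = np.column_stack([ds.table.counts[:2], [5.0, 5.0]])
        t_new = OtuTable(counts, ds.table.sample_ids[:2],
                         list(ds.table.otu_ids) + ["NEW"],
                         dict(ds.table.taxonomy))
        with pytest.warns(UserWarning, match="dropping"):
            rf = refit_theta(fit, t_new)
        assert rf.theta.shape == (2, fit.K)


class TestHeldout:
    def test_fitted_beats_uniform_topics(self, planted_dataset):
        ds, X, fit = planted_dataset
        ll = heldout_likelihood(fit, ds.table, X, seed=1)
        ll_unif = heldout_likelihood(fit, ds.table, X, seed=1,
                                     beta=np.full(fit.beta.shape, 1 / fit.V))
        assert ll > ll_unif

    def test_deterministic_under_seed(self, planted_dataset):
        ds, X, fit = planted_dataset
        assert heldout_likelihood(fit, ds.table, X, seed=2) == \
            heldout_likelihood(fit, ds.table, X, seed=2)

    def test_single_otu_sample_errors(self, planted_dataset):
        _, _, fit = planted_dataset
        t = OtuTable(np.array([[40.0]]), ["s"], [fit.vocabulary[0]])
        with pytest.raises(ValueError, match="2 distinct"):
            heldout_likelihood(fit, t)

    def test_bad_fraction_errors(self, planted_dataset):
        ds, X, fit = planted_dataset
        with pytest.raises(ValueError, match="frac"):
            heldout_likelihood(fit, ds.table, X, frac_heldout_tokens=1.0)


class TestPosteriorSampling:
    def test_monte_carlo_mean_matches_theta(self, planted_dataset):
        _, _, fit = planted_dataset
        draws = sample_theta(fit, 0, 10000, seed=3)
        assert np.abs(draws.mean(axis=0) - fit.theta[0]).max() < 0.02

    def test_draws_are_simplices(self, planted_dataset):
        _, _, fit = planted_dataset
        draws = sample_theta(fit, 1, 50, seed=4)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)

    def test_degenerate_covariance_gives_constant_draws(self, tiny_fit):
        draws = sample_theta(tiny_fit, 0, 20, seed=5)
        np.testing.assert_allclose(draws, np.tile(tiny_fit.theta[0], (20, 1)), atol=1e-12)

    def test_nonpositive_draws_errors(self, tiny_fit):
        with pytest.raises(ValueError):
            sample_theta(tiny_fit, 0, 0)

    def test_degenerate_theta_all_tokens_one_topic(self, tiny_fit):
        draw = sample_tokens(tiny_fit, np.array([1.0, 0.0]), 50, seed=6)
        assert np.all(draw.z == 0)

    def test_point_mass_beta_forces_otu(self, tiny_fit):
        tiny_fit.beta[0] = [1.0, 0.0, 0.0]
        draw = sample_tokens(tiny_fit, np.array([1.0, 0.0]), 30, seed=7)
        assert set(draw.w_sim) == {"A"}

    def test_token_frequencies_converge_to_mixture(self, planted_dataset):
        _, _, fit = planted_dataset
        theta = fit.theta[0]
        draw = sample_tokens(fit, theta, 10 ** 5, seed=8)
        idx = {o: j for j, o in enumerate(fit.vocabulary)}
        freq = np.bincount([idx[o] for o in draw.w_sim], minlength=fit.V) / 1e5
        assert np.abs(freq - theta @ fit.beta).max() < 0.01

    def test_nonpositive_tokens_errors(self, tiny_fit):
        with pytest.raises(ValueError):
            sample_tokens(tiny_fit, np.array([0.5, 0.5]), 0)


class TestDiagnostics:
    def test_dispersion_near_one_for_self_simulated(self, planted_dataset):
        ds, _, fit = planted_dataset
        rng = np.random.default_rng(9)
        mix = fit.theta @ fit.beta
        N = ds.table.counts.sum(axis=1).astype(int)
        sim = np.array([rng.multinomial(N[m], mix[m]) for m in range(fit.M)])
        t = OtuTable(sim.astype(float), ds.table.sample_ids, ds.table.otu_ids,
                     dict(ds.table.taxonomy))
        assert 0.8 <= residual_dispersion(fit, t) <= 1.2

    def test_dispersion_flags_extra_noise(self, planted_dataset):
        ds, _, fit = planted_dataset
        rng = np.random.default_rng(10)
        mix = fit.theta @ fit.beta
        noisy = mix * rng.gamma(2.0, 0.5, size=mix.shape)
        noisy /= noisy.sum(axis=1, keepdims=True)
        N = ds.table.counts.sum(axis=1).astype(int)
        sim = np.array([rng.multinomial(N[m], noisy[m]) for m in range(fit.M)])
        t = OtuTable(sim.astype(float), ds.table.sample_ids, ds.table.otu_ids,
                     dict(ds.table.taxonomy))
        assert residual_dispersion(fit, t) > 1.5

    def test_dispersion_shape_mismatch_errors(self, planted_dataset, small_table):
        _, _, fit = planted_dataset
        with pytest.raises(ValueError, match="shape"):
            residual_dispersion(fit, small_table)

    def test_permutation_test_shapes_and_errors(self):
        ds, X = make_binary_dataset(40, 25, 2, effect=0.0, seed=20)
        cfg = StmConfig(K=2, seed=20, max_em_iter=40)
        res = permutation_test_sample_effect(ds.table, X, "dx", cfg, n_perm=2,
                                             seed=0, n_effect_draws=30)
        assert res["observed"].shape == (2,)
        assert res["null"].shape == (2, 2)
        assert np.all(np.isfinite(res["null"]))
        with pytest.raises(ValueError):
            permutation_test_sample_effect(ds.table, X, "dx", cfg, n_perm=0)
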