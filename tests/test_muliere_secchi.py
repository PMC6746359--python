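import numpy as np
import pytest
from scipy import stats

from bayesdr import (
    ModelSpec,
    ObservationalDataset,
    PriorSpec,
    empirical_posterior,
    gamma_reweight,
    mix_prior,
    posterior_ate_pipeline,
    posterior_predictive_ate,
)
from bayesdr.bayes_bootstrap import EmpiricalPosterior
from bayesdr.muliere_secchi import ATEPosterior, MixturePosterior
from bayesdr.simulation_study import DGPParams, generate_sim_dataset

OR_FULL = ModelSpec("identity", ("x",))


def _fake_pn(L=200, seed=0):
    """An empirical posterior with known Normal(5, 0.2) treatment draws."""
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [rng.normal(10, 0.1, L), rng.normal(5.0, 0.2, L), rng.normal(0.2, 0.05, L)]
    )
    data = generate_sim_dataset(DGPParams(n=200), rng)
    pn = empirical_posterior(data, OR_FULL, L=2, rng=rng)
    return EmpiricalPosterior(draws, L, pn.kappa_used, pn.fit)


class TestMixPrior:
    def test_zero_faith_resamples_pn_only(self, rng):
        pn = _fake_pn()
        prior = PriorSpec(1, loc=0.0, scale=1.0, faith=0.0)
        support, origin = mix_prior(pn, prior, 500, rng, return_origin=True)
        assert not origin.any()
        # every support row is literally a pn row
        assert all(any(np.array_equal(s, r) for r in pn.draws) for s in support[:20])

    def test_infinite_faith_recovers_prior_marginal(self, rng):
        pn = _fake_pn()
        prior = PriorSpec(1, loc=-3.0, scale=0.5, faith=1e9)
        support = mix_prior(pn, prior, 10_000, rng)
        ref = prior.sample(10_000, rng)
        assert stats.ks_2samp(support[:, 1], ref).pvalue > 0.01

    def test_equal_faith_splits_half(self, rng):
        pn = _fake_pn(L=200)
        prior = PriorSpec(1, loc=0.0, scale=1.0, faith=200.0)
        _, origin = mix_prior(pn, prior, 10_000, rng, return_origin=True)
        frac = origin.mean()
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / 10_000)

    def test_non_target_coordinates_come_from_pn(self, rng):
        pn = _fake_pn()
        prior = PriorSpec(1, loc=1000.0, scale=0.1, faith=1e9)
        support = mix_prior(pn, prior, 200, rng)
        assert set(np.round(support[:, 0], 6)) <= set(np.round(pn.draws[:, 0], 6))

    def test_negative_faith_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(1, 0.0, 1.0, faith=-1.0)


class TestGammaReweight:
    def test_gamma_mass_mean(self, rng):
        # E[v_i] = (L+k)/m; pool 10^5 mass draws over repeated reweightings
        m, L, k = 200, 200, 1.0
        support = np.zeros((m, 1))
        masses = np.concatenate(
            [gamma_reweight(support, L, k, rng).gamma_weights for _ in range(500)]
        )
        assert masses.mean() == pytest.approx((L + k) / m, rel=0.01)

    def test_single_support_row_is_point_mass(self, rng):
        support = np.array([[1.0, 2.0]])
        pm = gamma_reweight(support, 200, 1.0, rng)
        np.testing.assert_array_equal(pm.resampled, support)
        np.testing.assert_array_equal(pm.sample(5, rng), np.tile(support, (5, 1)))

    def test_low_faith_close_to_plain_resampling(self, rng):
        # a single p_m is a finite random measure with total mass ~ L+k, so
        # its draws are exchangeable but dependent; the marginal law over
        # independent reweightings is what matches plain p_n resampling
        pn = _fake_pn(L=200)
        prior = PriorSpec(1, 5.0, 10.0, faith=1.0)
        marginal = np.array(
            [
                gamma_reweight(
                    mix_prior(pn, prior, 200, rng), 200, 1.0, rng
                ).sample(1, rng)[0, 1]
                for _ in range(4000)
            ]
        )
        direct = pn.draws[rng.integers(0, pn.L, 4000), 1]
        ks = stats.ks_2samp(marginal, direct).statistic
        assert ks < 0.05


class TestPosteriorPredictive:
    def test_identity_link_draws_are_treatment_coordinates(self, rng):
        pn = _fake_pn()
        data = generate_sim_dataset(DGPParams(n=300), np.random.default_rng(3))
        pm = gamma_reweight(pn.draws, pn.L, 0.0, rng)
        post = posterior_predictive_ate(pm, data, OR_FULL, V=50, M=500, rng=rng)
        treat_vals = np.round(pn.draws[:, 1], 12)
        assert set(np.round(post.draws, 12)) <= set(treat_vals)

    def test_log_link_point_mass_hand_oracle(self, rng):
        # point mass at xi=(0, ln 3, 1), covariates {0, ln 2}: per-unit
        # contrasts are exactly 2 and 4, so a V=2 resample averages to one of
        # {2, 3, 4} and the posterior predictive mean is the hand value 3
        x = np.array([0.0, np.log(2.0)])
        data = ObservationalDataset(np.ones(2), np.array([1, 0]), x[:, None], ("x",))
        xi = np.array([[0.0, np.log(3.0), 1.0]])
        pm = MixturePosterior(xi, np.array([1.0]), xi.copy())
        post = posterior_predictive_ate(
            pm, data, ModelSpec("log", ("x",)), V=2, M=400, rng=rng
        )
        assert set(np.round(post.draws, 9)) <= {2.0, 3.0, 4.0}
        assert post.mean == pytest.approx(3.0, abs=0.15)

    def test_zero_faith_matches_pn_resampling_distribution(self):
        data = generate_sim_dataset(DGPParams(n=500), np.random.default_rng(40))
        rng = np.random.default_rng(41)
        pn = empirical_posterior(data, OR_FULL, L=200, rng=rng)
        pm = gamma_reweight(mix_prior(pn, None, 200, rng), 200, 0.0, rng)
        post = posterior_predictive_ate(pm, data, OR_FULL, M=5000, rng=rng)
        res = stats.ks_2samp(post.draws, pn.treatment_draws())
        assert res.pvalue > 0.01

    def test_summaries_are_pure_functions_of_draws(self, rng):
        post = ATEPosterior(np.arange(101, dtype=float), V=10)
        assert post.summaries == post.summarize()
        assert post.credible_interval == (
            pytest.approx(np.percentile(post.draws, 2.5)),
            pytest.approx(np.percentile(post.draws, 97.5)),
        )

    def test_posterior_histogram_export(self, rng, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from bayesdr.muliere_secchi import plot_posterior

        post = ATEPosterior(rng.normal(5, 0.2, 500), V=10)
        out = tmp_path / "posterior.png"
        plot_posterior(post, path=out)
        assert out.stat().st_size > 0

    def test_pipeline_centres_on_true_effect(self):
        data = generate_sim_dataset(DGPParams(n=1000), np.random.default_rng(42))
        prior = PriorSpec(1, 5.0, 10.0, faith=1.0)
        post = posterior_ate_pipeline(
            data, OR_FULL, L=200, prior=prior, rng=np.random.default_rng(43)
        )
        assert post.mean == pytest.approx(5.0, abs=0.7)
        lo, hi = post.credible_interval
        assert lo < post.mean < hi
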