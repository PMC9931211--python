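"""HPDI computation, posterior summaries, exceedance, chooser imputation,
and MCMC contracts (determinism, prior recovery)."""

import numpy as np
import pandas as pd
import pytest

import handclasp as hc
from handclasp.inference import (exceedance_prob, hpdi, impute_choosers,
                                 run_mcmc, summarize)
from handclasp.model import ModelSpec


def brute_force_hpdi(x, mass=0.95):
    """Independent oracle: scan every candidate window over the sorted
    sample and keep the shortest one containing >= ceil(mass*n) points."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    k = int(np.ceil(mass * n))
    best = (np.inf, None, None)
    for i in range(n):
        for j in range(i, n):
            if j - i + 1 >= k and x[j] - x[i] < best[0]:
                best = (x[j] - x[i], x[i], x[j])
    return best[1], best[2]


class TestHpdi:
    def test_degenerate_constant_sample(self):
        assert hpdi([3.0, 3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_standard_normal_quantiles(self):
        x = np.random.default_rng(0).standard_normal(10 ** 6)
        lo, hi = hpdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_exponential_is_left_anchored(self):
        x = np.random.default_rng(1).exponential(1.0, 100_000)
        lo, hi = hpdi(x, 0.95)
        assert lo < 0.01
        eq_lo, eq_hi = np.quantile(x, [0.025, 0.975])
        assert hi - lo < eq_hi - eq_lo

    @pytest.mark.parametrize("dist,n", [
        ("normal", 37), ("exponential", 200), ("uniform", 1000), ("normal", 2),
    ])
    def test_matches_brute_force(self, dist, n):
        rng = np.random.default_rng(hash(dist) % 2 ** 31)
        x = getattr(rng, dist)(size=n)
        assert hpdi(x, 0.95) == brute_force_hpdi(x, 0.95)
        assert hpdi(x, 0.5) == brute_force_hpdi(x, 0.5)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            hpdi([])

    def test_agrees_with_arviz(self):
        # arviz rounds the window size down where this implementation rounds
        # up, so agreement is to within one order statistic
        import arviz as az
        x = np.random.default_rng(5).standard_normal(5000)
        lo, hi = hpdi(x, 0.9)
        ref = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)


class TestExceedance:
    def test_identical_paired_is_zero(self):
        x = np.arange(10.0)
        assert exceedance_prob(x, x) == 0.0

    def test_shifted_is_one(self):
        x = np.arange(10.0)
        assert exceedance_prob(x + 1, x) == 1.0

    def test_independent_normals_near_half(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 2000))
        assert exceedance_prob(a, b, paired=False) == pytest.approx(0.5, abs=0.05)

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            exceedance_prob([1, 2], [1, 2, 3])


class TestRunMcmc:
    def test_same_seed_bit_identical(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("baseline")
        kw = dict(chains=2, iterations=20, burn_in=15, seed=77,
                  check_convergence=False)
        a = run_mcmc(spec, ds, **kw)
        b = run_mcmc(spec, ds, **kw)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_different_seed_differs(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("baseline")
        a = run_mcmc(spec, ds, chains=2, iterations=10, burn_in=10, seed=1,
                     check_convergence=False)
        b = run_mcmc(spec, ds, chains=2, iterations=10, burn_in=10, seed=2,
                     check_convergence=False)
        assert not np.array_equal(a.draws["mu"], b.draws["mu"])

    def test_thinning_keeps_requested_draws(self, small_dataset):
        ds, _ = small_dataset
        sample = run_mcmc(ModelSpec("baseline"), ds, chains=2, iterations=6,
                          burn_in=5, thin=3, seed=4, check_convergence=False)
        assert sample.draws["mu"].shape[:2] == (2, 6)
        assert sample.meta["thin"] == 3

    def test_draws_respect_prior_support(self, small_dataset):
        ds, _ = small_dataset
        sample = run_mcmc(ModelSpec("combined"), ds, chains=2, iterations=40,
                          burn_in=40, seed=3, check_convergence=False)
        assert (sample.draws["sigma_W"] > 0).all()
        assert (sample.draws["sigma_W"] < 10).all()
        assert (sample.draws["sigma_I"] > 0).all()
        assert (sample.draws["m"] >= 0).all() and (sample.draws["m"] <= 1).all()
        assert np.all(sample.draws["mu"][..., 0] == 0)
        assert np.all(sample.draws["W"][..., 0] == 0)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    ds, _ = small_dataset
    return run_mcmc(ModelSpec("baseline"), ds, chains=4, iterations=150,
                    burn_in=150, seed=9, check_convergence=False)


class TestSummarize:
    def test_mean_simplices_sum_to_one(self, fitted):
        tab = summarize(fitted).preferences
        for j in (1, 2):
            assert tab[f"group{j}_mean"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_difference_linearity(self, fitted):
        tab = summarize(fitted).preferences
        np.testing.assert_allclose(
            tab["diff_mean"], tab["group1_mean"] - tab["group2_mean"], atol=1e-12)

    def test_rows_in_variant_order(self, fitted):
        tab = summarize(fitted).preferences
        assert list(tab["k"]) == [1, 2, 3, 4, 5]
        assert list(tab["variant"]) == ["wrist", "elbow", "forearm", "other", "palm"]

    def test_single_chain_equals_split_chains(self, fitted):
        """Summaries depend only on the pooled draws, not the chain layout."""
        pooled = {k: v.reshape(1, -1, *v.shape[2:]) for k, v in fitted.draws.items()}
        resplit = {k: v.reshape(4, -1, *v.shape[2:]) for k, v in pooled.items()}
        one = hc.PosteriorSample(pooled, fitted.spec, fitted.arrays)
        four = hc.PosteriorSample(resplit, fitted.spec, fitted.arrays)
        pd.testing.assert_frame_equal(summarize(one).preferences,
                                      summarize(four).preferences)

    def test_one_draw_summary_is_the_draw(self, fitted):
        one = {k: v[:1, :1] for k, v in fitted.draws.items()}
        s = hc.PosteriorSample(one, fitted.spec, fitted.arrays)
        tab = summarize(s).preferences
        from handclasp.model import group_mean_transform
        expect = group_mean_transform(one["mu"][0, 0, 0])
        np.testing.assert_allclose(tab["group1_mean"], expect, atol=1e-12)
        np.testing.assert_allclose(tab["group1_lo"], expect, atol=1e-12)


class TestImputeChoosers:
    def test_analytic_example(self, small_dataset):
        """Uniform preferences and pi = 1/3 each: a concordant event has
        situation posterior (0.04, 0.2, 0.2)/0.44."""
        ds, _ = small_dataset
        spec = ModelSpec("baseline")
        arrays = hc.build_model_arrays(ds, spec)
        C, T = 2, 3
        draws = {
            "mu": np.zeros((C, T, arrays.n_groups, 5)),
            "W": np.zeros((C, T, arrays.n_slots, 5)),
            "beta": np.zeros((C, T, 4)),
            "I_RE": np.zeros((C, T, arrays.n_individuals)),
            "sigma_W": np.ones((C, T, 1)),
            "sigma_I": np.ones((C, T)),
        }
        sample = hc.PosteriorSample(draws, spec, arrays)
        probs = impute_choosers(sample)
        conc = arrays.concordant
        expect = np.array([0.04, 0.2, 0.2]) / 0.44
        np.testing.assert_allclose(probs[conc], np.tile(expect, (conc.sum(), 1)),
                                   atol=1e-12)
        np.testing.assert_allclose(probs[~conc],
                                   np.tile([1.0, 0, 0], ((~conc).sum(), 1)))

    def test_rows_are_probabilities(self, small_dataset):
        ds, _ = small_dataset
        sample = run_mcmc(ModelSpec("baseline"), ds, chains=2, iterations=30,
                          burn_in=30, seed=5, check_convergence=False)
        probs = impute_choosers(sample, max_draws=20)
        assert probs.shape == (ds.n_events, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)


@pytest.fixture(scope="module")
def prior_sample():
    empty = hc.Dataset(
        individuals=pd.DataFrame(columns=["id", "group", "sex", "mother_id",
                                          "birth_year"]),
        windows=pd.DataFrame(columns=["window_id", "year"]),
        ranks=pd.DataFrame(columns=["window_id", "individual_id", "rater_id",
                                    "ordinal_rank"]),
        events=pd.DataFrame(columns=["event_id", "window_id", "g1_id", "g2_id",
                                     "y_g1", "y_g2"]),
        n_groups=2,
    )
    return run_mcmc(ModelSpec("combined"), empty, chains=4, iterations=1500,
                    burn_in=500, seed=123, check_convergence=False)


class TestPriorRecovery:
    """With no individuals and no events the posterior is the prior."""

    def test_mu_prior_moments(self, prior_sample):
        mu = prior_sample.flat("mu")[:, :, 1:]
        assert abs(mu.mean()) < 3.0
        assert mu.std() == pytest.approx(np.sqrt(1000), rel=0.1)

    def test_sigma_priors_uniform(self, prior_sample):
        for draws in (prior_sample.flat("sigma_W").ravel(),
                      prior_sample.flat("sigma_I").ravel()):
            assert draws.min() > 0 and draws.max() < 10
            assert draws.mean() == pytest.approx(5.0, abs=0.6)
            assert draws.std() == pytest.approx(10 / np.sqrt(12), rel=0.15)

    def test_m_prior_uniform(self, prior_sample):
        m = prior_sample.flat("m")
        assert m.min() >= 0 and m.max() <= 1
        assert m.mean() == pytest.approx(0.5, abs=0.08)

    def test_beta_prior_moments(self, prior_sample):
        beta = prior_sample.flat("beta")
        assert np.abs(beta.mean(axis=0)).max() < 4.0
        np.testing.assert_allclose(beta.std(axis=0), np.sqrt(1000), rtol=0.15)
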