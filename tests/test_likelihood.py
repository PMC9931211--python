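"""The generative probability model: softmax preferences, influence,
latent-chooser mixture, priors, and the assembled log posterior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import handclasp as hc
from handclasp.model import (ModelSpec, build_model_arrays, chooser_probs,
                             event_pair_loglik, group_mean_transform, influence,
                             log_posterior, preference_prior_logdensity,
                             preference_probs)

finite = st.floats(min_value=-8, max_value=8)


def enumerated_pair_prob(y1, y2, p1, p2, pi):
    """Independent oracle: explicit sum over the three latent situations."""
    total = pi[0] * p1[y1 - 1] * p2[y2 - 1]                  # both choose
    if y1 == y2:
        total += pi[1] * p1[y1 - 1]                          # performer 1 chooses
        total += pi[2] * p2[y2 - 1]                          # performer 2 chooses
    return total


class TestPreferenceProbs:
    def test_uniform_at_zero(self):
        assert preference_probs(np.zeros(5)) == pytest.approx([0.2] * 5)

    def test_log2_doubles_category(self):
        p = preference_probs([0, np.log(2), 0, 0, 0])
        assert p == pytest.approx([1 / 6, 1 / 3, 1 / 6, 1 / 6, 1 / 6])

    def test_limit_case(self):
        p = preference_probs([0, -50, 0, 0, 0])
        assert p[1] == pytest.approx(0.0, abs=1e-12)
        assert p[[0, 2, 3, 4]] == pytest.approx([0.25] * 4, abs=1e-10)

    @given(st.lists(finite, min_size=4, max_size=4), st.floats(-300, 300))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_and_simplex(self, w, c):
        W = np.array([0.0, *w])
        p = preference_probs(W)
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()
        assert preference_probs(W + c) == pytest.approx(p)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            preference_probs([0, np.nan, 0, 0, 0])


class TestInfluence:
    def test_rank_ratio_matches_exp_beta(self):
        top = influence(0, 0, 1.0, 0, 0, beta_rank=2.78)
        bottom = influence(0, 0, 0.0, 0, 0, beta_rank=2.78)
        assert float(f"{top / bottom:.3g}") == 16.1

    def test_identity_at_zero(self):
        assert influence(0.3, 1, 0.5, 0, 0, 0) == 1.0

    def test_age_fold_change(self):
        ratio = influence(1.0, 0, 0, 0.440, 0, 0) / influence(0.0, 0, 0, 0.440, 0, 0)
        assert ratio == pytest.approx(np.exp(0.440))
        assert ratio == pytest.approx(1.553, abs=5e-4)


class TestChooserProbs:
    def test_symmetry(self):
        assert chooser_probs(1, 1, 0.0) == pytest.approx([1 / 3] * 3)

    def test_direct_evaluation(self):
        assert chooser_probs(2, 1, 0.0) == pytest.approx([0.25, 0.5, 0.25])

    def test_zero_influence_forces_independence(self):
        assert chooser_probs(0, 0, 0.0) == pytest.approx([1, 0, 0])

    @given(st.floats(0, 50), st.floats(0, 50), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_simplex(self, I1, I2, ba):
        pi = chooser_probs(I1, I2, ba)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi >= 0).all()

    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(-3, 3),
           st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, I1, I2, ba, c):
        """Scaling both influences and exp(beta_a) by c leaves pi unchanged."""
        base = chooser_probs(I1, I2, ba)
        scaled = chooser_probs(c * I1, c * I2, ba + np.log(c))
        assert scaled == pytest.approx(base)


class TestEventPairLoglik:
    def test_discordant_uniform(self):
        p = np.full(5, 0.2)
        pi = np.full(3, 1 / 3)
        assert np.exp(event_pair_loglik(1, 2, p, p, pi)) == pytest.approx((1 / 3) * 0.04)

    def test_concordant_uniform(self):
        p = np.full(5, 0.2)
        pi = np.full(3, 1 / 3)
        expected = (1 / 3) * 0.04 + (1 / 3) * 0.2 + (1 / 3) * 0.2
        assert np.exp(event_pair_loglik(3, 3, p, p, pi)) == pytest.approx(expected)

    def test_independence_limit_factorizes(self):
        rng = np.random.default_rng(0)
        p1 = preference_probs(np.concatenate([[0], rng.normal(0, 1, 4)]))
        p2 = preference_probs(np.concatenate([[0], rng.normal(0, 1, 4)]))
        for y1 in range(1, 6):
            for y2 in range(1, 6):
                ll = event_pair_loglik(y1, y2, p1, p2, [1, 0, 0])
                assert np.exp(ll) == pytest.approx(p1[y1 - 1] * p2[y2 - 1])

    def test_marginalization_oracle_randomized(self):
        """Closed-form marginal equals explicit enumeration over situations,
        and total probability over the 25 outcome pairs is 1."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(1000):
            p1 = preference_probs(np.concatenate([[0], rng.normal(0, 2, 4)]))
            p2 = preference_probs(np.concatenate([[0], rng.normal(0, 2, 4)]))
            pi = chooser_probs(*rng.gamma(1.0, 2.0, size=2), rng.normal(0, 1.5))
            y1, y2 = rng.integers(1, 6, size=2)
            ll = event_pair_loglik(y1, y2, p1, p2, pi)
            oracle = enumerated_pair_prob(y1, y2, p1, p2, pi)
            worst = max(worst, abs(ll - np.log(oracle)))
        assert worst < 1e-10

    def test_total_probability(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p1 = preference_probs(np.concatenate([[0], rng.normal(0, 2, 4)]))
            p2 = preference_probs(np.concatenate([[0], rng.normal(0, 2, 4)]))
            pi = chooser_probs(*rng.gamma(1.0, 2.0, size=2), rng.normal(0, 1.5))
            total = sum(np.exp(event_pair_loglik(y1, y2, p1, p2, pi))
                        for y1 in range(1, 6) for y2 in range(1, 6))
            assert abs(total - 1.0) < 1e-12


class TestPreferencePrior:
    def test_maternal_m0_reduces_to_baseline_bitwise(self):
        rng = np.random.default_rng(1)
        W = np.concatenate([[0], rng.normal(0, 2, 4)])
        mu = np.concatenate([[0], rng.normal(0, 2, 4)])
        Wm = np.concatenate([[0], rng.normal(0, 2, 4)])
        base = preference_prior_logdensity(W, mu, 1.3)
        mat = preference_prior_logdensity(W, mu, 1.3, variant="maternal",
                                          W_mother=Wm, m=0.0)
        assert mat == base

    def test_maternal_m1_centers_on_mother(self):
        Wm = np.array([0, 1.0, -2.0, 0.5, 3.0])
        mu = np.array([0, -9.0, 9.0, -9.0, 9.0])
        at_mother = preference_prior_logdensity(Wm, mu, 1.0, variant="maternal",
                                                W_mother=Wm, m=1.0)
        peak = preference_prior_logdensity(
            np.zeros(5), np.zeros(5), 1.0)
        assert at_mother == pytest.approx(peak)

    def test_centered_density_is_normal_mode(self):
        mu = np.array([0, 0.5, -1.0, 2.0, 0.0])
        val = preference_prior_logdensity(mu, mu, 2.0)
        expected = 4 * (-np.log(2.0) - 0.5 * np.log(2 * np.pi))
        assert val == pytest.approx(expected)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            preference_prior_logdensity(np.zeros(5), np.zeros(5), 0.0)


class TestGroupMeanTransform:
    def test_softmax_and_normalization(self):
        mu = np.array([0, -3, -2, -4, 1])
        p = group_mean_transform(mu)
        assert p.sum() == pytest.approx(1.0)
        e = np.exp(mu)
        assert p == pytest.approx(e / e.sum())
        assert p.argmax() == 4


class TestLogPosterior:
    def _params(self, arrays, rng, spec):
        S, N, J = arrays.n_slots, arrays.n_individuals, arrays.n_groups
        mu = np.zeros((J, 5)); mu[:, 1:] = rng.normal(0, 1, (J, 4))
        W = np.zeros((S, 5)); W[:, 1:] = rng.normal(0, 1, (S, 4))
        return dict(mu=mu, W=W, beta=rng.normal(0, 1, 4),
                    I_RE=rng.normal(0, 0.5, N),
                    sigma_W=np.full(arrays.n_sigma, 1.2), sigma_I=0.8,
                    m=np.array([0.3, 0.6]))

    def test_outside_sigma_support_is_minus_inf(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("baseline")
        arrays = build_model_arrays(ds, spec)
        params = self._params(arrays, np.random.default_rng(0), spec)
        params["sigma_W"] = np.array([11.0])
        assert log_posterior(params, ds, spec, arrays) == -np.inf

    def test_empty_events_equals_prior_alone(self, small_dataset):
        """Dropping all events leaves exactly the prior terms."""
        ds, _ = small_dataset
        spec = ModelSpec("baseline")
        empty = hc.Dataset(ds.individuals, ds.windows, ds.ranks,
                           ds.events.iloc[:0])
        arrays_e = build_model_arrays(empty, spec)
        arrays_f = build_model_arrays(ds, spec)
        rng = np.random.default_rng(3)
        params = self._params(arrays_f, rng, spec)
        lp_full = log_posterior(params, ds, spec, arrays_f)
        lp_prior = log_posterior(params, empty, spec, arrays_e)
        # the difference is exactly the summed event log likelihood
        from handclasp.sampler import GibbsSampler
        s = GibbsSampler(arrays_f, 2, np.random.default_rng(0))
        s.W[0] = params["W"]; s.mu[0] = params["mu"]
        s.beta[0] = params["beta"]; s.re[0] = params["I_RE"]
        s.refresh_caches()
        assert lp_full - lp_prior == pytest.approx(s.total_loglik()[0])

    def test_one_event_composes_prior_and_pair_loglik(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("baseline")
        one = hc.Dataset(ds.individuals, ds.windows, ds.ranks, ds.events.iloc[:1])
        empty = hc.Dataset(ds.individuals, ds.windows, ds.ranks, ds.events.iloc[:0])
        arrays = build_model_arrays(one, spec)
        rng = np.random.default_rng(4)
        params = self._params(arrays, rng, spec)
        lp_one = log_posterior(params, one, spec, arrays)
        lp_prior = log_posterior(params, empty, spec,
                                 build_model_arrays(empty, spec))
        p1 = preference_probs(params["W"][arrays.s1[0]])
        p2 = preference_probs(params["W"][arrays.s2[0]])
        I1 = np.exp(params["I_RE"][arrays.i1[0]] + arrays.X1[0] @ params["beta"][1:])
        I2 = np.exp(params["I_RE"][arrays.i2[0]] + arrays.X2[0] @ params["beta"][1:])
        pi = chooser_probs(I1, I2, params["beta"][0])
        ell = event_pair_loglik(arrays.y1[0] + 1, arrays.y2[0] + 1, p1, p2, pi)
        assert lp_one - lp_prior == pytest.approx(ell)

    def test_variant_label_permutation_invariance(self, small_dataset):
        """Consistently permuting the non-reference variant labels in data and
        parameters leaves the log posterior unchanged."""
        ds, _ = small_dataset
        spec = ModelSpec("baseline")
        arrays = build_model_arrays(ds, spec)
        rng = np.random.default_rng(5)
        params = self._params(arrays, rng, spec)
        lp = log_posterior(params, ds, spec, arrays)

        perm = np.array([0, 3, 1, 4, 2])       # permutes categories 2..5
        ev2 = ds.events.copy()
        inv = np.empty(5, dtype=int)
        inv[perm] = np.arange(5)
        ev2["y_g1"] = [perm[y - 1] + 1 for y in ds.events["y_g1"]]
        ev2["y_g2"] = [perm[y - 1] + 1 for y in ds.events["y_g2"]]
        ds2 = hc.Dataset(ds.individuals, ds.windows, ds.ranks, ev2)
        params2 = dict(params)
        params2["W"] = params["W"][:, inv]
        params2["mu"] = params["mu"][:, inv]
        lp2 = log_posterior(params2, ds2, spec, build_model_arrays(ds2, spec))
        assert lp2 == pytest.approx(lp)


class TestSamplerConsistency:
    """The incremental caches of the Gibbs sampler must agree with direct
    recomputation and with the reference log posterior after arbitrary
    sweeps, for every model variant."""

    @pytest.mark.parametrize("variant", ["baseline", "maternal", "agesplit", "combined"])
    def test_cache_consistency_after_sweeps(self, small_dataset, variant):
        from handclasp.sampler import GibbsSampler
        ds, _ = small_dataset
        arrays = build_model_arrays(ds, ModelSpec(variant))
        s = GibbsSampler(arrays, 3, np.random.default_rng(9))
        for _ in range(25):
            s.sweep()
        caches = {n: getattr(s, n).copy()
                  for n in ("ell", "lp1", "lp2", "la", "lb", "lc", "li1", "li2")}
        s.refresh_caches()
        for n, before in caches.items():
            np.testing.assert_allclose(before, getattr(s, n), atol=1e-10,
                                       err_msg=f"cache {n} drifted")

    @pytest.mark.parametrize("variant", ["baseline", "combined"])
    def test_sampler_likelihood_matches_reference(self, small_dataset, variant):
        from handclasp.sampler import GibbsSampler
        ds, _ = small_dataset
        spec = ModelSpec(variant)
        arrays = build_model_arrays(ds, spec)
        s = GibbsSampler(arrays, 2, np.random.default_rng(11))
        for _ in range(10):
            s.sweep()
        empty = hc.Dataset(ds.individuals, ds.windows, ds.ranks, ds.events.iloc[:0])
        arrays_e = build_model_arrays(empty, spec)
        c = 1
        params = dict(mu=s.mu[c], W=s.W[c], beta=s.beta[c], I_RE=s.re[c],
                      sigma_W=s.sigw[c], sigma_I=s.sigi[c], m=s.m[c])
        lp_full = log_posterior(params, ds, spec, arrays)
        lp_prior = log_posterior(params, empty, spec, arrays_e)
        assert lp_full - lp_prior == pytest.approx(s.total_loglik()[c])
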