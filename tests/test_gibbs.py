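"""Gibbs sampler conditionals and whole-chain correctness."""

import math

import numpy as np
import pytest
from scipy import special, stats

from pyinar import (
    CountSeries,
    MixtureInnovationSpec,
    PYHyperparams,
    num_clusters_pmf,
    simulate_inar,
)
from pyinar.gibbs import (
    GibbsState,
    SamplerConfig,
    _SamplerCore,
    lambda_site_log_weights,
    refresh_cluster_values,
    run_gibbs,
    sample_alpha,
    sample_lambda_t,
    sample_maturation,
    sample_truncated_beta,
)


def make_state(y, alpha, rates, labels):
    labels = np.asarray(labels)
    cluster_values = list(dict.fromkeys(np.asarray(rates)[labels]))
    value_to_idx = {v: i for i, v in enumerate(cluster_values)}
    lab = np.array([value_to_idx[np.asarray(rates)[j]] for j in labels])
    sizes = list(np.bincount(lab, minlength=len(cluster_values)))
    return GibbsState(
        alpha=np.atleast_1d(np.asarray(alpha, dtype=float)),
        m=np.zeros((y.order, y.n_epochs), dtype=np.int64),
        labels=lab,
        cluster_values=[float(v) for v in cluster_values],
        cluster_sizes=[int(s) for s in sizes],
    )


@pytest.fixture
def hyper():
    return PYHyperparams(tau=1.0, sigma=0.5, a0=2.0, b0=1.0)


class TestTruncatedBeta:
    def test_untruncated_case_is_plain_beta(self, rng):
        draws = [sample_truncated_beta(3.0, 5.0, 1.0, rng) for _ in range(5000)]
        ref = rng.beta(3.0, 5.0, size=5000)
        assert stats.ks_2samp(draws, ref).pvalue > 0.001

    def test_draws_respect_bound(self, rng):
        bound = 0.3
        draws = np.array(
            [sample_truncated_beta(2.0, 1.0, bound, rng) for _ in range(100_000)]
        )
        assert np.all(draws > 0) and np.all(draws < bound)

    def test_inverse_cdf_matches_rejection(self, rng):
        a, b, bound = 3.0, 5.0, 0.6
        inv = np.array([sample_truncated_beta(a, b, bound, rng) for _ in range(5000)])
        rej = []
        while len(rej) < 5000:
            x = rng.beta(a, b)
            if x < bound:
                rej.append(x)
        assert stats.ks_2samp(inv, np.array(rej)).pvalue > 0.001

    def test_deep_tail_fallback_stays_in_support(self, rng):
        x = sample_truncated_beta(40.0, 2.0, 1e-8, rng)
        assert 0 < x < 1e-8


class TestLambdaConditional:
    def test_grouped_and_ungrouped_weights_identical(self, hyper, small_series):
        """sum over epochs of a cluster of (1 - sigma/n_r) * lam^d e^-lam
        equals (n_j - sigma) * lam^d e^-lam: same transition kernel."""
        y = small_series
        rates = np.array([2.0, 2.0, 5.0, 5.0, 5.0, 1.0, 2.0])
        state = make_state(y, 0.3, rates, np.arange(7))
        for t in range(y.order + 1, y.T + 1):
            lf_g, atoms = lambda_site_log_weights(t, state, hyper, y, grouped=True)
            lf_u, per_obs = lambda_site_log_weights(t, state, hyper, y, grouped=False)
            assert lf_g == lf_u
            grouped_from_obs = np.full(state.k, -np.inf)
            for r in range(y.n_epochs):
                if np.isfinite(per_obs[r]):
                    j = state.labels[r]
                    grouped_from_obs[j] = np.logaddexp(grouped_from_obs[j], per_obs[r])
            finite = np.isfinite(atoms)
            np.testing.assert_allclose(
                np.exp(atoms[finite]), np.exp(grouped_from_obs[finite]), rtol=1e-12
            )

    def test_residual_factorial_cancels_on_normalization(self, hyper, small_series):
        y = small_series
        rates = np.array([2.0, 2.0, 5.0, 5.0, 5.0, 1.0, 2.0])
        state = make_state(y, 0.3, rates, np.arange(7))
        t = 4
        lf, atoms = lambda_site_log_weights(t, state, hyper, y)
        lf2, atoms2 = lambda_site_log_weights(
            t, state, hyper, y, include_residual_factorial=True
        )
        w = np.exp(np.concatenate(([lf], atoms)))
        w2 = np.exp(np.concatenate(([lf2], atoms2)))
        np.testing.assert_allclose(w / w.sum(), w2 / w2.sum(), rtol=1e-12)

    def test_single_epoch_always_draws_fresh_gamma(self, hyper, rng):
        y = CountSeries(values=np.array([1, 3]), order=1)
        draws = []
        for _ in range(4000):
            state = make_state(y, 0.0, np.array([2.0]), [0])
            draws.append(sample_lambda_t(2, state, hyper, y, rng))
            assert state.k == 1  # its own cluster, freshly drawn
        # residual d = 3 (m = 0), so law is Gamma(3 + a0, b0 + 1)
        ref = rng.gamma(3 + hyper.a0, 1.0 / (hyper.b0 + 1.0), size=4000)
        assert stats.ks_2samp(draws, ref).pvalue > 0.001

    def test_empirical_transition_matches_exact_weights(self, hyper, rng):
        # epoch 3 holds the singleton atom 6.0; on update it either joins the
        # cluster at 2.0 (occupants: epochs 2 and 4) or opens a fresh cluster
        y = CountSeries(values=np.array([2, 3, 1, 4]), order=1)
        rates = np.array([2.0, 6.0, 2.0])
        reps = 30_000
        joins = 0
        for _ in range(reps):
            state = make_state(y, 0.0, rates, [0, 1, 2])
            sample_lambda_t(3, state, hyper, y, rng)
            if state.cluster_values[state.labels[1]] == 2.0:
                joins += 1
        state = make_state(y, 0.0, rates, [0, 1, 2])
        lf, atoms = lambda_site_log_weights(3, state, hyper, y)
        logw = np.concatenate(([lf], atoms[np.isfinite(atoms)]))
        w = np.exp(logw - logw.max())
        w /= w.sum()
        p_join = w[1]
        se = np.sqrt(p_join * (1 - p_join) / reps)
        assert joins / reps == pytest.approx(p_join, abs=4 * se)


class TestAlphaConditional:
    def test_order_one_is_plain_beta(self, small_series, rng):
        state = make_state(small_series, 0.4, np.array([2.0] * 7), [0] * 7)
        state.m[:] = 1
        cfg = SamplerConfig(n_iter=2, n_burn=0)
        draws = []
        for _ in range(5000):
            state.alpha[0] = 0.4
            draws.append(sample_alpha(state, small_series, cfg, rng).alpha[0])
        lag_sum = int(small_series.values[:-1].sum())
        ref = rng.beta(1 + 7, 1 + lag_sum - 7, size=5000)
        assert stats.ks_2samp(draws, ref).pvalue > 0.001

    def test_higher_order_sum_stays_below_one(self, rng):
        sim = simulate_inar([0.3, 0.3], 5.0, T=120, rng=5)
        y = sim.series
        state = GibbsState.initial(y)
        cfg = SamplerConfig(n_iter=2, n_burn=0)
        for _ in range(2000):
            sample_alpha(state, y, cfg, rng)
            assert state.alpha.sum() < 1.0
            assert np.all(state.alpha > 0)


class TestMaturationConditional:
    def test_zero_lag_count_forces_zero(self, hyper, rng):
        y = CountSeries(values=np.array([0, 3]), order=1)
        state = make_state(y, 0.5, np.array([2.0]), [0])
        assert sample_maturation(1, 2, state, y, rng) == 0

    def test_zero_alpha_forces_zero(self, rng):
        y = CountSeries(values=np.array([4, 3]), order=1)
        state = make_state(y, 0.0, np.array([2.0]), [0])
        assert sample_maturation(1, 2, state, y, rng) == 0

    def test_frequencies_match_enumeration(self, rng):
        y = CountSeries(values=np.array([4, 3]), order=1)
        alpha, lam = 0.6, 2.0
        reps = 100_000
        counts = np.zeros(4)
        for _ in range(reps):
            state = make_state(y, alpha, np.array([lam]), [0])
            counts[sample_maturation(1, 2, state, y, rng)] += 1
        ms = np.arange(4)
        logw = (
            -special.gammaln(ms + 1)
            - special.gammaln(3 - ms + 1)
            - special.gammaln(4 - ms + 1)
            + ms * (math.log(alpha) - math.log(lam) - math.log1p(-alpha))
        )
        w = np.exp(logw - logw.max())
        w /= w.sum()
        stat, pval = stats.chisquare(counts, w * reps)
        assert pval > 0.01


class TestClusterRefresh:
    def test_partition_unchanged_and_members_share_value(
        self, hyper, small_series, rng
    ):
        rates = np.array([2.0, 2.0, 5.0, 5.0, 5.0, 2.0, 7.0])
        state = make_state(small_series, 0.3, rates, np.arange(7))
        labels_before = state.labels.copy()
        refresh_cluster_values(state, hyper, small_series, rng)
        np.testing.assert_array_equal(state.labels, labels_before)
        for j, v in enumerate(state.cluster_values):
            members = state.rates[state.labels == j]
            assert np.all(members == v)

    def test_posterior_mean_of_cluster_value(self, hyper, small_series, rng):
        rates = np.array([2.0] * 7)
        resid = small_series.values[1:]  # m = 0
        draws = []
        for _ in range(20_000):
            state = make_state(small_series, 0.3, rates, [0] * 7)
            refresh_cluster_values(state, hyper, small_series, rng)
            draws.append(state.cluster_values[0])
        shape = hyper.a0 + resid.sum()
        rate = hyper.b0 + 7
        expected = shape / rate
        se = math.sqrt(shape) / rate / math.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(expected, abs=4 * se)


class TestRunGibbs:
    def test_state_invariants_after_sweeps(self, hyper, rng):
        sim = simulate_inar([0.2, 0.2], MixtureInnovationSpec(), T=60, rng=3)
        y = sim.series
        state = GibbsState.initial(y)
        core = _SamplerCore(y, hyper, SamplerConfig(n_iter=2, n_burn=0))
        for _ in range(50):
            core.sweep(state, rng)
            state.check_invariants(y)

    def test_all_zero_series_pulls_rates_below_prior_mean(self, hyper):
        y = CountSeries(values=np.zeros(40, dtype=int), order=1)
        draws = run_gibbs(y, hyper, SamplerConfig(n_iter=600, n_burn=200, seed=8))
        prior_mean = hyper.a0 / hyper.b0
        assert draws.rates.mean() < prior_mean / 2

    def test_alpha_recovery_on_homogeneous_inar1(self):
        sim = simulate_inar(0.15, 5.0, T=1000, rng=17)
        hyper = PYHyperparams(tau=1.0, sigma=0.5, a0=2.0, b0=0.4)
        draws = run_gibbs(
            sim.series, hyper, SamplerConfig(n_iter=1200, n_burn=400, seed=18)
        )
        post_mean = draws.alpha.mean()
        post_sd = draws.alpha.std(ddof=1)
        assert abs(post_mean - 0.15) < 3 * max(post_sd, 0.01)

    def test_retained_draw_count_and_serialization(self, hyper, small_series, tmp_path):
        cfg = SamplerConfig(n_iter=60, n_burn=20, thin=4, seed=1)
        draws = run_gibbs(small_series, hyper, cfg)
        assert draws.n_retained == 10
        draws.to_csv(tmp_path / "d.csv", tmp_path / "r.csv")
        header = (tmp_path / "d.csv").read_text().splitlines()[0]
        assert header == "alpha1,k,loglik"

    def test_geweke_prior_preservation_tiny_model(self):
        """Alternating parameter sweeps with data regeneration must leave the
        prior marginals of alpha and K invariant (joint-distribution test)."""
        rng = np.random.default_rng(71)
        tau, sigma, a0, b0 = 1.0, 0.5, 2.0, 1.0
        hyper = PYHyperparams(tau=tau, sigma=sigma, a0=a0, b0=b0)
        T, n, y1 = 5, 4, 3
        cfg = SamplerConfig(n_iter=2, n_burn=0)

        def prior_partition():
            vals, sizes, labels = [], [], np.zeros(n, dtype=int)
            for i in range(n):
                k = len(vals)
                w = np.array([tau + k * sigma] + [s - sigma for s in sizes])
                u = rng.random() * w.sum()
                j = int(np.searchsorted(np.cumsum(w), u))
                if j == 0:
                    vals.append(rng.gamma(a0, 1 / b0))
                    sizes.append(1)
                    labels[i] = k
                else:
                    sizes[j - 1] += 1
                    labels[i] = j - 1
            return vals, sizes, labels

        def gen_data(alpha, rates):
            y = np.empty(T, dtype=np.int64)
            y[0] = y1
            m = np.zeros((1, n), dtype=np.int64)
            for t in range(1, T):
                m[0, t - 1] = rng.binomial(y[t - 1], alpha)
                y[t] = m[0, t - 1] + rng.poisson(rates[t - 1])
            return y, m

        N, burn = 12_000, 1000
        alpha = float(rng.beta(1, 1))
        vals, sizes, labels = prior_partition()
        rates = np.asarray(vals)[labels]
        y, m = gen_data(alpha, rates)
        alphas = np.empty(N)
        ks = np.empty(N, dtype=int)
        for it in range(N):
            ys = CountSeries(values=y, order=1)
            state = GibbsState(
                alpha=np.array([alpha]),
                m=m.copy(),
                labels=labels.copy(),
                cluster_values=list(vals),
                cluster_sizes=list(sizes),
            )
            _SamplerCore(ys, hyper, cfg).sweep(state, rng)
            alpha = float(state.alpha[0])
            vals = list(state.cluster_values)
            sizes = list(state.cluster_sizes)
            labels = state.labels.copy()
            y, m = gen_data(alpha, state.rates)
            alphas[it] = alpha
            ks[it] = len(vals)
        a = alphas[burn:]
        k = ks[burn:]
        # autocorrelation-inflated standard error (conservative factor 5)
        se = a.std(ddof=1) / math.sqrt(len(a) / 25)
        assert a.mean() == pytest.approx(0.5, abs=4 * se)
        assert a.var() == pytest.approx(1 / 12, rel=0.1)
        pmf = num_clusters_pmf(n, tau, sigma)
        freq = np.bincount(k, minlength=n + 1)[1:] / len(k)
        np.testing.assert_allclose(freq, pmf, atol=0.03)
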