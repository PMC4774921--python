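"""MCMC machinery: reparametrization, likelihood, Gibbs and RWMH kernels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from forceshare.mcmc import (
    ALL_WEIGHT_SUBSETS,
    AdaptState,
    ModelSpec,
    PosteriorChain,
    ShareDataset,
    log_likelihood,
    posterior_summary,
    reparam_forward,
    reparam_inverse,
    run_chain,
    rwmh_step,
    variance_gibbs_update,
)
from forceshare.model import CostWeights, FingerProfile, normalization_constants
from forceshare.synthetic import PopulationSpec, ScenarioSpec, sample_population, simulate_share_data

from conftest import grid_posterior_medians


def small_dataset(seed=42, n_participants=2, n_obs=10, weights=CostWeights(0.2, 0.5, 0.3)):
    rng = np.random.default_rng(seed)
    pairs = sample_population(PopulationSpec(n_participants=n_participants), rng)
    scenario = ScenarioSpec(levels=(12.0,), weights=(weights,), n_obs=n_obs)
    data = simulate_share_data(pairs, scenario, rng)[0]
    return data, normalization_constants(pairs)


class TestReparam:
    def test_forward_example(self):
        w = reparam_forward(0.2, 0.5)
        assert (w.nu, w.lam, w.mu) == (pytest.approx(0.2), pytest.approx(0.4), pytest.approx(0.4))

    def test_inverse_example(self):
        assert reparam_inverse(CostWeights(0.2, 0.4, 0.4)) == (
            pytest.approx(0.2),
            pytest.approx(0.5),
        )

    def test_round_trip_identity_on_grid(self):
        grid = (np.arange(100) + 0.5) / 100
        for w in grid:
            for z in grid[::7]:
                weights = reparam_forward(w, z)
                assert weights.nu + weights.lam + weights.mu == pytest.approx(1.0, abs=1e-12)
                w2, z2 = reparam_inverse(weights)
                assert (w2, z2) == (pytest.approx(w, abs=1e-12), pytest.approx(z, abs=1e-12))

    def test_inverse_undefined_at_nu_one(self):
        with pytest.raises(ValueError):
            reparam_inverse(CostWeights(1.0, 0.0, 0.0))


class TestLogLikelihood:
    def test_zero_residual_unit_variance(self, mean_pair, mean_consts):
        from forceshare.model import share_for_pair

        weights = CostWeights(0.2, 0.5, 0.3)
        c = share_for_pair(weights, mean_consts, *mean_pair)
        data = ShareDataset(10.0, ["p1"], [np.array([c])], [mean_pair])
        ll = log_likelihood(data, weights, np.array([1.0]), mean_consts)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_all_zero_residuals_scale_with_n(self, mean_pair, mean_consts):
        from forceshare.model import share_for_pair

        weights = CostWeights(0.2, 0.5, 0.3)
        c = share_for_pair(weights, mean_consts, *mean_pair)
        data = ShareDataset(10.0, ["p1", "p2"], [np.full(4, c), np.full(3, c)],
                            [mean_pair, mean_pair])
        ll = log_likelihood(data, weights, np.array([1.0, 1.0]), mean_consts)
        assert ll == pytest.approx(-(7 / 2) * math.log(2 * math.pi))

    def test_against_per_point_summation_oracle(self):
        from forceshare.model import share_for_pair

        data, consts = small_dataset(seed=7, n_participants=3, n_obs=6)
        weights = CostWeights(0.15, 0.55, 0.3)
        var = np.array([0.002, 0.004, 0.001])
        naive = 0.0
        for m, (y, pair) in enumerate(zip(data.y, data.profiles)):
            c = share_for_pair(weights, consts, *pair)
            for v in y:
                naive += stats.norm.logpdf(v, loc=c, scale=math.sqrt(var[m]))
        assert log_likelihood(data, weights, var, consts) == pytest.approx(naive, abs=1e-10)

    def test_nonpositive_variance_rejected(self):
        data, consts = small_dataset()
        with pytest.raises(ValueError):
            log_likelihood(data, CostWeights(0.2, 0.5, 0.3), np.array([1.0, 0.0]), consts)


class TestVarianceGibbs:
    def test_moments_match_inverse_gamma(self):
        # residuals give InvGa(2, 0.02); analytic mean 0.02/(2-1) = 0.02
        rng = np.random.default_rng(11)
        resid = np.array([0.1, -0.1, 0.1, -0.1])
        draws = np.array([variance_gibbs_update(resid, rng) for _ in range(1_000_000)])
        # analytic mean is scale/(shape-1) = 0.02; InvGa(2, .) has infinite
        # variance, so floor the empirical SE to keep the bound meaningful
        se = draws.std(ddof=1) / 1000.0
        assert abs(draws.mean() - 0.02) < 3 * max(se, 1e-4)

    def test_quantiles_match_scipy_invgamma(self):
        rng = np.random.default_rng(12)
        resid = np.array([0.1, -0.1, 0.1, -0.1])
        draws = np.array([variance_gibbs_update(resid, rng) for _ in range(100_000)])
        ks = stats.kstest(draws, stats.invgamma(a=2, scale=0.02).cdf)
        assert ks.pvalue > 0.01

    def test_single_residual_bookkeeping(self):
        rng = np.random.default_rng(13)
        r = 0.2
        draws = np.array([variance_gibbs_update(np.array([r]), rng) for _ in range(100_000)])
        ks = stats.kstest(draws, stats.invgamma(a=0.5, scale=r**2 / 2).cdf)
        assert ks.pvalue > 0.01

    def test_flat_prior_shifts_shape(self):
        rng = np.random.default_rng(14)
        resid = np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
        draws = np.array(
            [variance_gibbs_update(resid, rng, prior="flat") for _ in range(100_000)]
        )
        ks = stats.kstest(draws, stats.invgamma(a=2, scale=0.03).cdf)
        assert ks.pvalue > 0.01

    def test_zero_residuals_rejected(self):
        with pytest.raises(ValueError):
            variance_gibbs_update(np.zeros(4), np.random.default_rng(0))


class TestRWMH:
    def test_adaptation_reaches_target_acceptance(self):
        rng = np.random.default_rng(3)
        adapt = AdaptState()
        x, lp = 0.5, 0.0
        accepts = []
        for _ in range(120_000):
            x, ok, lp = rwmh_step(x, lambda v: 0.0, adapt, rng, lp)
            accepts.append(ok)
        assert abs(np.mean(accepts[40_000:]) - 0.44) < 0.03

    def test_uniform_target_stationary_law(self):
        rng = np.random.default_rng(4)
        adapt = AdaptState(log_sd=1.4)  # near the adapted scale for U(0,1)
        x, lp = 0.5, 0.0
        xs = np.empty(100_000)
        for i in range(100_000):
            x, _, lp = rwmh_step(x, lambda v: 0.0, adapt, rng, lp)
            xs[i] = x
        # thin to roughly independent draws before the KS comparison
        assert stats.kstest(xs[::40], "uniform").pvalue > 0.01

    def test_tiny_proposal_accepts_almost_always(self):
        rng = np.random.default_rng(5)
        adapt = AdaptState(log_sd=-18.0)
        target = lambda v: math.log(v * (1 - v))  # any smooth density
        x, lp = 0.3, target(0.3)
        accepts = [rwmh_step(x, target, adapt, rng)[1] for _ in range(2000)]
        assert np.mean(accepts) > 0.999

    def test_three_bin_stationary_frequencies(self):
        # piecewise-constant target on three equal bins with masses 1:2:3
        heights = np.array([1.0, 2.0, 3.0])

        def log_target(v):
            return math.log(heights[min(int(v * 3), 2)])

        rng = np.random.default_rng(6)
        adapt = AdaptState(log_sd=1.0)
        x, lp = 0.5, log_target(0.5)
        counts = np.zeros(3)
        n = 300_000
        for _ in range(n):
            x, _, lp = rwmh_step(x, log_target, adapt, rng, lp)
            counts[min(int(x * 3), 2)] += 1
        freq = counts / n
        expected = heights / heights.sum()
        assert np.all(np.abs(freq - expected) < 0.02)


class TestRunChain:
    def test_same_seed_bit_identical(self):
        data, consts = small_dataset()
        a = run_chain(data, ModelSpec(), consts, T=2000, burn_in=500, seed=9)
        b = run_chain(data, ModelSpec(), consts, T=2000, burn_in=500, seed=9)
        assert np.array_equal(a.w, b.w)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_simplex_invariant_every_iteration(self):
        data, consts = small_dataset()
        for subset in ALL_WEIGHT_SUBSETS:
            chain = run_chain(
                data, ModelSpec(free_terms=subset), consts, T=800, burn_in=100, seed=2
            )
            total = chain.nu + chain.lam + chain.mu
            assert np.allclose(total, 1.0, atol=1e-12)
            assert chain.nu.min() >= 0 and chain.lam.min() >= 0 and chain.mu.min() >= 0
            for name in ("nu", "lam", "mu"):
                if name not in subset:
                    assert np.all(getattr(chain, name) == 0.0)
            assert np.all(chain.sigma2 > 0)

    def test_matches_grid_quadrature_on_small_instance(self):
        data, consts = small_dataset(seed=42, n_participants=2, n_obs=10)
        w_grid, z_grid = grid_posterior_medians(data, consts, n_grid=200)
        chain = run_chain(data, ModelSpec(), consts, T=30_000, burn_in=10_000, seed=7)
        assert abs(np.median(chain.retained("w")) - w_grid) < 0.02
        assert abs(np.median(chain.retained("z")) - z_grid) < 0.02

    def test_levels_fit_independently(self):
        rng = np.random.default_rng(21)
        pairs = sample_population(PopulationSpec(n_participants=4), rng)
        scenario = ScenarioSpec(
            levels=(8.0, 16.0),
            weights=(CostWeights(0.1, 0.6, 0.3), CostWeights(0.1, 0.4, 0.5)),
            n_obs=20,
        )
        d1, d2 = simulate_share_data(pairs, scenario, rng)
        consts = normalization_constants(pairs)
        # fitting level 2 alone gives the same chain as fitting it after level 1
        run_chain(d1, ModelSpec(), consts, T=500, burn_in=100, seed=31)
        alone = run_chain(d2, ModelSpec(), consts, T=500, burn_in=100, seed=32)
        again = run_chain(d2, ModelSpec(), consts, T=500, burn_in=100, seed=32)
        assert np.array_equal(alone.w, again.w)

    def test_pooled_variance_single_column(self):
        data, consts = small_dataset(n_participants=4, n_obs=15)
        chain = run_chain(
            data,
            ModelSpec(variance_structure="pooled"),
            consts,
            T=800,
            burn_in=200,
            seed=3,
        )
        assert chain.sigma2.shape[1] == 1

    def test_invalid_lengths_rejected(self):
        data, consts = small_dataset()
        with pytest.raises(ValueError):
            run_chain(data, ModelSpec(), consts, T=100, burn_in=100, seed=0)

    def test_degenerate_participant_rejected(self, mean_pair, mean_consts):
        data = ShareDataset(
            10.0, ["p1"], [np.full(5, 0.4)], [mean_pair]
        )
        with pytest.raises(ValueError, match="constant shares"):
            run_chain(data, ModelSpec(), mean_consts, T=100, burn_in=10, seed=0)


def fake_chain(nu_draws, burn_in=0):
    n = nu_draws.size
    nu = np.asarray(nu_draws, float)
    lam = (1 - nu) * 0.5
    mu = 1 - nu - lam
    z = np.full(n, 0.5)
    return PosteriorChain(
        w=nu,
        z=z,
        nu=nu,
        lam=lam,
        mu=mu,
        sigma2=np.full((n, 1), 0.01),
        participant_ids=["p1"],
        burn_in=burn_in,
        seed=0,
        spec=ModelSpec(),
        level_g=10.0,
        accept_rate_w=0.4,
        accept_rate_z=0.4,
        adapt_trace_w=np.array([]),
        adapt_trace_z=np.array([]),
    )


class TestPosteriorSummary:
    def test_degenerate_chain_zero_width(self):
        s = posterior_summary(fake_chain(np.full(100, 0.3)))
        assert s["nu"].median == s["nu"].lo95 == s["nu"].hi95 == pytest.approx(0.3)

    def test_normal_draws_match_quantile_oracle(self, rng):
        draws = np.clip(rng.normal(0.5, 0.1, 50_000), 1e-6, 1 - 1e-6)
        s = posterior_summary(fake_chain(draws))
        assert s["nu"].lo95 == pytest.approx(0.304, abs=0.01)
        assert s["nu"].hi95 == pytest.approx(0.696, abs=0.01)

    def test_median_stable_under_thinning(self, rng):
        draws = np.clip(rng.beta(4, 6, 40_000), 1e-6, 1 - 1e-6)
        full = posterior_summary(fake_chain(draws))["nu"].median
        thinned = posterior_summary(fake_chain(draws[::10]))["nu"].median
        assert thinned == pytest.approx(full, abs=0.01)

    def test_empty_retained_segment_rejected(self):
        chain = fake_chain(np.full(10, 0.3), burn_in=10)
        with pytest.raises(ValueError):
            posterior_summary(chain)
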