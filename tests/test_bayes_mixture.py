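import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from mmlfdr.bayes_mixture import (
    MCMCConfig,
    MixtureParams,
    PriorConfig,
    alpha_link,
    blfdr_given_params,
    decide,
    fit,
    gibbs_step_beta,
    gibbs_step_sigma2,
    gibbs_step_w,
    log_f0,
    log_f1,
    metropolis_step_coeffs,
    pi_link,
)
from mmlfdr.simulate import StatSimConfig, simulate_statistics


class TestDensities:
    def test_folded_normal_values(self):
        assert log_f0(0.0, 1.0) == pytest.approx(np.log(np.sqrt(2 / np.pi)), abs=1e-9)
        assert log_f0(1.0, 1.0) == pytest.approx(np.log(0.483941), abs=1e-6)

    def test_folded_normal_normalizes(self):
        val, _ = integrate.quad(lambda t: np.exp(log_f0(t, 2.3)), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_folded_normal_domain(self):
        with pytest.raises(ValueError):
            log_f0(-0.1, 1.0)
        with pytest.raises(ValueError):
            log_f0(1.0, 0.0)

    def test_gamma_values(self):
        assert log_f1(1.0, 2.0, 1.0) == pytest.approx(np.log(np.exp(-1.0)), abs=1e-9)
        assert log_f1(1.0, 1.0, 1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_gamma_normalizes(self):
        val, _ = integrate.quad(lambda t: np.exp(log_f1(t, 2.5, 0.7)), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_gamma_domain(self):
        for bad in [(0.0, 1.0, 1.0), (1.0, -1.0, 1.0), (1.0, 1.0, 0.0)]:
            with pytest.raises(ValueError):
                log_f1(*bad)


class TestLinkFunctions:
    def test_alpha_identity_at_zero_coefs(self):
        assert alpha_link(3.7, 0.0, 0.0) == 1.0

    def test_alpha_example(self):
        assert alpha_link(2.0, 0.5, 0.25) == pytest.approx(np.e, rel=1e-12)

    def test_alpha_monotone_when_slope_positive(self):
        s = np.linspace(0, 10, 50)
        a = alpha_link(s, 0.3, 0.4)
        assert np.all(np.diff(a) > 0)

    def test_pi_half_at_zero_logit(self):
        assert pi_link(5.0, 0.0, 0.0) == 0.5

    def test_pi_logistic_value(self):
        assert pi_link(0.0, -2.0, 1.0) == pytest.approx(0.119203, abs=1e-6)

    def test_pi_saturates(self):
        assert pi_link(1e4, 0.0, 1.0) == pytest.approx(1.0, abs=1e-12)


def _oracle_blfdr(t, s, p: MixtureParams):
    """Brute-force normalization in extended precision (independent path)."""
    t = max(np.longdouble(t), np.longdouble(1e-8))
    s = np.longdouble(s)
    pi = np.longdouble(1) / (np.longdouble(1) + np.exp(-(p.eta0 + p.eta1 * s)))
    alpha = np.exp(np.longdouble(min(p.gamma0 + p.gamma1 * float(s), np.log(1e6))))
    f0 = np.sqrt(np.longdouble(2) / (np.longdouble(np.pi) * p.sigma2)) * np.exp(
        -t * t / (2 * np.longdouble(p.sigma2))
    )
    logf1 = (
        alpha * np.log(np.longdouble(p.beta))
        + (alpha - 1) * np.log(t)
        - np.longdouble(p.beta) * t
        - np.longdouble(special.gammaln(float(alpha)))
    )
    f1 = np.exp(logf1)
    num = (1 - pi) * f0
    den = num + pi * f1
    return float(num / den) if den > 0 else 1.0


class TestBlfdrGivenParams:
    def test_hand_computed_equal_weight(self):
        # f0(1)=0.483941, f1(1; 2, 1)=0.367879, pi=1/2
        p = MixtureParams(sigma2=1.0, beta=1.0, gamma0=np.log(2.0), gamma1=0.0,
                          eta0=0.0, eta1=0.0)
        assert blfdr_given_params(1.0, 0.0, p) == pytest.approx(0.5681, abs=2e-4)

    def test_no_alternative_mass(self):
        p = MixtureParams(eta0=-800.0)
        assert blfdr_given_params(1.0, 0.0, p) == pytest.approx(1.0, abs=1e-12)

    def test_gamma_tail_dominates_gaussian(self):
        p = MixtureParams(sigma2=1.0, beta=1.0, gamma0=np.log(2.0), gamma1=0.0)
        assert blfdr_given_params(10.0, 0.0, p) < 1e-6
        assert blfdr_given_params(50.0, 0.0, p) < 1e-30

    def test_vanishing_t_with_shape_above_one(self):
        p = MixtureParams(sigma2=1.0, beta=1.0, gamma0=np.log(3.0), gamma1=0.0)
        assert blfdr_given_params(1e-12, 0.0, p) > 1 - 1e-6

    def test_matches_extended_precision_oracle_on_grid(self):
        rng = np.random.default_rng(404)
        for _ in range(400):
            p = MixtureParams(
                sigma2=float(rng.uniform(0.3, 3.0)),
                beta=float(rng.uniform(0.3, 3.0)),
                gamma0=float(rng.uniform(-1, 2)),
                gamma1=float(rng.uniform(-0.5, 1)),
                eta0=float(rng.uniform(-6, 2)),
                eta1=float(rng.uniform(-0.5, 1.5)),
            )
            t = float(rng.uniform(0, 8))
            s = float(rng.uniform(0, 6))
            got = blfdr_given_params(t, s, p)
            want = _oracle_blfdr(t, s, p)
            assert got == pytest.approx(want, abs=1e-10)

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(7)
        p = MixtureParams(sigma2=0.5, beta=2.0, gamma0=1.0, gamma1=0.3, eta0=-3, eta1=0.8)
        vals = blfdr_given_params(rng.uniform(0, 30, 1000), rng.uniform(0, 10, 1000), p)
        assert np.all((vals >= 0) & (vals <= 1))


class TestGibbsSteps:
    def test_w_degenerate_prior(self, rng):
        t = np.abs(np.random.default_rng(0).normal(size=200))
        s = np.zeros(200)
        all_null = MixtureParams(eta0=-800.0)
        assert gibbs_step_w(t, s, all_null, rng).sum() == 0
        all_alt = MixtureParams(eta0=800.0, gamma0=np.log(2.0))
        assert gibbs_step_w(np.maximum(t, 0.1), s, all_alt, rng).sum() == 200

    def test_w_long_run_frequency_matches_blfdr(self, rng):
        p = MixtureParams(sigma2=1.0, beta=1.0, gamma0=np.log(2.0), eta0=-1.0, eta1=0.5)
        t = np.array([0.5, 1.5, 3.0, 5.0])
        s = np.array([0.0, 1.0, 2.0, 4.0])
        draws = np.mean([gibbs_step_w(t, s, p, rng) for _ in range(10000)], axis=0)
        expected = 1.0 - blfdr_given_params(t, s, p)
        np.testing.assert_allclose(draws, expected, atol=0.02)

    def test_sigma2_prior_fallback(self, rng):
        draws = np.array([gibbs_step_sigma2([], (3.0, 2.0), rng) for _ in range(5000)])
        ks = stats.kstest(draws, stats.invgamma(3.0, scale=2.0).cdf)
        assert ks.pvalue > 0.01

    def test_sigma2_conditional_matches_analytic(self, rng):
        t_null = np.random.default_rng(3).normal(0, 1.4, size=300)
        a0, b0 = 2.0, 2.0
        a = a0 + t_null.size / 2
        b = b0 + 0.5 * np.sum(t_null**2)
        draws = np.array([gibbs_step_sigma2(np.abs(t_null), (a0, b0), rng) for _ in range(5000)])
        ks = stats.kstest(draws, stats.invgamma(a, scale=b).cdf)
        assert ks.pvalue > 0.01

    def test_sigma2_posterior_mean_approaches_mean_square(self, rng):
        big = np.random.default_rng(4).normal(0, 2.0, size=20000)
        draws = np.array([gibbs_step_sigma2(np.abs(big), (2.0, 2.0), rng) for _ in range(400)])
        assert draws.mean() == pytest.approx(np.mean(big**2), rel=0.05)

    def test_beta_prior_fallback(self, rng):
        draws = np.array([gibbs_step_beta([], [], (2.0, 3.0), rng) for _ in range(5000)])
        ks = stats.kstest(draws, stats.gamma(2.0, scale=1 / 3.0).cdf)
        assert ks.pvalue > 0.01

    def test_beta_conditional_mean(self, rng):
        t_alt = np.random.default_rng(5).gamma(2.0, 1.0, size=400)
        alpha = np.full(400, 2.0)
        c0, d0 = 1.0, 1.0
        expected = (c0 + alpha.sum()) / (d0 + t_alt.sum())
        draws = np.array(
            [gibbs_step_beta(t_alt, alpha, (c0, d0), rng) for _ in range(5000)]
        )
        assert draws.mean() == pytest.approx(expected, rel=0.01)

    def test_beta_rate_scale_duality(self, rng):
        t_alt = np.random.default_rng(6).gamma(3.0, 1.0, size=2000)
        alpha = np.full(2000, 3.0)
        m1 = np.mean([gibbs_step_beta(t_alt, alpha, (1.0, 1.0), rng) for _ in range(2000)])
        m2 = np.mean([gibbs_step_beta(2 * t_alt, alpha, (1.0, 1.0), rng) for _ in range(2000)])
        assert m2 == pytest.approx(m1 / 2, rel=0.05)

    def test_metropolis_zero_scale_is_immobile(self, rng):
        cur = np.array([0.3, -0.2])
        lp = -1.0
        new, new_lp, acc = metropolis_step_coeffs(lambda v: -1.0, cur, lp, 0.0, rng)
        assert acc and np.array_equal(new, cur)


class TestDecide:
    def test_running_mean_keeps_late_high_value(self):
        idx, k, est = decide(np.array([0.01, 0.05, 0.5]), 0.2)
        assert k == 3 and est == pytest.approx(0.56 / 3)

    def test_rejects_none_above_level(self):
        idx, k, est = decide(np.array([0.3, 0.4]), 0.2)
        assert k == 0 and idx.size == 0 and est == 0.0

    def test_boundary_is_inclusive(self):
        idx, k, est = decide(np.array([0.2]), 0.2)
        assert k == 1 and est == 0.2

    def test_ties_at_cutoff_all_or_none(self):
        # 0.1, then three 0.26: any strict prefix of the tie group is
        # forbidden; all four have mean 0.22 > 0.2 so only the first stays
        idx, k, _ = decide(np.array([0.26, 0.1, 0.26, 0.26]), 0.2)
        assert k == 1 and list(idx) == [1]

    def test_estimated_fdr_never_exceeds_level(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            v = rng.uniform(0, 1, rng.integers(1, 50))
            idx, k, est = decide(v, 0.2)
            assert est <= 0.2
            if k:
                assert np.mean(np.sort(v)[:k]) <= 0.2 + 1e-12

    def test_empty_input(self):
        idx, k, est = decide(np.array([]), 0.2)
        assert k == 0 and idx.size == 0

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            decide(np.array([0.5]), 1.5)


FAST_MCMC = MCMCConfig(n_iter=1500, n_burnin=700, n_chains=2, thin=2, seed=99)


class TestFit:
    def test_null_dominated_data_yields_high_blfdr(self):
        cfg = StatSimConfig(
            n_links=2000,
            params=MixtureParams(sigma2=1.0, beta=1.0, gamma0=1.0, gamma1=0.2,
                                 eta0=-8.0, eta1=0.0),
            seed=21,
        )
        stats_df, _ = simulate_statistics(cfg)
        res = fit(stats_df, mcmc=FAST_MCMC, q=0.2)
        assert (res.blfdr > 0.5).mean() >= 0.99

    def test_seed_reproducibility_and_chain_agreement(self):
        stats_df, _ = simulate_statistics(StatSimConfig(n_links=1500, seed=31))
        res1 = fit(stats_df, mcmc=FAST_MCMC, q=0.2)
        res2 = fit(stats_df, mcmc=FAST_MCMC, q=0.2)
        np.testing.assert_array_equal(res1.blfdr, res2.blfdr)

    def test_dispersed_starts_agree_on_blfdr_surface(self):
        stats_df, _ = simulate_statistics(StatSimConfig(n_links=800, seed=31))
        long_a = MCMCConfig(n_iter=10000, n_burnin=3000, n_chains=2, thin=1, seed=99)
        long_b = MCMCConfig(n_iter=10000, n_burnin=3000, n_chains=2, thin=1, seed=1234)
        res_a = fit(stats_df, mcmc=long_a, q=0.2)
        res_b = fit(stats_df, mcmc=long_b, q=0.2)
        assert np.max(np.abs(res_a.blfdr - res_b.blfdr)) < 0.05

    def test_link_order_invariance(self):
        stats_df, _ = simulate_statistics(StatSimConfig(n_links=800, seed=41))
        shuffled = stats_df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res1 = fit(stats_df, mcmc=FAST_MCMC, q=0.2)
        res2 = fit(shuffled, mcmc=FAST_MCMC, q=0.2)
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_blfdr_is_one_minus_posterior_w(self):
        stats_df, _ = simulate_statistics(StatSimConfig(n_links=500, seed=51))
        res = fit(stats_df, mcmc=FAST_MCMC, q=0.2)
        assert np.all((res.blfdr >= 0) & (res.blfdr <= 1))

    def test_adaptive_acceptance_in_target_band(self):
        stats_df, _ = simulate_statistics(StatSimConfig(n_links=2000, seed=61))
        res = fit(stats_df, mcmc=MCMCConfig(n_iter=3000, n_burnin=1500, n_chains=2,
                                            thin=2, seed=5), q=0.2)
        for rate in res.acceptance.values():
            assert 0.15 <= rate <= 0.55

    def test_small_input_warns(self, caplog):
        stats_df, _ = simulate_statistics(StatSimConfig(n_links=30, seed=71))
        with caplog.at_level("WARNING"):
            fit(stats_df, mcmc=FAST_MCMC, q=0.2)
        assert "prior-dominated" in caplog.text

    def test_zero_sc_statistics_flagged(self):
        stats_df, _ = simulate_statistics(StatSimConfig(n_links=300, seed=81))
        stats_df = stats_df.copy()
        stats_df["tS"] = 0.0
        res = fit(stats_df, mcmc=FAST_MCMC, q=0.2)
        assert any("tS" in f for f in res.flags)
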