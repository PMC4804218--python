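import math

import numpy as np
import pytest
from scipy import integrate, stats

from foldcep.mixture import (
    GmmPriors,
    McmcSettings,
    PosteriorSample,
    SamplerState,
    TmMaxMixture,
    c3p,
    c3p_analytic,
    fit_rjmcmc,
    log_joint,
    posterior_predictive,
)
from foldcep.synthetic import generate_gmm_data

FAST = McmcSettings(iterations=6000, burn_in=1000, thin=5, seed=3)


def _state_k1(x, mu=0.8, sigma2=0.0025, beta=0.5):
    return SamplerState(
        k=1,
        w=np.array([1.0]),
        mu=np.array([mu]),
        sigma2=np.array([sigma2]),
        beta=beta,
        z=np.zeros(len(x), dtype=int),
    )


class TestLogJoint:
    def test_k1_term_by_term(self, rng):
        x = rng.uniform(0.6, 0.95, size=20)
        p = GmmPriors(xi=0.8, kappa=10.0, h=50.0)
        st_ = _state_k1(x)
        expected = (
            math.log(p.lam) - math.lgamma(2)  # Poisson kernel at k=1
            + stats.norm.logpdf(0.8, p.xi, 1.0 / math.sqrt(p.kappa))
            + stats.invgamma.logpdf(0.0025, p.alpha, scale=st_.beta)
            + stats.gamma.logpdf(st_.beta, p.g, scale=1.0 / p.h)
            + stats.norm.logpdf(x, 0.8, math.sqrt(0.0025)).sum()
        )
        # Dirichlet over a single weight contributes 0 for gamma = 1
        assert log_joint(x, st_, p) == pytest.approx(expected, abs=1e-9)

    def test_gamma_change_isolated_to_dirichlet_term(self, rng):
        x = rng.uniform(0.5, 0.9, size=15)
        st_ = SamplerState(
            k=2,
            w=np.array([0.3, 0.7]),
            mu=np.array([0.6, 0.85]),
            sigma2=np.array([0.01, 0.02]),
            beta=1.0,
            z=rng.integers(0, 2, size=15),
        )
        p1 = GmmPriors(gamma=1.0)
        p2 = GmmPriors(gamma=2.0)
        delta = log_joint(x, st_, p2) - log_joint(x, st_, p1)
        expected = stats.dirichlet.logpdf(st_.w, [2.0, 2.0]) - stats.dirichlet.logpdf(
            st_.w, [1.0, 1.0]
        )
        assert delta == pytest.approx(expected, abs=1e-9)

    def test_label_permutation_invariance(self, rng):
        x = rng.uniform(0.4, 0.95, size=25)
        z = rng.integers(0, 3, size=25)
        st1 = SamplerState(
            k=3,
            w=np.array([0.2, 0.3, 0.5]),
            mu=np.array([0.5, 0.7, 0.9]),
            sigma2=np.array([0.01, 0.02, 0.03]),
            beta=2.0,
            z=z,
        )
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        st2 = SamplerState(
            k=3, w=st1.w[perm], mu=st1.mu[perm], sigma2=st1.sigma2[perm],
            beta=2.0, z=inv[z],
        )
        p = GmmPriors()
        assert log_joint(x, st1, p) == pytest.approx(log_joint(x, st2, p), abs=1e-9)

    def test_zero_variance_rejected(self, rng):
        x = rng.uniform(size=10)
        st_ = _state_k1(x, sigma2=0.0)
        with pytest.raises(ValueError):
            log_joint(x, st_, GmmPriors())


class TestSampler:
    def test_single_component_recovery_fast(self):
        x = generate_gmm_data([1.0], [0.8], [0.05], 300, seed=7)
        res = TmMaxMixture(x).fit(settings=FAST)
        assert res.modal_k == 1
        assert res.component_means(1)[0] == pytest.approx(0.8, abs=0.02)

    def test_two_component_recovery_fast(self):
        x = generate_gmm_data([0.5, 0.5], [0.65, 0.90], [0.03, 0.02], 400, seed=11)
        res = TmMaxMixture(x).fit(settings=FAST)
        assert res.modal_k == 2
        means = res.component_means(2)
        assert means == pytest.approx([0.65, 0.90], abs=0.03)
        acc = res.diagnostics["acceptance"]["split_combine"]
        assert 0.0 < acc < 1.0

    def test_chain_reproducible_from_seed(self):
        x = generate_gmm_data([1.0], [0.8], [0.05], 60, seed=2)
        s1 = fit_rjmcmc(x, settings=McmcSettings(iterations=800, burn_in=100, thin=2, seed=5))
        s2 = fit_rjmcmc(x, settings=McmcSettings(iterations=800, burn_in=100, thin=2, seed=5))
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            assert a.k == b.k and a.beta == b.beta
            assert np.array_equal(a.mu, b.mu)
            assert np.array_equal(a.pi, b.pi)
            assert np.array_equal(a.sigma2, b.sigma2)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="CEP"):
            fit_rjmcmc(np.array([0.8, 0.81, 0.82, 0.83]))

    def test_fixed_k_matches_conjugate_posterior(self):
        # with k_max = 1 the sampler is plain Gibbs; the posterior mean of
        # mu must match the Normal-Normal closed form (known variance taken
        # at the generating value; the kappa shrinkage is what is checked)
        sigma_true = 0.05
        x = generate_gmm_data([1.0], [0.8], [sigma_true], 200, seed=13)
        priors = GmmPriors.from_data(x, k_max=1)
        samples = fit_rjmcmc(
            x, priors, McmcSettings(iterations=20000, burn_in=2000, thin=2, seed=21)
        )
        mus = np.array([s.mu[0] for s in samples])
        n = len(x)
        prec = priors.kappa + n / sigma_true**2
        closed_form = (priors.kappa * priors.xi + x.sum() / sigma_true**2) / prec
        batches = mus.reshape(20, -1).mean(axis=1)
        mc_se = batches.std(ddof=1) / math.sqrt(len(batches))
        assert abs(mus.mean() - closed_form) < 3 * max(mc_se, 1e-5)


class TestPosteriorPredictive:
    def _sample(self, k=1, pi=(1.0,), mu=(0.8,), s2=(0.0025,)):
        return PosteriorSample(k, np.array(pi), np.array(mu), np.array(s2), beta=1.0)

    def test_degenerate_variance_returns_mean(self):
        pred = posterior_predictive([self._sample(s2=(1e-16,))], draws_per_sample=50, seed=0)
        assert np.allclose(pred.draws, 0.8, atol=1e-6)

    def test_mean_matches_mixture_mean(self):
        smp = self._sample(k=2, pi=(0.3, 0.7), mu=(0.6, 0.9), s2=(0.01, 0.01))
        pred = posterior_predictive([smp] * 50, draws_per_sample=200, seed=1)
        expect = 0.3 * 0.6 + 0.7 * 0.9
        se = pred.draws.std(ddof=1) / math.sqrt(pred.draws.size)
        assert abs(pred.draws.mean() - expect) < 3 * se

    def test_seed_reproducible(self):
        smp = self._sample()
        p1 = posterior_predictive([smp], draws_per_sample=100, seed=9)
        p2 = posterior_predictive([smp], draws_per_sample=100, seed=9)
        assert np.array_equal(p1.draws, p2.draws)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            posterior_predictive([])


class TestC3P:
    def _sample(self, pi, mu, s2):
        return PosteriorSample(len(pi), np.array(pi), np.array(mu), np.array(s2), beta=1.0)

    def test_above_all_draws(self):
        smp = self._sample([1.0], [0.5], [0.001])
        pred = posterior_predictive([smp], draws_per_sample=100, seed=0)
        assert c3p(1.5, pred) == 1.0

    def test_symmetry_at_the_mean(self):
        smp = self._sample([1.0], [0.8], [0.0025])
        pred = posterior_predictive([smp] * 100, draws_per_sample=100, seed=2)
        M = pred.draws.size
        assert abs(c3p(0.8, pred) - 0.5) < 3 * math.sqrt(0.25 / M)

    def test_analytic_exact_cases(self):
        smp = self._sample([1.0], [0.8], [0.0025])
        assert c3p_analytic(0.8, [smp]) == pytest.approx(0.5, abs=1e-12)
        assert c3p_analytic(10.0, [smp]) == pytest.approx(1.0, abs=1e-12)

    def test_analytic_matches_quadrature(self, rng):
        samples = [
            self._sample(
                pi=np.ones(2) / 2,
                mu=rng.uniform(0.4, 0.95, 2),
                s2=rng.uniform(0.001, 0.01, 2),
            )
            for _ in range(2)
        ]
        s = 0.75

        def density(v):
            total = 0.0
            for smp in samples:
                total += np.sum(
                    smp.pi * stats.norm.pdf(v, smp.mu, np.sqrt(smp.sigma2))
                )
            return total / len(samples)

        quad, _ = integrate.quad(density, -2.0, s, limit=200)
        assert c3p_analytic(s, samples) == pytest.approx(quad, abs=1e-8)

    def test_monte_carlo_matches_analytic(self, rng):
        for _ in range(5):
            k = int(rng.integers(1, 4))
            pi = rng.dirichlet(np.ones(k))
            samples = [
                self._sample(pi, rng.uniform(0.3, 0.95, k), rng.uniform(0.0005, 0.01, k))
                for _ in range(10)
            ]
            s = float(rng.uniform(0.4, 0.9))
            pred = posterior_predictive(samples, draws_per_sample=1000, seed=int(rng.integers(2**31)))
            p = c3p_analytic(s, samples)
            tol = 3 * math.sqrt(max(p * (1 - p), 1e-6) / pred.draws.size)
            assert abs(c3p(s, pred) - p) <= tol

    def test_monotone_in_s(self, rng):
        samples = [self._sample([0.5, 0.5], [0.6, 0.85], [0.005, 0.005])]
        grid = np.linspace(-0.5, 1.5, 50)
        vals = [c3p_analytic(s, samples) for s in grid]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert vals[-1] == pytest.approx(1.0, abs=1e-12)


def test_summary_reports_posterior(rng):
    x = generate_gmm_data([1.0], [0.8], [0.05], 80, seed=1)
    res = TmMaxMixture(x).fit(settings=McmcSettings(iterations=1500, burn_in=300, thin=3, seed=2))
    text = res.summary()
    assert "modal k" in text
    assert "move acceptance" in text
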