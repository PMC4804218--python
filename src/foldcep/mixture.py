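"""Bayesian Gaussian mixture with unknown component count for within-fold
TM_max-scores, fitted by reversible-jump MCMC, and the cumulative posterior
predictive probability (C3P).

Model
-----
The N within-fold TM_max-scores x of a fold are modelled as i.i.d. draws
from a k-component Gaussian mixture,

    x_i | z_i ~ Normal(mu_{z_i}, sigma2_{z_i}),   P(z_i = j) = pi_j,

with the weakly informative hierarchical priors of Richardson & Green's
univariate mixture analysis:

    k       ~ Poisson(lambda=1), truncated to 1..k_max
    pi      ~ Dirichlet(gamma, ..., gamma),  gamma = 1
    mu_j    ~ Normal(xi, kappa^-1),  xi = median(x),  kappa = 1/R^2
    1/sigma2_j ~ Gamma(alpha, beta),  alpha = 2
    beta    ~ Gamma(g, h),  g = 0.2,  h = 10/R^2

where R = max(x) - min(x).  The mixture is deliberately untruncated to
(0, 1]: predictive draws outside the score range simply count as below or
above a query score.

The sampler is the Richardson-Green move set: Gibbs sweeps of pi,
(mu_j, sigma2_j), allocations z and the hyperparameter beta, a moment-
matched split/combine move, and a birth/death move for empty components.
Components are kept sorted by mean, and the ordering factor (k+1) enters
the trans-dimensional acceptance ratios accordingly.

C3P
---
The posterior predictive distribution of an unobserved TM_max-score is
estimated by Monte Carlo: for each retained posterior draw theta, sample
x~ from the mixture under theta.  C3P(s) is the fraction of predictive
draws at or below the query-fold TM_max-score s — the posterior-predictive
analogue of the cumulative empirical probability, immune to CEP's hard
zero when s falls below every observed score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm as _norm

__all__ = [
    "GmmPriors",
    "McmcSettings",
    "PosteriorSample",
    "SamplerState",
    "PosteriorPredictive",
    "log_joint",
    "fit_rjmcmc",
    "posterior_predictive",
    "c3p",
    "c3p_analytic",
    "classify_c3p",
    "TmMaxMixture",
    "TmMaxMixtureResults",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GmmPriors:
    """Hyperparameters of the mixture priors (Richardson-Green settings)."""

    gamma: float = 1.0  # Dirichlet concentration per component
    xi: float = 0.5  # prior mean of the component means
    kappa: float = 1.0  # prior precision of the component means
    alpha: float = 2.0  # shape of the precision prior
    g: float = 0.2  # shape of the hyperprior on beta
    h: float = 10.0  # rate of the hyperprior on beta
    lam: float = 1.0  # Poisson rate for k
    k_max: int = 30  # truncation of the k prior

    def __post_init__(self) -> None:
        for name in ("gamma", "kappa", "alpha", "g", "h", "lam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior parameter {name} must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    @classmethod
    def from_data(cls, x: np.ndarray, k_max: int = 30) -> "GmmPriors":
        """Data-scaled defaults: xi = median(x), kappa = 1/R^2, h = 10/R^2."""
        x = np.asarray(x, dtype=float)
        R = float(x.max() - x.min())
        R = max(R, 1e-3)  # guard against degenerate constant data
        return cls(
            gamma=1.0,
            xi=float(np.median(x)),
            kappa=1.0 / R**2,
            alpha=2.0,
            g=0.2,
            h=10.0 / R**2,
            lam=1.0,
            k_max=k_max,
        )


@dataclass(frozen=True)
class McmcSettings:
    iterations: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class PosteriorSample:
    """One retained RJMCMC draw of the mixture parameters."""

    k: int
    pi: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.pi)) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if (np.asarray(self.sigma2) <= 0).any():
            raise ValueError("variances must be positive")


@dataclass
class SamplerState:
    """Full sampler state: a parameter draw plus the latent allocations z."""

    k: int
    w: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    beta: float
    z: np.ndarray  # component label per observation, 0-based

    def sample(self) -> PosteriorSample:
        return PosteriorSample(self.k, self.w.copy(), self.mu.copy(), self.sigma2.copy(), float(self.beta))


@dataclass(frozen=True)
class PosteriorPredictive:
    """Monte-Carlo draws from the posterior predictive distribution."""

    draws: np.ndarray
    draws_per_sample: int
    seed: int


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def _log_norm_pdf(x, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _log_gamma_pdf(x, shape, rate):
    return shape * math.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def _log_invgamma_pdf(v, shape, rate):
    # density of sigma2 when 1/sigma2 ~ Gamma(shape, rate)
    return shape * math.log(rate) - gammaln(shape) - (shape + 1.0) * np.log(v) - rate / v


def _log_beta_pdf(u, a, b):
    return (
        gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * math.log(u)
        + (b - 1.0) * math.log1p(-u)
    )


def log_joint(x: np.ndarray, state: SamplerState, priors: GmmPriors) -> float:
    """Log joint density of (k, pi, mu, sigma2, beta, z, x) up to a constant.

    Component labels are exchangeable: permuting them leaves the value
    unchanged.  Empty components are valid; non-positive variances are not.
    """
    x = np.asarray(x, dtype=float)
    k = state.k
    if k < 1 or len(state.w) != k or len(state.mu) != k or len(state.sigma2) != k:
        raise ValueError("inconsistent state dimensions")
    if (state.sigma2 <= 0).any():
        raise ValueError("zero or negative variance in state")
    if len(state.z) != len(x) or state.z.min() < 0 or state.z.max() >= k:
        raise ValueError("allocations inconsistent with data/state")
    p = priors
    lp = k * math.log(p.lam) - gammaln(k + 1)  # truncated-Poisson kernel on k
    lp += gammaln(k * p.gamma) - k * gammaln(p.gamma) + (p.gamma - 1.0) * np.log(state.w).sum()
    lp += _log_norm_pdf(state.mu, p.xi, 1.0 / p.kappa).sum()
    lp += _log_invgamma_pdf(state.sigma2, p.alpha, state.beta).sum()
    lp += _log_gamma_pdf(state.beta, p.g, p.h)
    lp += np.log(state.w[state.z]).sum()
    lp += _log_norm_pdf(x, state.mu[state.z], state.sigma2[state.z]).sum()
    return float(lp)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

_W_FLOOR = 1e-300


def _initial_state(x: np.ndarray, priors: GmmPriors) -> SamplerState:
    return SamplerState(
        k=1,
        w=np.array([1.0]),
        mu=np.array([float(np.median(x))]),
        sigma2=np.array([max(float(np.var(x)), 1e-8)]),
        beta=priors.g / priors.h,
        z=np.zeros(len(x), dtype=int),
    )


def _counts(z: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(z, minlength=k)


def _gibbs_sweep(x, st: SamplerState, p: GmmPriors, rng) -> None:
    n = _counts(st.z, st.k)
    # (i) weights | z
    st.w = rng.dirichlet(p.gamma + n)
    st.w = np.maximum(st.w, _W_FLOOR)
    st.w /= st.w.sum()
    # (ii) means and variances | z, beta — means keep the sort order
    sums = np.bincount(st.z, weights=x, minlength=st.k)
    for j in range(st.k):
        prec = n[j] / st.sigma2[j] + p.kappa
        mean = (sums[j] / st.sigma2[j] + p.kappa * p.xi) / prec
        cand = rng.normal(mean, 1.0 / math.sqrt(prec))
        lo = st.mu[j - 1] if j > 0 else -np.inf
        hi = st.mu[j + 1] if j < st.k - 1 else np.inf
        if lo < cand < hi:  # reject moves that break the mean ordering
            st.mu[j] = cand
    ssq = np.bincount(st.z, weights=(x - st.mu[st.z]) ** 2, minlength=st.k)
    tau = rng.gamma(p.alpha + 0.5 * n, 1.0 / (st.beta + 0.5 * ssq))
    st.sigma2 = 1.0 / np.maximum(tau, 1e-300)
    # (iii) allocations | parameters
    logp = np.log(st.w)[None, :] + _log_norm_pdf(x[:, None], st.mu[None, :], st.sigma2[None, :])
    logp -= logp.max(axis=1, keepdims=True)
    prob = np.exp(logp)
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(len(x))
    st.z = (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)
    # (iv) beta | variances
    st.beta = rng.gamma(p.g + st.k * p.alpha, 1.0 / (p.h + (1.0 / st.sigma2).sum()))


def _b_k(k: int, k_max: int) -> float:
    """Probability of attempting the dimension-increasing move at k."""
    return 0.0 if k >= k_max else 0.5


def _d_k(k: int) -> float:
    return 0.0 if k <= 1 else 0.5


def _split_combine(x, st: SamplerState, p: GmmPriors, rng) -> bool:
    """One split-or-combine attempt; returns True if accepted."""
    k = st.k
    if rng.random() < _b_k(k, p.k_max):
        return _split(x, st, p, rng)
    if rng.random() < _d_k(k) / max(1.0 - _b_k(k, p.k_max), 1e-12):
        # reached with overall probability d_k
        return _combine(x, st, p, rng)
    return False


def _split(x, st: SamplerState, p: GmmPriors, rng) -> bool:
    k = st.k
    j = rng.integers(k)
    u1 = rng.beta(2.0, 2.0)
    u2 = rng.beta(2.0, 2.0)
    u3 = rng.beta(1.0, 1.0)
    wj, muj, s2j = st.w[j], st.mu[j], st.sigma2[j]
    sj = math.sqrt(s2j)
    w1, w2 = wj * u1, wj * (1.0 - u1)
    mu1 = muj - u2 * sj * math.sqrt(w2 / w1)
    mu2 = muj + u2 * sj * math.sqrt(w1 / w2)
    s2_1 = u3 * (1.0 - u2**2) * s2j * wj / w1
    s2_2 = (1.0 - u3) * (1.0 - u2**2) * s2j * wj / w2
    lo = st.mu[j - 1] if j > 0 else -np.inf
    hi = st.mu[j + 1] if j < k - 1 else np.inf
    if not (lo < mu1 < mu2 < hi):  # adjacency condition of the reverse combine
        return False
    if min(s2_1, s2_2, w1, w2) <= 0:
        return False

    members = np.flatnonzero(st.z == j)
    if members.size:
        l1 = math.log(w1) + _log_norm_pdf(x[members], mu1, s2_1)
        l2 = math.log(w2) + _log_norm_pdf(x[members], mu2, s2_2)
        denom = np.logaddexp(l1, l2)
        p1 = np.exp(l1 - denom)
        to_second = rng.random(members.size) >= p1
        log_palloc = float(
            np.where(to_second, np.log1p(-np.clip(p1, 0.0, 1.0 - 1e-16)), np.log(np.clip(p1, 1e-300, 1.0))).sum()
        )
    else:
        to_second = np.zeros(0, dtype=bool)
        log_palloc = 0.0

    new = SamplerState(
        k=k + 1,
        w=np.concatenate([st.w[:j], [w1, w2], st.w[j + 1 :]]),
        mu=np.concatenate([st.mu[:j], [mu1, mu2], st.mu[j + 1 :]]),
        sigma2=np.concatenate([st.sigma2[:j], [s2_1, s2_2], st.sigma2[j + 1 :]]),
        beta=st.beta,
        z=st.z.copy(),
    )
    new.z[new.z > j] += 1
    new.z[members[to_second]] = j + 1

    log_jac = (
        math.log(wj)
        + math.log(mu2 - mu1)
        + math.log(s2_1)
        + math.log(s2_2)
        - math.log(u2)
        - math.log1p(-(u2**2))
        - math.log(u3)
        - math.log1p(-u3)
        - math.log(s2j)
    )
    log_alpha = (
        log_joint(x, new, p)
        - log_joint(x, st, p)
        + math.log(k + 1)  # ordered-representation factor
        + math.log(_d_k(k + 1))
        - math.log(_b_k(k, p.k_max))
        - log_palloc
        - _log_beta_pdf(u1, 2.0, 2.0)
        - _log_beta_pdf(u2, 2.0, 2.0)
        + log_jac
    )
    if math.log(rng.random()) < log_alpha:
        st.k, st.w, st.mu, st.sigma2, st.z = new.k, new.w, new.mu, new.sigma2, new.z
        return True
    return False


def _combine(x, st: SamplerState, p: GmmPriors, rng) -> bool:
    k = st.k
    j = int(rng.integers(k - 1))  # adjacent pair (j, j+1) in mean order
    w1, w2 = st.w[j], st.w[j + 1]
    mu1, mu2 = st.mu[j], st.mu[j + 1]
    s2_1, s2_2 = st.sigma2[j], st.sigma2[j + 1]
    wj = w1 + w2
    muj = (w1 * mu1 + w2 * mu2) / wj
    s2j = (w1 * (mu1**2 + s2_1) + w2 * (mu2**2 + s2_2)) / wj - muj**2
    if s2j <= 0:
        return False
    # invert the split construction to recover the auxiliary variables
    u1 = w1 / wj
    u2 = (muj - mu1) / math.sqrt(s2j * w2 / w1)
    if not (0.0 < u2 < 1.0):
        return False
    u3 = s2_1 * w1 / ((1.0 - u2**2) * s2j * wj)
    if not (0.0 < u3 < 1.0):
        return False

    new = SamplerState(
        k=k - 1,
        w=np.concatenate([st.w[:j], [wj], st.w[j + 2 :]]),
        mu=np.concatenate([st.mu[:j], [muj], st.mu[j + 2 :]]),
        sigma2=np.concatenate([st.sigma2[:j], [s2j], st.sigma2[j + 2 :]]),
        beta=st.beta,
        z=st.z.copy(),
    )
    members = np.flatnonzero((st.z == j) | (st.z == j + 1))
    new.z[st.z == j + 1] = j
    new.z[st.z > j + 1] -= 1

    if members.size:
        l1 = math.log(w1) + _log_norm_pdf(x[members], mu1, s2_1)
        l2 = math.log(w2) + _log_norm_pdf(x[members], mu2, s2_2)
        denom = np.logaddexp(l1, l2)
        p1 = np.exp(l1 - denom)
        was_second = st.z[members] == j + 1
        log_palloc = float(
            np.where(
                was_second,
                np.log1p(-np.clip(p1, 0.0, 1.0 - 1e-16)),
                np.log(np.clip(p1, 1e-300, 1.0)),
            ).sum()
        )
    else:
        log_palloc = 0.0

    log_jac = (
        math.log(wj)
        + math.log(mu2 - mu1)
        + math.log(s2_1)
        + math.log(s2_2)
        - math.log(u2)
        - math.log1p(-(u2**2))
        - math.log(u3)
        - math.log1p(-u3)
        - math.log(s2j)
    )
    log_alpha = (
        log_joint(x, new, p)
        - log_joint(x, st, p)
        - math.log(k)  # ordered-representation factor, reversed
        + math.log(_b_k(k - 1, p.k_max))
        - math.log(_d_k(k))
        + log_palloc
        + _log_beta_pdf(u1, 2.0, 2.0)
        + _log_beta_pdf(u2, 2.0, 2.0)
        - log_jac
    )
    if math.log(rng.random()) < log_alpha:
        st.k, st.w, st.mu, st.sigma2, st.z = new.k, new.w, new.mu, new.sigma2, new.z
        return True
    return False


def _birth_death(x, st: SamplerState, p: GmmPriors, rng) -> bool:
    k = st.k
    if rng.random() < _b_k(k, p.k_max):
        return _birth(x, st, p, rng)
    if rng.random() < _d_k(k) / max(1.0 - _b_k(k, p.k_max), 1e-12):
        return _death(x, st, p, rng)
    return False


def _log_birth_terms(x, small: SamplerState, big: SamplerState, p: GmmPriors,
                     w_star: float, mu_star: float, s2_star: float, n_empty_big: int) -> float:
    """log acceptance ratio of the birth small -> big (negate for death)."""
    k = small.k
    return (
        log_joint(x, big, p)
        - log_joint(x, small, p)
        + math.log(k + 1)  # ordered-representation factor
        + math.log(_d_k(k + 1))
        - math.log(n_empty_big)
        - math.log(_b_k(k, p.k_max))
        - _log_beta_pdf(w_star, 1.0, float(k))
        - float(_log_norm_pdf(mu_star, p.xi, 1.0 / p.kappa))
        - float(_log_invgamma_pdf(s2_star, p.alpha, small.beta))
        + (k - 1) * math.log1p(-w_star)  # Jacobian of the weight rescale
    )


def _birth(x, st: SamplerState, p: GmmPriors, rng) -> bool:
    k = st.k
    w_star = rng.beta(1.0, k)
    if not (0.0 < w_star < 1.0):
        return False
    mu_star = rng.normal(p.xi, 1.0 / math.sqrt(p.kappa))
    s2_star = 1.0 / rng.gamma(p.alpha, 1.0 / st.beta)
    pos = int(np.searchsorted(st.mu, mu_star))
    new = SamplerState(
        k=k + 1,
        w=np.insert(st.w * (1.0 - w_star), pos, w_star),
        mu=np.insert(st.mu, pos, mu_star),
        sigma2=np.insert(st.sigma2, pos, s2_star),
        beta=st.beta,
        z=st.z.copy(),
    )
    new.z[new.z >= pos] += 1
    n_empty_big = int((_counts(new.z, new.k) == 0).sum())
    log_alpha = _log_birth_terms(x, st, new, p, w_star, mu_star, s2_star, n_empty_big)
    if math.log(rng.random()) < log_alpha:
        st.k, st.w, st.mu, st.sigma2, st.z = new.k, new.w, new.mu, new.sigma2, new.z
        return True
    return False


def _death(x, st: SamplerState, p: GmmPriors, rng) -> bool:
    k = st.k
    n = _counts(st.z, k)
    empties = np.flatnonzero(n == 0)
    if empties.size == 0:
        return False
    j = int(empties[rng.integers(empties.size)])
    w_star = float(st.w[j])
    if w_star >= 1.0:
        return False
    new = SamplerState(
        k=k - 1,
        w=np.delete(st.w, j) / (1.0 - w_star),
        mu=np.delete(st.mu, j),
        sigma2=np.delete(st.sigma2, j),
        beta=st.beta,
        z=st.z.copy(),
    )
    new.z[new.z > j] -= 1
    log_alpha = -_log_birth_terms(
        x, new, st, p, w_star, float(st.mu[j]), float(st.sigma2[j]), int(empties.size)
    )
    if math.log(rng.random()) < log_alpha:
        st.k, st.w, st.mu, st.sigma2, st.z = new.k, new.w, new.mu, new.sigma2, new.z
        return True
    return False


def _run_sampler(x, priors: GmmPriors, settings: McmcSettings):
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError(
            "need at least 5 observations to fit the mixture; "
            "fall back to the empirical CEP for such folds"
        )
    if not np.isfinite(x).all():
        raise ValueError("non-finite data")
    rng = np.random.default_rng(settings.seed)
    st = _initial_state(x, priors)
    samples: list[PosteriorSample] = []
    k_trace = np.empty(settings.iterations, dtype=int)
    moves = {"split_combine": [0, 0], "birth_death": [0, 0]}
    for it in range(settings.iterations):
        _gibbs_sweep(x, st, priors, rng)
        if priors.k_max > 1:
            acc = _split_combine(x, st, priors, rng)
            moves["split_combine"][0] += 1
            moves["split_combine"][1] += int(acc)
            acc = _birth_death(x, st, priors, rng)
            moves["birth_death"][0] += 1
            moves["birth_death"][1] += int(acc)
        k_trace[it] = st.k
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            samples.append(st.sample())
    diagnostics = {
        "k_trace": k_trace,
        "acceptance": {
            name: (cnt[1] / cnt[0] if cnt[0] else float("nan")) for name, cnt in moves.items()
        },
        "n_retained": len(samples),
    }
    return samples, diagnostics


def fit_rjmcmc(
    x: np.ndarray,
    priors: GmmPriors | None = None,
    settings: McmcSettings | None = None,
) -> list[PosteriorSample]:
    """Fit the mixture to a within-fold TM_max vector; returns retained draws."""
    x = np.asarray(x, dtype=float)
    if priors is None:
        priors = GmmPriors.from_data(x)
    if settings is None:
        settings = McmcSettings()
    samples, _ = _run_sampler(x, priors, settings)
    return samples


# ---------------------------------------------------------------------------
# Posterior predictive and C3P
# ---------------------------------------------------------------------------

def posterior_predictive(
    samples: Sequence[PosteriorSample],
    draws_per_sample: int = 1,
    seed: int = 0,
) -> PosteriorPredictive:
    """Sample unobserved TM_max-scores: per retained draw, pick a component
    by its weight then draw from its Gaussian.  Draws are not truncated."""
    samples = list(samples)
    if not samples:
        raise ValueError("no posterior samples")
    rng = np.random.default_rng(seed)
    out = np.empty(len(samples) * draws_per_sample)
    pos = 0
    for s in samples:
        comp = rng.choice(s.k, size=draws_per_sample, p=s.pi / s.pi.sum())
        out[pos : pos + draws_per_sample] = rng.normal(
            s.mu[comp], np.sqrt(s.sigma2[comp])
        )
        pos += draws_per_sample
    return PosteriorPredictive(out, draws_per_sample, seed)


def c3p(s: float, predictive: PosteriorPredictive) -> float:
    """Fraction of posterior-predictive draws <= s (inclusive, as in CEP)."""
    draws = predictive.draws
    if draws.size == 0:
        raise ValueError("empty posterior predictive")
    return float(np.mean(draws <= s))


def c3p_analytic(s: float, samples: Sequence[PosteriorSample]) -> float:
    """Rao-Blackwellized C3P: average mixture CDF at s over posterior draws."""
    samples = list(samples)
    if not samples:
        raise ValueError("no posterior samples")
    total = 0.0
    for smp in samples:
        total += float(np.sum(smp.pi * _norm.cdf((s - smp.mu) / np.sqrt(smp.sigma2))))
    return total / len(samples)


def classify_c3p(
    query_id: str,
    matrix,
    profiles,
    fitted: dict,
    predictive_draws: int = 1,
    seed: int = 0,
    analytic: bool = True,
):
    """Assign a query to the fold with the highest C3P (same protocol as CEP)."""
    from .classify import classify

    return classify(
        query_id,
        matrix,
        profiles,
        method="c3p",
        fitted=fitted,
        predictive_draws=predictive_draws,
        seed=seed,
        analytic=analytic,
    )


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------

class TmMaxMixture:
    """Gaussian mixture model (unknown k) for a fold's TM_max-scores.

    Parameters
    ----------
    endog : array-like
        The within-fold TM_max vector x of one fold, values in (0, 1].
    priors : GmmPriors, optional
        Defaults to the data-scaled Richardson-Green settings.

    Examples
    --------
    >>> res = TmMaxMixture(x).fit(seed=1)
    >>> res.modal_k
    1
    >>> res.c3p(0.85)
    """

    def __init__(self, endog, priors: GmmPriors | None = None):
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        self.priors = priors if priors is not None else GmmPriors.from_data(self.endog)

    def fit(
        self,
        iterations: int = 30_000,
        burn_in: int = 5_000,
        thin: int = 5,
        seed: int = 0,
        settings: McmcSettings | None = None,
    ) -> "TmMaxMixtureResults":
        if settings is None:
            settings = McmcSettings(iterations=iterations, burn_in=burn_in, thin=thin, seed=seed)
        samples, diagnostics = _run_sampler(self.endog, self.priors, settings)
        return TmMaxMixtureResults(self, samples, diagnostics, settings)


class TmMaxMixtureResults:
    """Posterior summary of a fitted :class:`TmMaxMixture`."""

    def __init__(self, model, samples, diagnostics, settings):
        self.model = model
        self.samples = samples
        self.diagnostics = diagnostics
        self.settings = settings

    @property
    def k_values(self) -> np.ndarray:
        return np.array([s.k for s in self.samples])

    @property
    def k_posterior(self) -> dict[int, float]:
        vals, counts = np.unique(self.k_values, return_counts=True)
        return {int(v): float(c) / len(self.samples) for v, c in zip(vals, counts)}

    @property
    def modal_k(self) -> int:
        post = self.k_posterior
        return max(post, key=lambda k: (post[k], -k))

    def component_means(self, k: int | None = None) -> np.ndarray:
        """Posterior-mean component means among draws with the given k
        (default: modal k); components are in ascending mean order."""
        k = self.modal_k if k is None else k
        sel = [s.mu for s in self.samples if s.k == k]
        if not sel:
            raise ValueError(f"no retained draws with k={k}")
        return np.mean(sel, axis=0)

    def posterior_predictive(self, draws_per_sample: int = 1, seed: int = 0) -> PosteriorPredictive:
        return posterior_predictive(self.samples, draws_per_sample, seed)

    def c3p(self, s: float, draws_per_sample: int = 1, seed: int = 0) -> float:
        return c3p(s, self.posterior_predictive(draws_per_sample, seed))

    def c3p_analytic(self, s: float) -> float:
        return c3p_analytic(s, self.samples)

    def summary(self) -> str:
        post = self.k_posterior
        lines = [
            "Gaussian mixture posterior (reversible-jump MCMC)",
            "=" * 50,
            f"observations:        {len(self.model.endog)}",
            f"iterations/burn/thin: {self.settings.iterations}/{self.settings.burn_in}/{self.settings.thin}",
            f"retained draws:      {len(self.samples)}",
            f"modal k:             {self.modal_k}",
            "P(k | x):            "
            + ", ".join(f"k={k}: {p:.3f}" for k, p in sorted(post.items())),
        ]
        try:
            means = self.component_means()
            lines.append(
                f"component means (k={self.modal_k}): "
                + ", ".join(f"{m:.4f}" for m in means)
            )
        except ValueError:
            pass
        acc = self.diagnostics["acceptance"]
        lines.append(
            "move acceptance:     "
            + ", ".join(f"{name}: {rate:.3f}" for name, rate in acc.items())
        )
        return "\n".join(lines)
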