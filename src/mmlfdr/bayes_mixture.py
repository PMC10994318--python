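"""Stage 2: the Bayesian multimodal local false discovery rate (BLfdr).

The model is a two-group mixture for the magnitude of the FC statistic
:math:`t_i = |t_i(F)|` at each link, with the SC statistic magnitude
:math:`s_i = |t_i(S)|` acting as auxiliary information:

* null links (no FC group difference): :math:`t_i` follows a zero-mean
  folded normal (half-normal) with unknown variance :math:`\\sigma^2`,
  density :math:`f_0(t) = \\sqrt{2 / (\\pi \\sigma^2)}\\,
  e^{-t^2 / 2\\sigma^2}`;
* alternative links: :math:`t_i \\sim \\mathrm{Gamma}(\\alpha(s_i),
  \\beta)` with a log-linear shape link
  :math:`\\alpha(s) = \\exp(\\gamma_0 + \\gamma_1 s)` and an SC-free rate
  :math:`\\beta`;
* a latent indicator :math:`w_i \\in \\{0, 1\\}` selects the component,
  with a logistic prior weight
  :math:`\\pi_i = \\Pr(w_i = 1) = \\mathrm{logit}^{-1}(\\eta_0 +
  \\eta_1 s_i)`.

The BLfdr of link :math:`i` is the posterior probability that it is null
given both statistics; conditional on the parameters,

.. math::

    \\mathrm{BLfdr}_i = \\frac{(1 - \\pi_i) f_0(t_i)}
        {(1 - \\pi_i) f_0(t_i) + \\pi_i f_1(t_i; \\alpha(s_i), \\beta)},

and the reported value marginalizes over parameter uncertainty as the
posterior mean of :math:`1 - w_i` across MCMC draws.

Inference is Metropolis-within-Gibbs: exact conjugate updates for
:math:`\\sigma^2` (inverse-gamma) and :math:`\\beta` (gamma), Gaussian
random-walk Metropolis for the coefficient pairs :math:`(\\gamma_0,
\\gamma_1)` and :math:`(\\eta_0, \\eta_1)` with optional scale
adaptation during burn-in only.

Significant links at FDR level ``q`` are chosen by the adaptive
step-up rule on sorted BLfdr values: reject the largest prefix whose
running mean stays at or below ``q``, which bounds the estimated FDR of
the rejected set by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .connectivity_io import validate_link_statistics

logger = logging.getLogger(__name__)

_LOG_SQRT_2_OVER_PI = 0.5 * np.log(2.0 / np.pi)
#: |t| is clamped away from zero before gamma-density evaluation so that
#: shapes alpha < 1 (density unbounded at 0) cannot produce infinities
T_FLOOR = 1e-8
#: cap on the gamma shape to keep exp(gamma0 + gamma1 * s) finite
ALPHA_CAP = 1e6


# ---------------------------------------------------------------------------
# parameters and configuration
# ---------------------------------------------------------------------------

@dataclass
class MixtureParams:
    """Parameters of the two-group mixture.

    sigma2 : null folded-normal variance (> 0)
    beta : gamma rate of the alternative (> 0)
    gamma0, gamma1 : log-linear shape coefficients, alpha(s) = exp(g0 + g1 s)
    eta0, eta1 : logistic prior-weight coefficients, pi(s) = logit^-1(e0 + e1 s)
    """

    sigma2: float = 1.0
    beta: float = 1.0
    gamma0: float = 0.0
    gamma1: float = 0.0
    eta0: float = 0.0
    eta1: float = 0.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        vals = [self.sigma2, self.beta, self.gamma0, self.gamma1, self.eta0, self.eta1]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all mixture parameters must be finite")


@dataclass
class PriorConfig:
    """Hyperparameters of the (weakly informative, proper) priors.

    gamma and eta coefficients get independent normal priors; sigma2 an
    inverse-gamma(a0, b0); beta a gamma(c0, d0) (shape/rate).
    """

    gamma_prior_mean: tuple[float, float] = (0.0, 0.0)
    gamma_prior_var: tuple[float, float] = (100.0, 100.0)
    eta_prior_mean: tuple[float, float] = (0.0, 0.0)
    eta_prior_var: tuple[float, float] = (100.0, 100.0)
    sigma2_prior: tuple[float, float] = (2.0, 2.0)   # IG(a0, b0)
    beta_prior: tuple[float, float] = (1.0, 1.0)     # Gamma(c0, d0)

    def __post_init__(self):
        for v in (*self.gamma_prior_var, *self.eta_prior_var,
                  *self.sigma2_prior, *self.beta_prior):
            if v <= 0:
                raise ValueError("variance/shape/rate hyperparameters must be > 0")


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``proposal_scales`` are the random-walk standard deviations for the
    gamma and eta blocks; with ``adapt=True`` they are tuned toward a 0.3
    acceptance rate during burn-in and frozen afterwards (preserving
    detailed balance for the kept draws).
    """

    n_iter: int = 10_000
    n_burnin: int = 5_000
    n_chains: int = 4
    thin: int = 5
    seed: int = 0
    proposal_scales: dict = field(
        default_factory=lambda: {"gamma": 0.1, "eta": 0.3}
    )
    adapt: bool = True

    def __post_init__(self):
        if not (0 < self.n_burnin < self.n_iter):
            raise ValueError("need 0 < n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


# ---------------------------------------------------------------------------
# densities and the closed-form BLfdr
# ---------------------------------------------------------------------------

def log_f0(t, sigma2):
    """Log density of the zero-mean folded normal (half-normal) at t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("folded-normal support is t >= 0")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    out = _LOG_SQRT_2_OVER_PI - 0.5 * np.log(sigma2) - t * t / (2.0 * sigma2)
    return out.item() if out.ndim == 0 else out


def log_f1(t, alpha, beta):
    """Log gamma density with shape alpha and rate beta at t > 0."""
    t = np.asarray(t, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(t <= 0):
        raise ValueError("gamma support is t > 0")
    if np.any(alpha <= 0) or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    out = alpha * np.log(beta) + (alpha - 1.0) * np.log(t) - beta * t - special.gammaln(alpha)
    return out.item() if out.ndim == 0 else out


def alpha_link(s, gamma0, gamma1):
    """Log-linear shape link alpha(s) = exp(gamma0 + gamma1 * s), capped."""
    s = np.asarray(s, dtype=float)
    out = np.exp(np.minimum(gamma0 + gamma1 * s, np.log(ALPHA_CAP)))
    return out.item() if out.ndim == 0 else out


def pi_link(s, eta0, eta1):
    """Logistic prior non-null probability pi(s) = logit^-1(eta0 + eta1 s)."""
    s = np.asarray(s, dtype=float)
    out = special.expit(eta0 + eta1 * s)
    return out.item() if out.ndim == 0 else out


def blfdr_given_params(tF_abs, s, params: MixtureParams):
    """Conditional BLfdr: posterior null probability given the parameters.

    Computed in log space; |t| is floored at ``T_FLOOR`` so shapes below 1
    cannot blow up the alternative density at zero.
    """
    t = np.maximum(np.asarray(tF_abs, dtype=float), T_FLOOR)
    s = np.asarray(s, dtype=float)
    pi = pi_link(s, params.eta0, params.eta1)
    alpha = alpha_link(s, params.gamma0, params.gamma1)
    l0 = log_f0(t, params.sigma2) + np.log1p(-np.minimum(pi, 1 - 1e-300))
    with np.errstate(divide="ignore"):
        l1 = log_f1(t, alpha, params.beta) + np.log(pi)
    # stable normalization: blfdr = 1 / (1 + exp(l1 - l0))
    out = special.expit(l0 - l1)
    out = np.where(pi == 0.0, 1.0, out)
    out = np.where(pi == 1.0, 0.0, out)
    return out.item() if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Gibbs / Metropolis updates
# ---------------------------------------------------------------------------

def gibbs_step_w(tF_abs, s, params: MixtureParams, rng: np.random.Generator):
    """Draw the latent indicators w_i ~ Bernoulli(1 - BLfdr_i | params)."""
    p1 = 1.0 - blfdr_given_params(tF_abs, s, params)
    return (rng.random(np.shape(p1)) < p1).astype(np.int8)


def gibbs_step_sigma2(t_null, prior_ig, rng: np.random.Generator) -> float:
    """Conjugate inverse-gamma draw for the null variance.

    The half-normal likelihood of the null-assigned magnitudes gives
    sigma2 | ... ~ IG(a0 + n0/2, b0 + sum(t^2)/2); an empty null set
    falls back to the prior.
    """
    a0, b0 = prior_ig
    t_null = np.asarray(t_null, dtype=float)
    a = a0 + 0.5 * t_null.size
    b = b0 + 0.5 * float(np.sum(t_null * t_null))
    return 1.0 / rng.gamma(a, 1.0 / b)


def gibbs_step_beta(t_alt, alpha_alt, prior_gamma, rng: np.random.Generator) -> float:
    """Conjugate gamma draw for the alternative rate.

    beta | ... ~ Gamma(c0 + sum(alpha_i), d0 + sum(t_i)) over the
    alternative-assigned links; an empty set falls back to the prior.
    """
    c0, d0 = prior_gamma
    t_alt = np.asarray(t_alt, dtype=float)
    alpha_alt = np.asarray(alpha_alt, dtype=float)
    c = c0 + float(np.sum(alpha_alt))
    d = d0 + float(np.sum(t_alt))
    return rng.gamma(c, 1.0 / d)


def _log_post_gamma(gam, t_alt, log_t_alt, s_alt, beta, prior_mean, prior_var):
    """Unnormalized log posterior of (gamma0, gamma1) given the alternative set."""
    lp = -0.5 * np.sum((gam - prior_mean) ** 2 / prior_var)
    if t_alt.size:
        alpha = np.exp(np.minimum(gam[0] + gam[1] * s_alt, np.log(ALPHA_CAP)))
        lp += float(
            np.sum(alpha * np.log(beta) + (alpha - 1.0) * log_t_alt
                   - beta * t_alt - special.gammaln(alpha))
        )
    return lp


def _log_post_eta(eta, w, s, prior_mean, prior_var):
    """Unnormalized log posterior of (eta0, eta1) given all indicators."""
    lp = -0.5 * np.sum((eta - prior_mean) ** 2 / prior_var)
    z = eta[0] + eta[1] * s
    # Bernoulli log-likelihood: w*z - log(1 + e^z), numerically stable
    lp += float(np.sum(w * z - np.logaddexp(0.0, z)))
    return lp


def metropolis_step_coeffs(log_post, current, current_lp, scale, rng):
    """One Gaussian random-walk Metropolis update of a 2-vector block.

    ``scale`` is either a scalar (isotropic proposal sd) or a 2x2 lower
    Cholesky factor of the proposal covariance.  Returns (value, log
    posterior, accepted flag).
    """
    z = rng.standard_normal(2)
    step = scale @ z if np.ndim(scale) == 2 else scale * z
    prop = current + step
    lp_prop = log_post(prop)
    if np.log(rng.random()) < lp_prop - current_lp:
        return prop, lp_prop, True
    return current, current_lp, False


# ---------------------------------------------------------------------------
# the full sampler
# ---------------------------------------------------------------------------

@dataclass
class BlfdrResult:
    """Posterior summaries of a BLfdr fit.

    ``table`` has one row per link in the input order with columns
    ``region1, region2, tF, tS, blfdr, rejected, direction``; ``blfdr`` is
    the posterior mean of the null indicator (1 - mean of w).
    """

    table: pd.DataFrame
    params_mean: dict
    params_sd: dict
    params_ci: dict
    rhat: dict
    acceptance: dict
    q: float
    est_fdr: float
    threshold_index: int
    n_kept_draws: int
    flags: list = field(default_factory=list)
    draws: dict | None = None

    @property
    def blfdr(self) -> np.ndarray:
        return self.table["blfdr"].to_numpy()

    @property
    def rejected(self) -> pd.DataFrame:
        return self.table[self.table["rejected"] == 1]

    def summary_dict(self) -> dict:
        """JSON-serializable record sufficient to re-run the analysis."""
        return {
            "params_mean": self.params_mean,
            "params_sd": self.params_sd,
            "params_ci": self.params_ci,
            "rhat": self.rhat,
            "acceptance": self.acceptance,
            "q": self.q,
            "est_fdr": self.est_fdr,
            "n_rejected": int(self.table["rejected"].sum()),
            "n_kept_draws": self.n_kept_draws,
            "flags": self.flags,
        }


_PARAM_NAMES = ("sigma2", "beta", "gamma0", "gamma1", "eta0", "eta1")


def _run_chain(t, s, priors: PriorConfig, mcmc: MCMCConfig, rng, init: MixtureParams):
    """One Metropolis-within-Gibbs chain; returns kept draws.

    The alpha-dependent per-link quantities (gamma shape, its gammaln and
    the (alpha-1)*log t term) are cached and refreshed only when a gamma
    proposal is accepted; likewise the logistic weights for eta.  This is
    purely an evaluation cache — the target distribution is untouched.
    """
    n = t.size
    log_t = np.log(t)
    gam = np.array([init.gamma0, init.gamma1], dtype=float)
    eta = np.array([init.eta0, init.eta1], dtype=float)
    sigma2 = init.sigma2
    beta = init.beta
    g_mean = np.asarray(priors.gamma_prior_mean, dtype=float)
    g_var = np.asarray(priors.gamma_prior_var, dtype=float)
    e_mean = np.asarray(priors.eta_prior_mean, dtype=float)
    e_var = np.asarray(priors.eta_prior_var, dtype=float)

    # proposal state: isotropic scale to start, adaptive-Metropolis
    # covariance (2.38^2/d * empirical cov) learned during burn-in
    scales = {k: float(v) * np.eye(2) for k, v in mcmc.proposal_scales.items()}
    n_keep = (mcmc.n_iter - mcmc.n_burnin + mcmc.thin - 1) // mcmc.thin
    kept_params = np.empty((n_keep, len(_PARAM_NAMES)))
    w_sum = np.zeros(n)
    accept = {"gamma": 0, "eta": 0}
    attempts = {"gamma": 0, "eta": 0}
    adapt_accept = {"gamma": 0, "eta": 0}
    adapt_window = 50
    log_mult = {"gamma": 0.0, "eta": 0.0}  # acceptance-tuned multiplier
    hist = {"gamma": np.empty((mcmc.n_burnin, 2)), "eta": np.empty((mcmc.n_burnin, 2))}

    t_sq = t * t
    log_cap = np.log(ALPHA_CAP)

    def alpha_cache(g):
        a = np.exp(np.minimum(g[0] + g[1] * s, log_cap))
        return a, (a - 1.0) * log_t, special.gammaln(a)

    alpha, am1_logt, gln_alpha = alpha_cache(gam)
    logit_w = eta[0] + eta[1] * s  # logistic weights cache

    k = 0
    for it in range(mcmc.n_iter):
        # --- latent indicators: w_i ~ Bern(1 - blfdr_i | params),
        # computed from the cached per-link quantities
        l0 = (_LOG_SQRT_2_OVER_PI - 0.5 * np.log(sigma2)) - t_sq / (2.0 * sigma2)
        l1 = alpha * np.log(beta) + am1_logt - beta * t - gln_alpha
        # log odds of non-null: logit(pi) + l1 - l0
        w = (rng.random(n) < special.expit(logit_w + l1 - l0)).astype(np.int8)
        is_alt = w == 1
        t_alt, log_t_alt, s_alt = t[is_alt], log_t[is_alt], s[is_alt]

        # conjugate blocks
        sigma2 = gibbs_step_sigma2(t[~is_alt], priors.sigma2_prior, rng)
        beta = gibbs_step_beta(t_alt, alpha[is_alt], priors.beta_prior, rng)

        # Metropolis blocks
        lp_g = _log_post_gamma(gam, t_alt, log_t_alt, s_alt, beta, g_mean, g_var)
        gam, lp_g, acc_g = metropolis_step_coeffs(
            lambda v: _log_post_gamma(v, t_alt, log_t_alt, s_alt, beta, g_mean, g_var),
            gam, lp_g, scales["gamma"], rng,
        )
        if acc_g:
            alpha, am1_logt, gln_alpha = alpha_cache(gam)
        lp_e = _log_post_eta(eta, w, s, e_mean, e_var)
        eta, lp_e, acc_e = metropolis_step_coeffs(
            lambda v: _log_post_eta(v, w, s, e_mean, e_var),
            eta, lp_e, scales["eta"], rng,
        )
        if acc_e:
            logit_w = eta[0] + eta[1] * s

        in_burnin = it < mcmc.n_burnin
        if in_burnin:
            hist["gamma"][it] = gam
            hist["eta"][it] = eta
        for name, acc in (("gamma", acc_g), ("eta", acc_e)):
            if in_burnin:
                adapt_accept[name] += acc
            else:
                attempts[name] += 1
                accept[name] += acc
        if mcmc.adapt and in_burnin and (it + 1) % adapt_window == 0:
            # adaptive Metropolis: proposal covariance from the burn-in
            # history (2.38^2/d scaling), with a Robbins-Monro acceptance
            # correction; frozen after burn-in to preserve detailed balance
            for name in ("gamma", "eta"):
                rate = adapt_accept[name] / adapt_window
                adapt_accept[name] = 0
                if it + 1 < 200:
                    # early phase: isotropic multiplicative tuning
                    scales[name] *= np.exp(0.5 * (rate - 0.3))
                    continue
                log_mult[name] += 0.5 * (rate - 0.3)
                recent = hist[name][(it + 1) // 2: it + 1]
                cov = (2.38**2 / 2.0) * np.cov(recent.T) + 1e-8 * np.eye(2)
                try:
                    scales[name] = np.exp(log_mult[name]) * np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass

        state = np.array([sigma2, beta, gam[0], gam[1], eta[0], eta[1]])
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"non-finite sampler state at iteration {it}")

        if not in_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
            kept_params[k] = state
            w_sum += w
            k += 1

    acc_rates = {
        name: (accept[name] / attempts[name]) if attempts[name] else float("nan")
        for name in ("gamma", "eta")
    }
    return kept_params[:k], w_sum / k, acc_rates, scales


def fit(
    stats: pd.DataFrame,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
    q: float = 0.2,
    keep_draws: bool = False,
) -> BlfdrResult:
    """Fit the multimodal mixture by MCMC and decide at FDR level ``q``.

    Parameters
    ----------
    stats
        LinkStatistics table (``region1, region2, tF, tS``).
    priors, mcmc
        Prior hyperparameters and sampler settings (defaults as in
        :class:`PriorConfig` / :class:`MCMCConfig`).
    q
        Nominal FDR level for the decision rule.
    keep_draws
        Retain the per-chain parameter draws on the result (for
        diagnostics plots); off by default to save memory.
    """
    import arviz as az

    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    stats = validate_link_statistics(stats)
    n = len(stats)
    if n < 50:
        logger.warning("only %d links; mixture fit will be prior-dominated", n)

    # canonical (sorted) link order makes results invariant to input order;
    # validate_link_statistics has already sorted by region pair
    t = np.maximum(np.abs(stats["tF"].to_numpy()), T_FLOOR)
    s = np.abs(stats["tS"].to_numpy())

    flags = []
    if np.all(s == 0):
        flags.append("all |tS| zero: gamma1 and eta1 are prior-dominated")

    master = np.random.SeedSequence(mcmc.seed)
    chain_seeds = master.spawn(mcmc.n_chains)
    all_params, all_wmean = [], []
    acc_all = []
    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        # overdispersed starts
        init = MixtureParams(
            sigma2=float(np.exp(rng.normal(0.0, 0.3))),
            beta=float(np.exp(rng.normal(0.0, 0.3))),
            gamma0=float(rng.normal(0.5, 0.5)),
            gamma1=float(rng.normal(0.0, 0.2)),
            eta0=float(rng.normal(-2.0, 0.5)),
            eta1=float(rng.normal(0.0, 0.2)),
        )
        kp, wmean, acc, _ = _run_chain(t, s, priors, mcmc, rng, init)
        all_params.append(kp)
        all_wmean.append(wmean)
        acc_all.append(acc)

    draws = np.stack(all_params)  # (chains, kept, 6)
    w_mean = np.mean(all_wmean, axis=0)
    blfdr = np.clip(1.0 - w_mean, 0.0, 1.0)

    idata = az.from_dict(
        posterior={name: draws[:, :, j] for j, name in enumerate(_PARAM_NAMES)}
    )
    rhat_ds = az.rhat(idata)
    rhat = {name: float(rhat_ds[name].values) for name in _PARAM_NAMES}
    bad = [k for k, v in rhat.items() if np.isfinite(v) and v > 1.1]
    if bad:
        flags.append(f"R-hat > 1.1 for: {', '.join(bad)}")
        logger.warning("convergence flags: %s", flags[-1])

    flat = draws.reshape(-1, len(_PARAM_NAMES))
    params_mean = {k: float(v) for k, v in zip(_PARAM_NAMES, flat.mean(axis=0))}
    params_sd = {k: float(v) for k, v in zip(_PARAM_NAMES, flat.std(axis=0, ddof=1))}
    lo, hi = np.percentile(flat, [5.0, 95.0], axis=0)
    params_ci = {k: (float(a), float(b)) for k, a, b in zip(_PARAM_NAMES, lo, hi)}

    reject_idx, threshold_index, est_fdr = decide(blfdr, q)
    rejected = np.zeros(n, dtype=int)
    rejected[reject_idx] = 1

    table = stats.loc[:, ["region1", "region2", "tF", "tS"]].copy()
    table["blfdr"] = blfdr
    table["rejected"] = rejected
    table["direction"] = np.where(table["tF"] > 0, "hyper",
                                  np.where(table["tF"] < 0, "hypo", "none"))

    acceptance = {
        k: float(np.mean([a[k] for a in acc_all])) for k in ("gamma", "eta")
    }
    return BlfdrResult(
        table=table,
        params_mean=params_mean,
        params_sd=params_sd,
        params_ci=params_ci,
        rhat=rhat,
        acceptance=acceptance,
        q=q,
        est_fdr=est_fdr,
        threshold_index=threshold_index,
        n_kept_draws=int(draws.shape[0] * draws.shape[1]),
        flags=flags,
        draws={n_: draws[:, :, j] for j, n_ in enumerate(_PARAM_NAMES)} if keep_draws else None,
    )


def decide(blfdr, q: float):
    """Adaptive FDR thresholding of local fdr values.

    Sorts the values ascending and rejects the largest prefix whose
    running mean is <= ``q``; ties at the cutoff value are included only
    if the running mean over all of them stays <= ``q``.  Returns
    ``(indices of rejected links, k*, estimated FDR of the rejected
    set)`` where the estimated FDR is the running mean at the cutoff
    (0.0 when nothing is rejected).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    blfdr = np.asarray(blfdr, dtype=float)
    n = blfdr.size
    if n == 0:
        return np.array([], dtype=int), 0, 0.0
    order = np.argsort(blfdr, kind="stable")
    sorted_vals = blfdr[order]
    # running mean of ascending values is nondecreasing, so the feasible
    # prefixes form an initial segment
    running = np.cumsum(sorted_vals) / np.arange(1, n + 1)
    ok = np.nonzero(running <= q)[0]
    if ok.size == 0:
        return np.array([], dtype=int), 0, 0.0
    k = int(ok[-1]) + 1
    # ties at the cutoff value go in together or not at all; including the
    # whole group would push the running mean above q (monotonicity), so a
    # split tie group is dropped entirely
    cut = sorted_vals[k - 1]
    hi = int(np.searchsorted(sorted_vals, cut, side="right"))
    if hi > k:
        k = int(np.searchsorted(sorted_vals, cut, side="left"))
    if k == 0:
        return np.array([], dtype=int), 0, 0.0
    return np.sort(order[:k]), k, float(running[k - 1])
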