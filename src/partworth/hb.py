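"""Hierarchical Bayesian multinomial logit estimated by Metropolis-within-Gibbs.

Model
-----
Respondent ``i`` chooses alternative ``j`` in task ``t`` with probability
``softmax_j(x_tj' beta_i)``.  Individual part-worth vectors are exchangeable
draws from a population multivariate normal,

    beta_i ~ N(mu, Sigma),
    mu ~ N(0, s2 * I),            (weakly informative, s2 = 100)
    Sigma ~ InvWishart(nu0, S0),  (nu0 = p + 3, S0 = I)

Sampling alternates per-respondent random-walk Metropolis updates of beta_i
(multivariate normal proposal shaped by the current Sigma, step size adapted
during burn-in toward ~23% acceptance; ``beta_scans`` scans per cycle) with
conjugate Gibbs draws of mu and Sigma.  All randomness descends from a
single seed; runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import invwishart

from .data import RespondentChoices
from .design import ChoiceDesign
from .schema import CodingMap

__all__ = ["MCMCSettings", "HBPosterior", "mnl_loglik", "fit_hb"]


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration.

    The documented full-scale profile runs 3 chains of 350,000 monitoring
    iterations after 150,000 burn-in each; desk-scale work passes smaller
    counts.  ``thin`` controls how many monitoring draws are stored
    (``n_monitor // thin`` per chain).
    """

    n_chains: int = 3
    n_burnin: int = 150_000
    n_monitor: int = 350_000
    thin: int = 350
    beta_scans: int = 3
    adapt_window: int = 50
    accept_target: float = 0.23
    mu_prior_var: float = 100.0
    wishart_df: float | None = None  # default p + 3
    wishart_scale: float | None = None  # default identity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("convergence diagnostics require >= 2 chains")
        if min(self.n_burnin, self.n_monitor, self.thin) <= 0:
            raise ValueError("iteration counts must be positive")
        if self.thin > self.n_monitor:
            raise ValueError("thin exceeds the monitoring run")


@dataclass
class HBPosterior:
    """MCMC draws organised by chain.

    ``beta`` has shape (chains, kept, respondents, p); ``mu`` (chains, kept,
    p); ``sigma`` (chains, kept, p, p).
    """

    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    loglik: np.ndarray  # (chains, kept) total data log-likelihood
    acceptance: np.ndarray  # (chains, respondents) monitoring-phase rates
    respondent_ids: list[str] = field(default_factory=list)
    settings: MCMCSettings | None = None

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        """Kept draws per chain."""
        return self.mu.shape[1]

    @property
    def p(self) -> int:
        return self.mu.shape[2]

    def mu_draws(self) -> np.ndarray:
        """Pooled population-mean draws, shape (chains * kept, p)."""
        return self.mu.reshape(-1, self.p)

    def beta_draws(self) -> np.ndarray:
        """Pooled individual part-worth draws, shape (chains * kept, n, p)."""
        return self.beta.reshape(-1, *self.beta.shape[2:])


def mnl_loglik(beta: np.ndarray, coded_tasks: np.ndarray, choices: np.ndarray) -> float:
    """Multinomial-logit log-likelihood for one respondent.

    ``coded_tasks`` is (T, A, p); ``choices`` the chosen alternative index per
    task.  Computed as ``sum_t [x_chosen' beta - logsumexp_j x_j' beta]``.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    u = coded_tasks @ beta  # (T, A)
    m = u.max(axis=-1)
    lse = m + np.log(np.exp(u - m[:, None]).sum(axis=-1))
    chosen = np.take_along_axis(u, np.asarray(choices)[:, None], axis=-1)[:, 0]
    return float((chosen - lse).sum())


def _loglik_all(beta: np.ndarray, X: np.ndarray, choices: np.ndarray) -> np.ndarray:
    """Vectorised per-respondent log-likelihoods.  X: (n, T, A, p)."""
    u = np.einsum("ntap,np->nta", X, beta)
    m = u.max(axis=-1)
    lse = m + np.log(np.exp(u - m[..., None]).sum(axis=-1))
    chosen = np.take_along_axis(u, choices[..., None], axis=-1)[..., 0]
    return (chosen - lse).sum(axis=-1)


def fit_hb(
    data: RespondentChoices,
    design: ChoiceDesign,
    coding: CodingMap,
    settings: MCMCSettings | None = None,
) -> HBPosterior:
    """Fit the hierarchical model; deterministic given ``settings.seed``.

    Warm-up answers never enter the likelihood: only the main-task cells of
    each respondent's design version are coded.
    """
    settings = settings or MCMCSettings()
    data.validate_against(design)
    n = data.n_respondents
    if n < 2:
        raise ValueError("hierarchical estimation needs >= 2 respondents")
    p = coding.n_columns
    coded = coding.code_design(design.cells)  # (V, T, A, p)
    X = coded[data.versions]  # (n, T, A, p)
    choices = data.choices

    nu0 = settings.wishart_df if settings.wishart_df is not None else p + 3
    S0 = (
        np.asarray(settings.wishart_scale, dtype=float)
        if settings.wishart_scale is not None
        else np.eye(p)
    )
    n_kept = settings.n_monitor // settings.thin
    beta_out = np.empty((settings.n_chains, n_kept, n, p))
    mu_out = np.empty((settings.n_chains, n_kept, p))
    sigma_out = np.empty((settings.n_chains, n_kept, p, p))
    ll_out = np.empty((settings.n_chains, n_kept))
    acc_out = np.empty((settings.n_chains, n))

    children = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    for c in range(settings.n_chains):
        rng = np.random.default_rng(children[c])
        _run_chain(
            rng, X, choices, nu0, S0, settings,
            beta_out[c], mu_out[c], sigma_out[c], ll_out[c], acc_out[c],
        )
    return HBPosterior(
        beta=beta_out,
        mu=mu_out,
        sigma=sigma_out,
        loglik=ll_out,
        acceptance=acc_out,
        respondent_ids=list(data.respondent_ids),
        settings=settings,
    )


def _run_chain(rng, X, choices, nu0, S0, settings, beta_out, mu_out, sigma_out, ll_out, acc_out):
    n, _, _, p = X.shape
    beta = rng.normal(scale=0.1, size=(n, p))
    mu = np.zeros(p)
    sigma = np.eye(p)
    step = np.full(n, 0.3)
    ll = _loglik_all(beta, X, choices)
    win_acc = np.zeros(n)
    mon_acc = np.zeros(n)
    total = settings.n_burnin + settings.n_monitor
    kept = 0
    prior_prec_mu = 1.0 / settings.mu_prior_var
    scans = max(1, settings.beta_scans)
    for it in range(total):
        chol = linalg.cholesky(sigma, lower=True)
        # several random-walk scans per conjugate cycle improve mixing of the
        # hierarchy relative to one scan at the same stored-draw count
        for _ in range(scans):
            z = rng.standard_normal((n, p))
            prop = beta + step[:, None] * (z @ chol.T)
            ll_prop = _loglik_all(prop, X, choices)
            # prior terms: -0.5 (b - mu)' Sigma^-1 (b - mu)
            dev = linalg.solve_triangular(chol, (beta - mu).T, lower=True)
            dev_p = linalg.solve_triangular(chol, (prop - mu).T, lower=True)
            logr = (ll_prop - ll) - 0.5 * ((dev_p**2).sum(axis=0) - (dev**2).sum(axis=0))
            accept = np.log(rng.random(n)) < logr
            beta[accept] = prop[accept]
            ll[accept] = ll_prop[accept]
            win_acc += accept
            if it >= settings.n_burnin:
                mon_acc += accept
        if it < settings.n_burnin and (it + 1) % settings.adapt_window == 0:
            rate = win_acc / (settings.adapt_window * scans)
            step *= np.exp(0.5 * (rate - settings.accept_target))
            np.clip(step, 1e-4, 10.0, out=step)
            win_acc[:] = 0.0

        # Gibbs: mu | beta, Sigma  ~  N(m, P^-1)
        sigma_inv = linalg.cho_solve((chol, True), np.eye(p))
        prec = n * sigma_inv + prior_prec_mu * np.eye(p)
        chol_prec = linalg.cholesky(prec, lower=True)
        m = linalg.cho_solve((chol_prec, True), sigma_inv @ beta.sum(axis=0))
        mu = m + linalg.solve_triangular(
            chol_prec.T, rng.standard_normal(p), lower=False
        )
        # Gibbs: Sigma | beta, mu  ~  IW(nu0 + n, S0 + sum of outer products)
        centered = beta - mu
        scale = S0 + centered.T @ centered
        sigma = invwishart.rvs(df=nu0 + n, scale=scale, random_state=rng)

        if it >= settings.n_burnin and (it - settings.n_burnin) % settings.thin == settings.thin - 1:
            beta_out[kept] = beta
            mu_out[kept] = mu
            sigma_out[kept] = sigma
            ll_out[kept] = ll.sum()
            kept += 1
    acc_out[:] = mon_acc / (settings.n_monitor * scans)
    low, high = acc_out.min(), acc_out.max()
    if low < 0.05 or high > 0.8:
        warnings.warn(
            f"Metropolis acceptance rates outside [0.05, 0.8] (min {low:.3f}, "
            f"max {high:.3f}); adaptation may not have converged",
            RuntimeWarning,
            stacklevel=3,
        )
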