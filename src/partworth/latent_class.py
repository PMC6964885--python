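"""Latent-class multinomial logit mixtures fitted by EM.

Respondents are modelled as belonging to one of K classes, each with its own
homogeneous part-worth vector; the mixture likelihood for respondent i is

    L_i = sum_k pi_k * prod_t P_MNL(choice_it | beta_k).

The E-step computes responsibilities r_ik, the M-step updates shares as the
responsibility means and each beta_k by responsibility-weighted MNL maximum
likelihood (BFGS with analytic gradient, warm-started — a generalised EM
step, so the log-likelihood never decreases).  Multi-start guards against
local optima; class count is chosen by BIC with the respondent count as the
sample size (the mixture is over respondents, not choice observations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import RespondentChoices
from .design import ChoiceDesign
from .schema import CodingMap

__all__ = ["LatentClassSolution", "fit_lc", "assign_classes", "ClassAssignment"]


@dataclass
class LatentClassSolution:
    n_classes: int
    shares: np.ndarray  # (K,)
    betas: np.ndarray  # (K, p)
    responsibilities: np.ndarray  # (n_resp, K)
    loglik: float
    bic: float
    n_params: int
    n_starts: int
    converged: bool
    ll_trace: list[float]


def _resp_class_loglik(betas: np.ndarray, X: np.ndarray, choices: np.ndarray) -> np.ndarray:
    """Log-likelihood of each respondent's choices under each class, (n, K)."""
    u = np.einsum("ntap,kp->knta", X, betas)  # (K, n, T, A)
    m = u.max(axis=-1)
    lse = m + np.log(np.exp(u - m[..., None]).sum(axis=-1))
    chosen = np.take_along_axis(
        u, np.broadcast_to(choices[None, :, :, None], m.shape + (1,)), axis=-1
    )[..., 0]
    return (chosen - lse).sum(axis=-1).T  # (n, K)


def _weighted_mnl_negll_grad(beta, X, choices, weights, Xc):
    """Responsibility-weighted MNL negative log-likelihood and gradient."""
    u = np.einsum("ntap,p->nta", X, beta)
    m = u.max(axis=-1, keepdims=True)
    e = np.exp(u - m)
    denom = e.sum(axis=-1, keepdims=True)
    probs = e / denom
    lse = (m + np.log(denom))[..., 0]
    chosen_u = np.take_along_axis(u, choices[..., None], axis=-1)[..., 0]
    ll = (weights * (chosen_u - lse).sum(axis=-1)).sum()
    # gradient: sum_i w_i sum_t (x_chosen - sum_j p_j x_j)
    expected = np.einsum("nta,ntap->ntp", probs, X)
    grad = (weights[:, None] * (Xc - expected).sum(axis=1)).sum(axis=0)
    return -ll, -grad


def fit_lc(
    data: RespondentChoices,
    design: ChoiceDesign,
    coding: CodingMap,
    n_classes: int,
    n_starts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> LatentClassSolution:
    """Fit a K-class MNL mixture by EM, best of ``n_starts`` random starts.

    ``tol`` is the relative log-likelihood change that stops EM.  A class
    whose share collapses below 1/(10 n) is perturbed and refloored rather
    than left empty.  With ``n_classes=1`` this reduces to a pooled MNL
    maximum-likelihood fit.
    """
    if n_classes < 1 or n_starts < 1:
        raise ValueError("n_classes and n_starts must be >= 1")
    data.validate_against(design)
    n = data.n_respondents
    p = coding.n_columns
    coded = coding.code_design(design.cells)
    X = coded[data.versions]  # (n, T, A, p)
    choices = data.choices
    Xc = np.take_along_axis(
        X, choices[:, :, None, None].repeat(p, axis=-1), axis=2
    )[:, :, 0, :]  # (n, T, p) chosen covariates

    rng = np.random.default_rng(seed)
    best: LatentClassSolution | None = None
    for _ in range(n_starts):
        sol = _em_once(X, Xc, choices, n_classes, tol, max_iter, rng)
        if best is None or sol.loglik > best.loglik:
            best = sol
    q = n_classes * p + (n_classes - 1)
    best.n_params = q
    best.bic = -2.0 * best.loglik + q * np.log(n)
    best.n_starts = n_starts
    return best


def _em_once(X, Xc, choices, K, tol, max_iter, rng) -> LatentClassSolution:
    n, _, _, p = X.shape
    betas = rng.normal(scale=0.3, size=(K, p))
    log_pi = np.full(K, -np.log(K))
    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    floor = 1.0 / (10.0 * n)
    for _ in range(max_iter):
        # E-step
        cls_ll = _resp_class_loglik(betas, X, choices)  # (n, K)
        joint = cls_ll + log_pi
        ll = float(logsumexp(joint, axis=1).sum())
        resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        trace.append(ll)
        if ll + 1e-9 < ll_prev:
            raise RuntimeError("EM log-likelihood decreased")  # GEM guarantee violated
        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M-step
        pi = resp.mean(axis=0)
        empty = pi < floor
        if empty.any():
            betas[empty] += rng.normal(scale=0.5, size=(int(empty.sum()), p))
            pi = np.maximum(pi, floor)
            pi /= pi.sum()
        log_pi = np.log(pi)
        for k in range(K):
            res = minimize(
                _weighted_mnl_negll_grad,
                betas[k],
                args=(X, choices, resp[:, k], Xc),
                jac=True,
                method="BFGS",
                options={"maxiter": 50, "gtol": 1e-7},
            )
            betas[k] = res.x
    cls_ll = _resp_class_loglik(betas, X, choices)
    joint = cls_ll + log_pi
    ll = float(logsumexp(joint, axis=1).sum())
    resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    return LatentClassSolution(
        n_classes=K,
        shares=np.exp(log_pi),
        betas=betas,
        responsibilities=resp,
        loglik=ll,
        bic=np.nan,
        n_params=K * p + (K - 1),
        n_starts=1,
        converged=converged,
        ll_trace=trace,
    )


@dataclass
class ClassAssignment:
    assignments: np.ndarray  # (n_resp,) class index
    max_probability: np.ndarray  # (n_resp,)
    tie_flags: np.ndarray  # (n_resp,) bool
    below_threshold: np.ndarray  # (n_resp,) bool
    n_below_threshold: int
    fraction_below_threshold: float
    threshold: float


def assign_classes(solution: LatentClassSolution, threshold: float = 0.90) -> ClassAssignment:
    """Maximum-posterior-probability class assignment with certainty summary.

    Ties go to the lowest class index and are flagged; the report counts
    respondents whose maximum membership probability falls below
    ``threshold`` (default 0.90), a standard certainty audit.
    """
    resp = solution.responsibilities
    assignments = resp.argmax(axis=1)
    max_prob = resp.max(axis=1)
    ties = (np.isclose(resp, max_prob[:, None])).sum(axis=1) > 1
    below = max_prob < threshold
    return ClassAssignment(
        assignments=assignments,
        max_probability=max_prob,
        tie_flags=ties,
        below_threshold=below,
        n_below_threshold=int(below.sum()),
        fraction_below_threshold=float(below.mean()),
        threshold=threshold,
    )
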