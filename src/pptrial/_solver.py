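"""Weighted logistic regression by Newton-Raphson (IRLS).

A single small solver backs every pooled logistic fit in the package:
propensity-score mechanisms, the proportional-hazards MSM, and all of
their bootstrap refits.  Rolling our own keeps a full pipeline replicate
in the low tens of milliseconds, which the bootstrap machinery depends
on; tests cross-check the solver against statsmodels GLM.

Numerical conventions:
 - linear predictors are clipped to +/-ETA_MAX before the inverse logit,
   and coefficients are clipped to the same box after each Newton step,
   so quasi-separated indicator cells saturate instead of diverging;
 - a tiny ridge (1e-10) stabilises the Hessian solve;
 - convergence is declared when the Newton step is below ``tol`` relative
   to the coefficient magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

ETA_MAX = 30.0

__all__ = ["LogisticFit", "fit_logistic"]


@dataclass
class LogisticFit:
    beta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separated: bool
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray | None:
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))


def _loglik(eta: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> float:
    # sum w * (y*eta - log(1 + exp(eta))), computed stably
    core = y * eta - np.logaddexp(0.0, eta)
    if w is not None:
        core = w * core
    return float(core.sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    ridge: float = 1e-10,
    compute_cov: bool = False,
    fast: bool = False,
) -> LogisticFit:
    """Maximise the (weighted) Bernoulli log-likelihood of ``y`` on ``X``.

    ``weights`` act as prior/case weights (the estimating-equation weights
    of a weighted MSM fit), not frequency weights; ``compute_cov`` returns
    the naive inverse-Hessian covariance for z-diagnostics.  ``fast``
    skips the likelihood bookkeeping and step-halving safeguard — plain
    Newton, intended for warm-started bootstrap refits.
    """
    if fast:
        return _fit_fast(X, y, weights, beta0=beta0, max_iter=max_iter,
                         tol=tol, ridge=ridge)
    n, p = X.shape
    y = np.asarray(y, dtype=np.float64)
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=np.float64)
    eye = np.eye(p)

    eta = np.clip(X @ beta, -ETA_MAX, ETA_MAX)
    ll = _loglik(eta, y, weights)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        resid = y - mu
        wdiag = mu * (1.0 - mu)
        if weights is not None:
            resid = weights * resid
            wdiag = weights * wdiag
        grad = X.T @ resid
        hess = (X * wdiag[:, None]).T @ X + ridge * eye
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]

        # step-halving keeps the ascent monotone on badly scaled starts
        new_beta = np.clip(beta + step, -ETA_MAX, ETA_MAX)
        new_eta = np.clip(X @ new_beta, -ETA_MAX, ETA_MAX)
        new_ll = _loglik(new_eta, y, weights)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 8:
            step = 0.5 * step
            new_beta = np.clip(beta + step, -ETA_MAX, ETA_MAX)
            new_eta = np.clip(X @ new_beta, -ETA_MAX, ETA_MAX)
            new_ll = _loglik(new_eta, y, weights)
            halvings += 1

        delta = np.max(np.abs(new_beta - beta))
        beta, eta, ll = new_beta, new_eta, new_ll
        if delta <= tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break

    separated = bool(np.any(np.abs(beta) >= ETA_MAX - 1e-6))
    cov = None
    if compute_cov:
        mu = expit(eta)
        wdiag = mu * (1.0 - mu)
        if weights is not None:
            wdiag = weights * wdiag
        hess = (X * wdiag[:, None]).T @ X + ridge * np.eye(p)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
    return LogisticFit(beta=beta, loglik=ll, n_iter=it, converged=converged,
                       separated=separated, cov=cov)


def _fit_fast(X, y, weights, *, beta0, max_iter, tol, ridge) -> LogisticFit:
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=np.float64)
    eye = ridge * np.eye(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -ETA_MAX, ETA_MAX)
        mu = expit(eta)
        resid = y - mu
        wdiag = mu * (1.0 - mu)
        if weights is not None:
            resid = weights * resid
            wdiag = weights * wdiag
        grad = X.T @ resid
        hess = (X * wdiag[:, None]).T @ X + eye
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        new_beta = np.clip(beta + step, -ETA_MAX, ETA_MAX)
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta <= tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    separated = bool(np.any(np.abs(beta) >= ETA_MAX - 1e-6))
    return LogisticFit(beta=beta, loglik=np.nan, n_iter=it, converged=converged,
                       separated=separated, cov=None)
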