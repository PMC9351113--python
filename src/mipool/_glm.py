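"""Fast Newton/IRLS fitters for small logistic and multinomial models.

Backward elimination across multiply imputed stacks evaluates thousands of
small logistic regressions per replication (n <= a few thousand rows, a
dozen columns).  This module provides a lean Newton solver for that hot
path: binary logistic ML with optional ridge stabilisation and warm starts,
a multinomial (baseline-category) logit used by the chained-equations
imputer, and plain log-likelihood evaluation at fixed parameters (needed by
the Meng-Rubin pooled likelihood-ratio test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import expit


class FitError(RuntimeError):
    """Raised when a model cannot be fitted even after ridge stabilisation."""


@dataclass
class LogitFit:
    beta: np.ndarray          # (p,)
    cov: np.ndarray           # (p, p) inverse observed information
    loglik: float
    converged: bool
    ridged: bool              # True if the ridge fallback was used


def logit_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Bernoulli log-likelihood at ``beta`` (numerically stable)."""
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _newton_logit(X, y, beta, ridge, pen_mask, max_iter, tol):
    """Newton-Raphson with step halving; returns (beta, H, ll, converged)."""
    ll = logit_loglik(X, y, beta) - 0.5 * ridge * float(pen_mask @ beta**2)
    H = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * pen_mask * beta
        H = (X * w[:, None]).T @ X
        if ridge:
            H = H + ridge * np.diag(pen_mask)
        try:
            c = cho_factor(H, check_finite=False)
        except LinAlgError:
            return beta, H, ll, False
        step = cho_solve(c, grad, check_finite=False)
        # step halving to guarantee ascent
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = logit_loglik(X, y, cand) - 0.5 * ridge * float(pen_mask @ cand**2)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            return beta, H, ll, False
        beta = cand
        improved = ll_new - ll
        ll = ll_new
        if improved < tol and np.max(np.abs(t * step)) < 1e-6:
            return beta, H, ll, True
    return beta, H, ll, False


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
    ridge_fallback: float = 1e-3,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> LogitFit:
    """Fit a binary logistic regression by Newton-Raphson.

    On non-convergence or a singular Hessian (separation, empty dummy
    columns) the fit is retried with a mild ridge penalty on the
    non-intercept columns (column 0 is assumed to be the intercept).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=np.float64).copy()
    pen_mask = np.zeros(p)
    beta_hat, H, ll, ok = _newton_logit(X, y, beta, 0.0, pen_mask, max_iter, tol)
    ridged = False
    if not ok or not np.all(np.isfinite(beta_hat)):
        pen_mask = np.ones(p)
        pen_mask[0] = 0.0
        beta_hat, H, ll, ok = _newton_logit(
            X, y, np.zeros(p), ridge_fallback, pen_mask, max_iter, tol
        )
        ridged = True
        if not ok:
            raise FitError("logistic fit failed to converge even with ridge")
        ll = logit_loglik(X, y, beta_hat)  # report unpenalised log-likelihood
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise FitError("singular information matrix") from exc
    return LogitFit(beta=beta_hat, cov=cov, loglik=float(ll), converged=ok, ridged=ridged)


# ---------------------------------------------------------------------------
# multinomial (baseline-category) logit, used by the imputer
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    beta: np.ndarray          # (p, C-1), class 0 is the reference
    cov: np.ndarray           # (p*(C-1), p*(C-1)), Fortran-order vec of beta
    loglik: float
    converged: bool
    ridged: bool


def multinomial_probs(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Class probabilities (n, C) under a baseline-category logit."""
    eta = X @ beta                                   # (n, C-1)
    eta = np.concatenate([np.zeros((X.shape[0], 1)), eta], axis=1)
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)


def _mn_loglik(X, Y, beta, ridge):
    P = multinomial_probs(X, beta)
    ll = float(np.sum(Y * np.log(np.clip(P, 1e-300, None))))
    if ridge:
        ll -= 0.5 * ridge * float(np.sum(beta[1:] ** 2))
    return ll


def fit_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    ridge: float = 0.0,
    ridge_fallback: float = 0.05,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> MultinomialFit:
    """Baseline-category multinomial logit via full Newton iterations.

    ``y`` holds integer codes 0..n_classes-1; class 0 is the reference.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.intp)
    n, p = X.shape
    C = n_classes
    Y = np.zeros((n, C))
    Y[np.arange(n), y] = 1.0

    def run(lam):
        beta = np.zeros((p, C - 1))
        ll = _mn_loglik(X, Y, beta, lam)
        H = None
        for _ in range(max_iter):
            P = multinomial_probs(X, beta)
            grad = (X.T @ (Y[:, 1:] - P[:, 1:])).ravel(order="F")
            K = p * (C - 1)
            H = np.empty((K, K))
            for j in range(1, C):
                for k in range(j, C):
                    w = P[:, j] * ((j == k) - P[:, k])
                    blk = (X * w[:, None]).T @ X
                    H[(j - 1) * p:j * p, (k - 1) * p:k * p] = blk
                    H[(k - 1) * p:k * p, (j - 1) * p:j * p] = blk.T
            if lam:
                pen = np.ones(p)
                pen[0] = 0.0
                H += lam * np.diag(np.tile(pen, C - 1))
                grad -= lam * np.tile(pen, C - 1) * beta.ravel(order="F")
            try:
                c = cho_factor(H, check_finite=False)
            except LinAlgError:
                return beta, H, ll, False
            step = cho_solve(c, grad, check_finite=False).reshape((p, C - 1), order="F")
            t = 1.0
            for _ in range(30):
                cand = beta + t * step
                ll_new = _mn_loglik(X, Y, cand, lam)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                t *= 0.5
            else:
                return beta, H, ll, False
            beta = cand
            improved = ll_new - ll
            ll = ll_new
            if improved < tol:
                return beta, H, ll, True
        return beta, H, ll, False

    beta, H, ll, ok = run(ridge)
    ridged = bool(ridge)
    if not ok:
        beta, H, ll, ok = run(ridge_fallback)
        ridged = True
        if not ok:
            raise FitError("multinomial fit failed to converge even with ridge")
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise FitError("singular multinomial information matrix") from exc
    return MultinomialFit(beta=beta, cov=cov, loglik=float(ll), converged=ok, ridged=ridged)
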