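"""Pooled significance tests for multiply imputed data.

After multiple imputation, a model is fitted in each of the ``m`` completed
datasets and per-imputation results must be combined into one test per
predictor (or per block of dummy terms for a categorical predictor).  This
module implements the five standard procedures:

* :func:`pool_rubin` -- Rubin's Rules for a single scalar parameter, with the
  Barnard-Rubin small-sample degrees of freedom;
* :func:`d1_test` -- the pooled multivariate Wald test (D1), which combines
  within- and between-imputation covariance of a k-vector of estimates;
* :func:`d2_test` -- pooling of per-imputation chi-square statistics (D2)
  via the variance of their square roots;
* :func:`d3_test` -- the Meng-Rubin pooled likelihood-ratio test (D3), which
  re-evaluates the per-imputation likelihoods at parameter estimates
  averaged across imputations;
* :func:`mpr_test` -- the median-p-rule, the median of the m per-imputation
  p-values.

The D1/D2/D3 small-sample reference distributions are F(k, df2) with the
denominator degrees of freedom of the canonical published forms, including
the alternative branch for k*(m-1) <= 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, LinAlgError

__all__ = [
    "RepeatedEstimates",
    "PoolSummary",
    "PooledTestResult",
    "pool_rubin",
    "d1_test",
    "d2_test",
    "d3_test",
    "mpr_test",
]


@dataclass
class RepeatedEstimates:
    """Per-imputation estimates for one tested parameter block.

    Parameters
    ----------
    theta : (m, k) array
        Parameter estimates from each of the m imputed datasets.
    U : (m, k, k) array
        Within-imputation covariance matrices.
    n_obs : int
        Rows per completed dataset (used for the complete-data df).
    p_model : int
        Total number of parameters in the fitted model, intercept included.
    loglik : (m,) array, optional
        Maximised log-likelihoods, when a likelihood-based test is wanted.
    """

    theta: np.ndarray
    U: np.ndarray
    n_obs: int
    p_model: int
    loglik: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        U = np.asarray(self.U, dtype=float)
        if U.ndim == 1:
            U = U.reshape(-1, 1, 1)
        self.U = U
        if self.theta.shape[0] != self.U.shape[0]:
            raise ValueError("theta and U disagree on the number of imputations")
        if not np.allclose(self.U, np.swapaxes(self.U, 1, 2), atol=1e-8):
            raise ValueError("within-imputation covariances must be symmetric")

    @property
    def m(self) -> int:
        return self.theta.shape[0]

    @property
    def k(self) -> int:
        return self.theta.shape[1]


@dataclass(frozen=True)
class PoolSummary:
    """Rubin's Rules summary of repeated scalar estimates."""

    qbar: float
    ubar: float
    B: float
    T: float
    riv: float
    nu: float


@dataclass(frozen=True)
class PooledTestResult:
    method: str
    p: float
    statistic: float | None = None
    df1: float | None = None
    df2: float | None = None


def _barnard_rubin_nu(lam: float, m: int, nu_com: float) -> float:
    """Barnard-Rubin adjusted df for a scalar pooled estimate."""
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    if lam <= 0.0:
        return nu_obs
    nu_old = (m - 1.0) / lam**2
    return 1.0 / (1.0 / nu_old + 1.0 / nu_obs)


def pool_rubin(rep: RepeatedEstimates) -> tuple[PoolSummary, PooledTestResult]:
    """Rubin's Rules for a scalar parameter with a Wald t test of theta = 0.

    T = Ubar + (1 + 1/m) B; the reference distribution is Student t with the
    Barnard-Rubin degrees of freedom using nu_com = n_obs - p_model.
    """
    if rep.k != 1:
        raise ValueError("pool_rubin handles scalar parameters only; use d1_test")
    if rep.m < 2:
        raise ValueError("between-imputation variance requires m >= 2")
    theta = rep.theta[:, 0]
    u = rep.U[:, 0, 0]
    m = rep.m
    qbar = float(theta.mean())
    ubar = float(u.mean())
    B = float(theta.var(ddof=1))
    T = ubar + (1.0 + 1.0 / m) * B
    riv = (1.0 + 1.0 / m) * B / ubar if ubar > 0 else np.inf
    lam = (1.0 + 1.0 / m) * B / T if T > 0 else 0.0
    nu_com = rep.n_obs - rep.p_model
    if nu_com <= 0:
        raise ValueError("model has no residual degrees of freedom")
    nu = _barnard_rubin_nu(lam, m, nu_com)
    tstat = qbar / np.sqrt(T)
    p = float(2.0 * stats.t.sf(abs(tstat), nu))
    summary = PoolSummary(qbar=qbar, ubar=ubar, B=B, T=T, riv=riv, nu=nu)
    return summary, PooledTestResult(method="RR", p=p, statistic=float(tstat), df1=1.0, df2=nu)


def _small_sample_df2(r: float, k: int, m: int) -> float:
    """Denominator df for the D1/D3 family; +inf in the r -> 0 limit."""
    if r <= 0.0:
        return np.inf
    t = k * (m - 1.0)
    if t > 4.0:
        return 4.0 + (t - 4.0) * (1.0 + (1.0 - 2.0 / t) / r) ** 2
    return 0.5 * t * (1.0 + 1.0 / k) * (1.0 + 1.0 / r) ** 2


def _f_sf(stat: float, k: int, df2: float) -> float:
    if not np.isfinite(df2):
        return float(stats.chi2.sf(k * stat, k))
    return float(stats.f.sf(stat, k, df2))


def d1_test(rep: RepeatedEstimates, k: int | None = None) -> PooledTestResult:
    """Pooled multivariate Wald test (D1) of theta = 0.

    Uses the average within covariance Ubar inflated by the average relative
    increase in variance r1 = (1+1/m) tr(B Ubar^-1)/k.
    """
    if rep.m < 2:
        raise ValueError("d1_test requires m >= 2")
    if k is None:
        k = rep.k
    if k != rep.k:
        raise ValueError("k does not match the estimate dimension")
    m = rep.m
    qbar = rep.theta.mean(axis=0)
    ubar = rep.U.mean(axis=0)
    dev = rep.theta - qbar
    B = dev.T @ dev / (m - 1.0)
    try:
        c = cho_factor(ubar, check_finite=False)
    except LinAlgError as exc:
        raise ValueError(
            "singular pooled within-imputation covariance Ubar; the tested "
            "block may contain an empty dummy column"
        ) from exc
    r1 = (1.0 + 1.0 / m) * float(np.trace(cho_solve(c, B, check_finite=False))) / k
    r1 = max(r1, 0.0)
    wald = float(qbar @ cho_solve(c, qbar, check_finite=False))
    stat = wald / (k * (1.0 + r1))
    df2 = _small_sample_df2(r1, k, m)
    return PooledTestResult(method="D1", p=_f_sf(stat, k, df2), statistic=stat, df1=float(k), df2=df2)


def d2_test(d: Sequence[float], k: int) -> PooledTestResult:
    """Pool per-imputation chi-square statistics (D2).

    ``d`` holds one k-df chi-square statistic (Wald or likelihood ratio) per
    imputed dataset.  A negative combined statistic is truncated to zero.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("d2_test needs a vector of m >= 2 chi-square statistics")
    if np.any(d < 0):
        raise ValueError("chi-square statistics must be non-negative")
    m = d.size
    dbar = float(d.mean())
    r2 = (1.0 + 1.0 / m) * float(np.sqrt(d).var(ddof=1))
    if r2 <= 0.0:
        stat = dbar / k
        return PooledTestResult(method="D2", p=_f_sf(stat, k, np.inf), statistic=stat,
                                df1=float(k), df2=np.inf)
    stat = (dbar / k - (m + 1.0) / (m - 1.0) * r2) / (1.0 + r2)
    df2 = k ** (-3.0 / m) * (m - 1.0) * (1.0 + 1.0 / r2) ** 2
    if stat <= 0.0:
        return PooledTestResult(method="D2", p=1.0, statistic=0.0, df1=float(k), df2=df2)
    return PooledTestResult(method="D2", p=float(stats.f.sf(stat, k, df2)),
                            statistic=stat, df1=float(k), df2=df2)


def d3_test(
    datasets: Sequence,
    fit_full: Callable,
    fit_reduced: Callable,
    loglik_full: Callable,
    loglik_reduced: Callable,
    k: int,
) -> PooledTestResult:
    """Meng-Rubin pooled likelihood-ratio test (D3).

    Parameters
    ----------
    datasets : sequence of m imputed datasets (opaque; only passed through).
    fit_full, fit_reduced : callables ``dataset -> (theta, loglik)``
        Maximum-likelihood fit of the full / reduced (nested) model.
    loglik_full, loglik_reduced : callables ``(dataset, theta) -> loglik``
        Log-likelihood evaluation at fixed parameters.
    k : number of parameters constrained by the reduced model.

    The per-imputation LR statistics d_l are averaged; both parameter vectors
    are averaged across imputations and the likelihoods re-evaluated at the
    pooled parameters give the dtilde_l whose mean forms the test statistic.
    """
    m = len(datasets)
    if m < 2:
        raise ValueError("d3_test requires m >= 2 datasets")
    th_full, th_red, d_l = [], [], []
    for ds in datasets:
        tf, llf = fit_full(ds)
        tr, llr = fit_reduced(ds)
        if llr > llf + 1e-8:
            raise ValueError("reduced model log-likelihood exceeds the full model; models not nested")
        th_full.append(np.asarray(tf, dtype=float))
        th_red.append(np.asarray(tr, dtype=float))
        d_l.append(2.0 * (llf - llr))
    dbar = float(np.mean(d_l))
    tbar_full = np.mean(th_full, axis=0)
    tbar_red = np.mean(th_red, axis=0)
    dtil = [2.0 * (loglik_full(ds, tbar_full) - loglik_reduced(ds, tbar_red)) for ds in datasets]
    dtilde = float(np.mean(dtil))
    r3 = (m + 1.0) / (k * (m - 1.0)) * (dbar - dtilde)
    r3 = max(r3, 0.0)
    stat = max(dtilde, 0.0) / (k * (1.0 + r3))
    df2 = _small_sample_df2(r3, k, m)
    return PooledTestResult(method="D3", p=_f_sf(stat, k, df2), statistic=stat,
                            df1=float(k), df2=df2)


def mpr_test(p_values: Sequence[float]) -> PooledTestResult:
    """Median-p-rule: the pooled p-value is the median of the m p-values.

    For even m this is the mean of the two middle order statistics.  The rule
    uses p-values only, so no statistic or degrees of freedom are reported.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("mpr_test needs at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return PooledTestResult(method="MPR", p=float(np.median(p)))
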