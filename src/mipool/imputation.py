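"""Chained-equations multiple imputation (MICE).

Each incomplete variable gets a conditional model on all other predictors
(dummy-coded categoricals) plus, by default, the outcome:

* continuous targets: Bayesian linear regression + predictive mean matching
  (k = 5 donors), so every imputed value equals some observed value;
* dichotomous targets: a Bayesian logistic draw (parameters drawn from the
  approximate posterior N(beta_hat, cov), then Bernoulli);
* four-level categorical targets: a multinomial-logit draw of the same form.

Missing cells are initialised by random draws from the observed values, the
variables are then visited cyclically for a fixed number of sweeps, and the
whole chain is repeated independently m times.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _glm
from .data_sim import MissingDataset, VariableSpec

__all__ = ["ImputedStack", "impute_mice"]


@dataclass
class ImputedStack:
    """The m completed copies of a MissingDataset."""

    datasets: list[pd.DataFrame]
    outcome: np.ndarray
    specs: list[VariableSpec]
    m: int
    iterations: int
    include_outcome: bool
    mask: pd.DataFrame | None = None

    def to_long_csv(self, path: str | Path, original: pd.DataFrame | None = None) -> None:
        """Long-format interchange CSV with an `.imp` column (0 = original
        with blanks, 1..m = completed copies)."""
        frames = []
        if original is not None:
            f = original.copy()
            f.insert(0, ".imp", 0)
            frames.append(f)
        for i, df in enumerate(self.datasets, start=1):
            f = df.copy()
            f.insert(0, ".imp", i)
            frames.append(f)
        long = pd.concat(frames, axis=0, ignore_index=True)
        long["outcome"] = np.tile(self.outcome, len(frames))
        long.to_csv(path, index=False)


def _design_for_target(
    cols: dict[str, np.ndarray],
    specs_by_name: dict[str, VariableSpec],
    target: str,
    outcome: np.ndarray | None,
) -> np.ndarray:
    """Intercept + every other predictor (categoricals as dummies) + outcome."""
    parts = [np.ones(len(next(iter(cols.values()))))]
    for name, x in cols.items():
        if name == target:
            continue
        s = specs_by_name.get(name)
        if s is not None and s.role == "categorical4":
            for level in (1, 2, 3):
                parts.append((x == level).astype(float))
        else:
            parts.append(x.astype(float))
    if outcome is not None:
        parts.append(outcome.astype(float))
    return np.column_stack(parts)


def _pmm_draw(X_obs, y_obs, X_mis, rng, k=5):
    """Bayesian linear regression + type-1 predictive mean matching."""
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs
    XtX_reg = XtX + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX_reg, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    cov_chol = np.linalg.cholesky(np.linalg.inv(XtX_reg) * sigma2)
    beta_star = beta_hat + cov_chol @ rng.standard_normal(p)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_star
    dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    kk = min(k, n)
    donors = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    pick = donors[np.arange(len(yhat_mis)), rng.integers(0, kk, size=len(yhat_mis))]
    return y_obs[pick]


def _logistic_draw(X_obs, y_obs, X_mis, rng):
    fit = _glm.fit_logit(X_obs, y_obs)
    chol = _chol_psd(fit.cov)
    beta_star = fit.beta + chol @ rng.standard_normal(len(fit.beta))
    from scipy.special import expit

    p = expit(X_mis @ beta_star)
    return (rng.uniform(size=len(p)) < p).astype(float)


def _multinomial_draw(X_obs, y_obs, X_mis, rng, n_classes=4):
    fit = _glm.fit_multinomial(X_obs, y_obs.astype(int), n_classes, ridge=1e-6)
    chol = _chol_psd(fit.cov)
    vec = fit.beta.ravel(order="F") + chol @ rng.standard_normal(fit.cov.shape[0])
    beta_star = vec.reshape(fit.beta.shape, order="F")
    P = _glm.multinomial_probs(X_mis, beta_star)
    u = rng.uniform(size=len(P))
    return (P.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(float)


def _chol_psd(A: np.ndarray) -> np.ndarray:
    A = (A + A.T) / 2.0
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(A)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def impute_mice(
    missing: MissingDataset,
    m: int = 5,
    iterations: int = 10,
    include_outcome: bool = True,
    rng: np.random.Generator | None = None,
    pmm_k: int = 5,
) -> ImputedStack:
    """Run chained-equations MI and return the m completed datasets.

    Fully observed targets are left untouched (a dataset with no missing
    cells yields m identical copies); a fully missing column is rejected.
    """
    rng = np.random.default_rng() if rng is None else rng
    preds = missing.predictors
    specs_by_name = {s.name: s for s in missing.specs}
    targets = [c for c in preds.columns if preds[c].isna().any()]
    for c in targets:
        if preds[c].isna().all():
            raise ValueError(f"column {c} is entirely missing")
    outcome = missing.outcome.astype(float) if include_outcome else None
    child_rngs = rng.spawn(m)

    datasets: list[pd.DataFrame] = []
    for chain in range(m):
        crng = child_rngs[chain]
        cols = {c: preds[c].to_numpy(dtype=float).copy() for c in preds.columns}
        miss_idx = {c: np.flatnonzero(preds[c].isna().to_numpy()) for c in targets}
        obs_idx = {c: np.flatnonzero(~preds[c].isna().to_numpy()) for c in targets}
        # initialise missing cells from the observed distribution
        for c in targets:
            obs_vals = cols[c][obs_idx[c]]
            cols[c][miss_idx[c]] = crng.choice(obs_vals, size=len(miss_idx[c]), replace=True)
        sweeps = iterations if targets else 0
        for _ in range(sweeps):
            for c in targets:
                X = _design_for_target(cols, specs_by_name, c, outcome)
                Xo, Xm = X[obs_idx[c]], X[miss_idx[c]]
                yo = cols[c][obs_idx[c]]
                role = specs_by_name[c].role if c in specs_by_name else "continuous"
                if role == "categorical4":
                    cols[c][miss_idx[c]] = _multinomial_draw(Xo, yo, Xm, crng)
                elif role == "dichotomous":
                    cols[c][miss_idx[c]] = _logistic_draw(Xo, yo, Xm, crng)
                else:
                    cols[c][miss_idx[c]] = _pmm_draw(Xo, yo, Xm, crng, k=pmm_k)
        df = pd.DataFrame(cols)
        for c in preds.columns:
            s = specs_by_name.get(c)
            if s is not None and s.role in ("categorical4", "dichotomous"):
                df[c] = df[c].astype(np.int64)
        datasets.append(df)
    return ImputedStack(
        datasets=datasets,
        outcome=missing.outcome,
        specs=missing.specs,
        m=m,
        iterations=iterations,
        include_outcome=include_outcome,
        mask=missing.mask,
    )
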