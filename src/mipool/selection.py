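"""Backward elimination from pooled logistic models.

A categorical predictor is always treated as one block: its dummy terms are
tested jointly (k = levels - 1) and enter or leave the model together.  At
each step the pooled p-value of every variable still in the model is
computed; if the largest exceeds the removal threshold ``p_out`` the
corresponding variable is dropped and the models are refitted, otherwise
selection stops.

Two pooling routes are supported per the study design:

* ``mode="mixed"`` -- Rubin's Rules for 1-df (continuous / dichotomous)
  variables and the chosen method (D1/D2/D3/MPR) for categorical blocks;
* ``mode="uniform"`` -- the chosen method for every variable (k = 1 blocks
  for 1-df variables).

The complete-data reference selection uses the single-dataset
likelihood-ratio test of dropping each block, refitted exactly at every
step.

Because the greedy removal path at a stricter threshold is a continuation
of the path at a looser one, a whole descending ``p_out`` grid is resolved
in a single elimination pass (:class:`SelectionEngine` snapshots the model
each time the running maximum p-value first falls below a grid value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .data_sim import CompleteDataset, VariableSpec
from .imputation import ImputedStack
from .pooled_inference import (
    RepeatedEstimates,
    d1_test,
    d2_test,
    d3_test,
    mpr_test,
    pool_rubin,
)

__all__ = [
    "ModelSpec",
    "SelectionResult",
    "SelectionEngine",
    "per_variable_pooled_p",
    "backward_select_pooled",
    "backward_select_path",
    "backward_select_complete",
    "backward_select_complete_path",
]

METHODS = ("D1", "D2", "D3", "MPR")


@dataclass(frozen=True)
class ModelSpec:
    """The full model: predictor order and categorical dummy groups."""

    variables: tuple[str, ...]
    groups: dict[str, tuple[str, ...]]
    outcome: str = "outcome"

    @classmethod
    def from_specs(cls, specs: Sequence[VariableSpec]) -> "ModelSpec":
        groups = {
            s.name: tuple(f"{s.name}_{lvl}" for lvl in (1, 2, 3))
            for s in specs
            if s.role == "categorical4"
        }
        return cls(variables=tuple(s.name for s in specs), groups=groups)


@dataclass
class SelectionResult:
    final_variables: tuple[str, ...]
    trace: list[tuple[str, float]]
    final_p: dict[str, float]
    method: str
    p_out: float
    mode: str


class SelectionEngine:
    """Caches per-imputation logistic fits over subsets of the predictors.

    Identical imputed datasets (e.g. a mask-all-false stack) are detected by
    content hash and share one cache slot, so degenerate stacks cost no more
    than a single dataset.
    """

    def __init__(
        self,
        datasets: Sequence[pd.DataFrame],
        outcome: np.ndarray,
        specs: Sequence[VariableSpec],
    ) -> None:
        self.specs = list(specs)
        self.variables: tuple[str, ...] = tuple(s.name for s in self.specs)
        self._k = {s.name: (3 if s.role == "categorical4" else 1) for s in self.specs}
        self.y = np.asarray(outcome, dtype=np.float64)
        self.n = len(self.y)
        # full design: intercept + per-variable term columns, fixed layout
        self._col_of: dict[str, np.ndarray] = {}
        designs = []
        for df in datasets:
            parts = [np.ones((len(df), 1))]
            pos = 1
            for s in self.specs:
                x = df[s.name].to_numpy(dtype=np.float64)
                if s.role == "categorical4":
                    cols = np.column_stack([(x == lvl).astype(float) for lvl in (1, 2, 3)])
                else:
                    cols = x[:, None]
                self._col_of[s.name] = np.arange(pos, pos + cols.shape[1])
                pos += cols.shape[1]
                parts.append(cols)
            designs.append(np.ascontiguousarray(np.concatenate(parts, axis=1)))
        self.m = len(designs)
        # dedupe identical imputations
        canon: dict[bytes, int] = {}
        self._imp_slot: list[int] = []
        self._X: list[np.ndarray] = []
        for X in designs:
            key = X.tobytes()
            if key not in canon:
                canon[key] = len(self._X)
                self._X.append(X)
            self._imp_slot.append(canon[key])
        self._cache: dict[tuple[int, tuple[str, ...]], _glm.LogitFit] = {}

    # -- low-level fit plumbing ------------------------------------------

    def k_of(self, variable: str) -> int:
        return self._k[variable]

    def _design_cols(self, state: tuple[str, ...]) -> np.ndarray:
        return np.concatenate([[0]] + [self._col_of[v] for v in state]).astype(np.intp)

    def param_index(self, state: tuple[str, ...], variable: str) -> np.ndarray:
        """Positions of ``variable``'s terms in the state's beta vector."""
        pos = 1
        for v in state:
            if v == variable:
                return np.arange(pos, pos + self._k[v])
            pos += self._k[v]
        raise KeyError(variable)

    def n_params(self, state: tuple[str, ...]) -> int:
        return 1 + sum(self._k[v] for v in state)

    def fit(self, imp: int, state: tuple[str, ...], beta0: np.ndarray | None = None) -> _glm.LogitFit:
        slot = self._imp_slot[imp]
        key = (slot, state)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        X = self._X[slot][:, self._design_cols(state)]
        fit = _glm.fit_logit(X, self.y, beta0=beta0)
        self._cache[key] = fit
        return fit

    def loglik_at(self, imp: int, state: tuple[str, ...], beta: np.ndarray) -> float:
        X = self._X[self._imp_slot[imp]][:, self._design_cols(state)]
        return _glm.logit_loglik(X, self.y, beta)

    # -- pooled per-variable tests ---------------------------------------

    def _reduced_state(self, state: tuple[str, ...], variable: str) -> tuple[str, ...]:
        return tuple(v for v in state if v != variable)

    def _reduced_beta0(self, fit: _glm.LogitFit, state: tuple[str, ...], variable: str) -> np.ndarray:
        keep = np.setdiff1d(np.arange(len(fit.beta)), self.param_index(state, variable))
        return fit.beta[keep]

    def pooled_p(self, state: tuple[str, ...], variable: str, method: str, mode: str) -> float:
        """Pooled p-value for dropping ``variable`` from the model ``state``."""
        if method == "complete":
            return self._complete_p(state, variable)
        k = self._k[variable]
        fits = [self.fit(i, state) for i in range(self.m)]
        idx = self.param_index(state, variable)
        if method == "RR" or (mode == "mixed" and k == 1):
            rep = RepeatedEstimates(
                theta=np.array([f.beta[idx] for f in fits]),
                U=np.array([f.cov[np.ix_(idx, idx)] for f in fits]),
                n_obs=self.n,
                p_model=self.n_params(state),
            )
            return pool_rubin(rep)[1].p
        if method == "D1":
            rep = RepeatedEstimates(
                theta=np.array([f.beta[idx] for f in fits]),
                U=np.array([f.cov[np.ix_(idx, idx)] for f in fits]),
                n_obs=self.n,
                p_model=self.n_params(state),
            )
            return d1_test(rep).p
        red = self._reduced_state(state, variable)
        if method == "D2":
            if k == 1:
                d = [float(f.beta[idx[0]] ** 2 / f.cov[idx[0], idx[0]]) for f in fits]
            else:
                d = [
                    2.0 * (f.loglik - self.fit(i, red, self._reduced_beta0(f, state, variable)).loglik)
                    for i, f in enumerate(fits)
                ]
                d = [max(v, 0.0) for v in d]
            return d2_test(d, k).p
        if method == "D3":
            return d3_test(
                list(range(self.m)),
                fit_full=lambda i: (fits[i].beta, fits[i].loglik),
                fit_reduced=lambda i: (
                    (rf := self.fit(i, red, self._reduced_beta0(fits[i], state, variable))).beta,
                    rf.loglik,
                ),
                loglik_full=lambda i, th: self.loglik_at(i, state, th),
                loglik_reduced=lambda i, th: self.loglik_at(i, red, th),
                k=k,
            ).p
        if method == "MPR":
            if k == 1:
                ps = [
                    float(stats.chi2.sf(f.beta[idx[0]] ** 2 / f.cov[idx[0], idx[0]], 1))
                    for f in fits
                ]
            else:
                ps = [
                    float(stats.chi2.sf(
                        max(2.0 * (f.loglik - self.fit(i, red, self._reduced_beta0(f, state, variable)).loglik), 0.0),
                        k,
                    ))
                    for i, f in enumerate(fits)
                ]
            return mpr_test(ps).p
        raise ValueError(f"unknown pooling method {method!r}")

    def _complete_p(self, state: tuple[str, ...], variable: str) -> float:
        """Single-dataset likelihood-ratio p for dropping the block."""
        k = self._k[variable]
        full = self.fit(0, state)
        red = self.fit(0, self._reduced_state(state, variable),
                       self._reduced_beta0(full, state, variable))
        lr = max(2.0 * (full.loglik - red.loglik), 0.0)
        return float(stats.chi2.sf(lr, k))

    # -- backward elimination --------------------------------------------

    def backward_path(
        self, method: str, p_out_grid: Sequence[float], mode: str = "mixed"
    ) -> dict[float, SelectionResult]:
        """One greedy elimination pass resolving every threshold in the grid.

        Removal rule: drop the variable with the largest pooled p while that
        maximum strictly exceeds the threshold (ties broken toward the
        variable later in the canonical order).  The model is snapshotted
        for each grid value the first time the maximum falls to or below it.
        """
        grid = sorted(set(p_out_grid), reverse=True)
        if any(not 0.0 < t <= 1.0 for t in grid):
            raise ValueError("p_out values must lie in (0, 1]")
        current = list(self.variables)
        trace: list[tuple[str, float]] = []
        results: dict[float, SelectionResult] = {}
        pending = list(grid)
        while True:
            state = tuple(current)
            pvals = {v: self.pooled_p(state, v, method, mode) for v in current}
            if current:
                maxp = max(pvals.values())
                victim = [v for v in current if pvals[v] == maxp][-1]
            else:
                maxp = -np.inf
                victim = None
            while pending and maxp <= pending[0]:
                threshold = pending.pop(0)
                results[threshold] = SelectionResult(
                    final_variables=state,
                    trace=list(trace),
                    final_p=dict(pvals),
                    method=method,
                    p_out=threshold,
                    mode=mode,
                )
            if not pending:
                return results
            trace.append((victim, maxp))
            current.remove(victim)


def _engine_from_stack(stack: ImputedStack) -> SelectionEngine:
    return SelectionEngine(stack.datasets, stack.outcome, stack.specs)


def _engine_from_complete(ds: CompleteDataset) -> SelectionEngine:
    return SelectionEngine([ds.predictors], ds.outcome, ds.specs)


def per_variable_pooled_p(
    stack: ImputedStack,
    model: ModelSpec | Sequence[str],
    variable: str,
    method: str,
    mode: str = "mixed",
) -> float:
    """Pooled p-value of ``variable`` in the model given by ``model``."""
    engine = _engine_from_stack(stack)
    state = tuple(model.variables) if isinstance(model, ModelSpec) else tuple(model)
    if variable not in state:
        raise ValueError(f"{variable} is not in the model")
    return engine.pooled_p(state, variable, method, mode)


def backward_select_pooled(
    stack: ImputedStack, method: str, p_out: float, mode: str = "mixed"
) -> SelectionResult:
    return _engine_from_stack(stack).backward_path(method, [p_out], mode)[p_out]


def backward_select_path(
    stack: ImputedStack, method: str, p_out_grid: Sequence[float], mode: str = "mixed"
) -> dict[float, SelectionResult]:
    return _engine_from_stack(stack).backward_path(method, p_out_grid, mode)


def backward_select_complete(complete: CompleteDataset, p_out: float) -> SelectionResult:
    """Reference selection on the pre-amputation data (exact stepwise LRT)."""
    return _engine_from_complete(complete).backward_path("complete", [p_out], "complete")[p_out]


def backward_select_complete_path(
    complete: CompleteDataset, p_out_grid: Sequence[float]
) -> dict[float, SelectionResult]:
    return _engine_from_complete(complete).backward_path("complete", p_out_grid, "complete")
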