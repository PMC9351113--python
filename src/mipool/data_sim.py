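"""Simulated prognostic datasets with MAR missingness.

The generator emulates a low-back-pain style prognostic dataset: nine
predictors drawn from a multivariate normal with an exchangeable latent
correlation, of which two are categorised to four levels at fixed population
quantiles, two are dichotomised at the median, and five stay continuous
(one, "Noise", carries a zero coefficient).  A binary outcome follows a
logistic model whose intercept is calibrated numerically to a target
prevalence.  Missingness is then imposed missing-at-random: for each
incomplete variable the per-row missingness probability is a logistic
function of a fully observed driver variable, with the intercept solved so
the marginal missing rate hits the requested value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "VariableSpec",
    "SimCondition",
    "CompleteDataset",
    "MissingDataset",
    "build_default_specs",
    "generate_latent",
    "discretize",
    "simulate_outcome",
    "simulate_complete",
    "ampute_mar",
    "DEFAULT_DRIVER_MAP",
    "write_dataset",
    "read_dataset",
]

ROLES = ("categorical4", "dichotomous", "continuous", "noise")


@dataclass(frozen=True)
class VariableSpec:
    """Declarative description of one simulated predictor."""

    name: str
    role: str
    latent_mean: float
    latent_sd: float
    coefficients: tuple[float, ...]
    cut_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        if self.role == "categorical4":
            if len(self.coefficients) != 3:
                raise ValueError("categorical4 needs 3 dummy coefficients")
            cp = self.cut_probs
            if cp is None or len(cp) != 5 or cp[0] != 0.0 or cp[-1] != 1.0:
                raise ValueError("categorical4 needs 5 cumulative cut_probs from 0 to 1")
            if np.any(np.diff(cp) <= 0):
                raise ValueError("cut_probs must be strictly increasing")
        else:
            if len(self.coefficients) != 1:
                raise ValueError(f"{self.role} takes exactly one coefficient")
        if self.role == "noise" and any(c != 0.0 for c in self.coefficients):
            raise ValueError("noise variables must have zero coefficients")

    @property
    def n_levels(self) -> int:
        return 4 if self.role == "categorical4" else 2 if self.role == "dichotomous" else 0


@dataclass
class SimCondition:
    """One experimental condition of the simulation study."""

    n: int = 500
    rho: float = 0.2
    m: int = 5
    p_out_grid: tuple[float, ...] = (1.0, 0.5, 0.3, 0.1, 0.05)
    n_reps: int = 500
    seed: int = 0
    target_prevalence: float = 0.5
    include_outcome_in_imputation: bool = True

    def __post_init__(self) -> None:
        if self.n < 50:
            raise ValueError("n must be >= 50")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if any(not 0.0 < p <= 1.0 for p in self.p_out_grid):
            raise ValueError("every p_out must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def label(self) -> str:
        return f"n{self.n}_rho{self.rho:g}"


@dataclass
class CompleteDataset:
    predictors: pd.DataFrame
    outcome: np.ndarray
    specs: list[VariableSpec]
    intercept: float


@dataclass
class MissingDataset:
    """A complete dataset with MAR missingness imposed on some predictors.

    ``predictors`` holds NaN at masked cells; ``mask`` is True where missing.
    """

    predictors: pd.DataFrame
    outcome: np.ndarray
    specs: list[VariableSpec]
    intercept: float
    mask: pd.DataFrame
    incomplete_vars: list[str] = field(default_factory=list)


# --- Variable definitions: low-back-pain style means/SDs and coefficients ---

_DEFAULT_TABLE = [
    # name, role, mean, sd, coefficients, cut_probs
    ("Cat1", "categorical4", 2.0, 0.95, (0.5, 1.5, 1.5), (0.0, 0.6, 0.8, 0.9, 1.0)),
    ("Cat2", "categorical4", 3.0, 1.0, (1.5, 1.5, 1.5), (0.0, 0.3, 0.6, 0.8, 1.0)),
    ("Dich1", "dichotomous", 0.8, 0.45, (-0.5,), None),
    ("Dich2", "dichotomous", 0.7, 0.55, (-1.0,), None),
    ("Cont1", "continuous", 7.0, 1.41, (0.5,), None),
    ("Noise", "noise", 7.0, 1.41, (0.0,), None),
    ("Cont2", "continuous", 140.0, 9.5, (-0.1,), None),
    ("Cont3", "continuous", 26.0, 3.9, (-0.1,), None),
    ("Cont4", "continuous", 34.0, 4.8, (-0.1,), None),
]


def build_default_specs() -> list[VariableSpec]:
    """The nine default predictors (means, SDs, coefficients, cut points)."""
    return [
        VariableSpec(name=n, role=r, latent_mean=mu, latent_sd=sd,
                     coefficients=co, cut_probs=cp)
        for n, r, mu, sd, co, cp in _DEFAULT_TABLE
    ]


def generate_latent(
    specs: Sequence[VariableSpec], n: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n rows from the latent multivariate normal.

    Covariance is D R D with D = diag(latent SDs) and R exchangeable with
    off-diagonal ``rho``; R must be positive definite (rho > -1/(k-1)).
    """
    k = len(specs)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (-1.0 / (k - 1) < rho < 1.0):
        raise ValueError(f"exchangeable correlation must lie in (-1/{k-1}, 1)")
    means = np.array([s.latent_mean for s in specs])
    sds = np.array([s.latent_sd for s in specs])
    R = np.full((k, k), rho)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, k))
    return means + (z @ L.T) * sds


def discretize(latent: np.ndarray, specs: Sequence[VariableSpec]) -> pd.DataFrame:
    """Map latent columns to their observed form.

    Categorical columns are cut at the latent normal's quantiles of the
    cumulative ``cut_probs`` (theoretical, not sample, quantiles, so the cut
    points are identical across replications); dichotomous columns are split
    at the theoretical median (= latent mean); continuous columns pass
    through unchanged.
    """
    if latent.shape[1] != len(specs):
        raise ValueError("latent matrix width does not match specs")
    cols: dict[str, np.ndarray] = {}
    for j, s in enumerate(specs):
        x = latent[:, j]
        if s.role == "categorical4":
            cuts = norm.ppf(np.asarray(s.cut_probs[1:-1]), loc=s.latent_mean, scale=s.latent_sd)
            cols[s.name] = np.searchsorted(cuts, x, side="right").astype(np.int64)
        elif s.role == "dichotomous":
            cols[s.name] = (x > s.latent_mean).astype(np.int64)
        else:
            cols[s.name] = x
    return pd.DataFrame(cols)


def linear_predictor(
    predictors: pd.DataFrame, specs: Sequence[VariableSpec], intercept: float = 0.0
) -> np.ndarray:
    """alpha + sum of coefficient * predictor terms, dummy-coding categoricals."""
    lp = np.full(len(predictors), float(intercept))
    for s in specs:
        x = predictors[s.name].to_numpy()
        if s.role == "categorical4":
            for level, beta in zip((1, 2, 3), s.coefficients):
                lp += beta * (x == level)
        else:
            lp += s.coefficients[0] * x
    return lp


def simulate_outcome(
    predictors: pd.DataFrame,
    specs: Sequence[VariableSpec],
    target_prevalence: float = 0.5,
    rng: np.random.Generator | None = None,
    paper_literal_outcome: bool = False,
) -> tuple[np.ndarray, float]:
    """Draw the binary outcome from the logistic model, calibrating the intercept.

    The intercept alpha is solved by monotone root finding so that the mean of
    the event probabilities equals ``target_prevalence`` (to 1e-6).  By
    default y = 1{u <= p} with u ~ Uniform(0,1); ``paper_literal_outcome``
    flips the comparison (y = 1 when p < u), which inverts every effect sign
    and is provided for auditing only.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    lp0 = linear_predictor(predictors, specs, 0.0)

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + lp0)) - target_prevalence)

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("target prevalence unattainable for these predictors")
    alpha = brentq(gap, lo, hi, xtol=1e-10)
    p = expit(alpha + lp0)
    u = rng.uniform(size=len(p))
    y = (p < u) if paper_literal_outcome else (u <= p)
    return y.astype(np.int64), float(alpha)


def simulate_complete(
    condition: SimCondition,
    rng: np.random.Generator,
    specs: Sequence[VariableSpec] | None = None,
    paper_literal_outcome: bool = False,
) -> CompleteDataset:
    """Generate one complete dataset under a condition (latent draw ->
    discretisation -> calibrated logistic outcome)."""
    specs = build_default_specs() if specs is None else list(specs)
    latent = generate_latent(specs, condition.n, condition.rho, rng)
    predictors = discretize(latent, specs)
    y, alpha = simulate_outcome(
        predictors, specs, condition.target_prevalence, rng,
        paper_literal_outcome=paper_literal_outcome,
    )
    return CompleteDataset(predictors=predictors, outcome=y, specs=list(specs), intercept=alpha)


# --- MAR amputation ---------------------------------------------------------

# Each incomplete variable's missingness depends on a distinct, always
# observed driver.
DEFAULT_DRIVER_MAP: dict[str, str] = {
    "Cat1": "Cont1",
    "Cat2": "Cont2",
    "Noise": "Cont3",
    "Cont4": "Dich2",
}


def ampute_mar(
    complete: CompleteDataset,
    driver_map: Mapping[str, str] | None = None,
    rate: float = 0.2,
    gamma1: float = 0.4,
    rng: np.random.Generator | None = None,
) -> MissingDataset:
    """Impose MAR missingness on the target variables.

    For target j with driver d, rows are masked independently with
    probability expit(gamma0_j + gamma1 * z(d_i)) where z is the
    standardised driver; gamma0_j is solved so the expected marginal missing
    rate equals ``rate``.  Drivers and the outcome are never masked.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    driver_map = dict(DEFAULT_DRIVER_MAP) if driver_map is None else dict(driver_map)
    preds = complete.predictors
    for target, driver in driver_map.items():
        if target not in preds.columns or driver not in preds.columns:
            raise ValueError(f"unknown target/driver pair {target}->{driver}")
        if driver in driver_map:
            raise ValueError(f"driver {driver} is itself a missingness target")
        if preds[driver].isna().any():
            raise ValueError(f"driver {driver} has missing values")

    mask = pd.DataFrame(False, index=preds.index, columns=preds.columns)
    amputed = preds.copy().astype(float)
    for target, driver in driver_map.items():
        d = preds[driver].to_numpy(dtype=float)
        sd = d.std()
        z = (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)

        def gap(g0: float) -> float:
            return float(np.mean(expit(g0 + gamma1 * z)) - rate)

        g0 = brentq(gap, -40.0, 40.0, xtol=1e-10)
        pi = expit(g0 + gamma1 * z)
        miss = rng.uniform(size=len(pi)) < pi
        mask[target] = miss
        amputed.loc[miss, target] = np.nan
    return MissingDataset(
        predictors=amputed,
        outcome=complete.outcome,
        specs=complete.specs,
        intercept=complete.intercept,
        mask=mask,
        incomplete_vars=list(driver_map),
    )


# --- CSV round trip ---------------------------------------------------------

def write_dataset(ds: CompleteDataset | MissingDataset, path: str | Path) -> None:
    """Write predictors + outcome as CSV (missing cells empty) with a JSON
    sidecar recording the specs, intercept and mask provenance."""
    path = Path(path)
    out = ds.predictors.copy()
    out["outcome"] = ds.outcome
    out.to_csv(path, index=False)
    meta = {
        "intercept": ds.intercept,
        "specs": [asdict(s) for s in ds.specs],
        "incomplete_vars": getattr(ds, "incomplete_vars", []),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_dataset(path: str | Path) -> CompleteDataset | MissingDataset:
    path = Path(path)
    df = pd.read_csv(path)
    y = df.pop("outcome").to_numpy(dtype=np.int64)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    specs: list[VariableSpec] = []
    intercept = 0.0
    incomplete: list[str] = []
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        intercept = meta.get("intercept", 0.0)
        incomplete = meta.get("incomplete_vars", [])
        for s in meta.get("specs", []):
            cp = s.get("cut_probs")
            specs.append(VariableSpec(
                name=s["name"], role=s["role"], latent_mean=s["latent_mean"],
                latent_sd=s["latent_sd"], coefficients=tuple(s["coefficients"]),
                cut_probs=tuple(cp) if cp else None,
            ))
    if df.isna().any().any() or incomplete:
        mask = df.isna()
        return MissingDataset(predictors=df, outcome=y, specs=specs, intercept=intercept,
                              mask=mask, incomplete_vars=incomplete or
                              [c for c in df.columns if mask[c].any()])
    return CompleteDataset(predictors=df, outcome=y, specs=specs, intercept=intercept)
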