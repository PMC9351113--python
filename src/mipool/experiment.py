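"""Study orchestration: condition grid, replication loop, output tables.

One replication of a condition:

1. simulate a complete dataset (seed = condition seed + replication index);
2. run the complete-data reference selection over the p_out grid;
3. ampute (MAR) and impute (MICE, m copies);
4. run pooled backward selection for every method x mode over the grid.

A replication whose model fits fail beyond the ridge fallback is re-drawn
with a fresh derived seed (counts are reported in the manifest).  Results
are deterministic given the condition seed and independent of the worker
count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import evaluation
from ._glm import FitError
from .data_sim import (
    DEFAULT_DRIVER_MAP,
    SimCondition,
    ampute_mar,
    build_default_specs,
    simulate_complete,
)
from .imputation import impute_mice
from .selection import METHODS, SelectionEngine, SelectionResult

logger = logging.getLogger("mipool")

__all__ = [
    "StudyConfig",
    "paper_conditions",
    "run_replication",
    "run_study",
    "records_to_frame",
]

REPORT_VARIABLES = ("Noise", "Cont4", "Cat1", "Cat2", "Dich1")
_RESEED_STRIDE = 100_003  # offset between redraw attempts of one replication


def paper_conditions(
    seed: int = 2022,
    n_reps: int = 500,
    p_out_grid: tuple[float, ...] = (1.0, 0.5, 0.3, 0.1, 0.05),
    m: int = 5,
) -> list[SimCondition]:
    """The four study conditions: n in {200, 500} crossed with rho in {0.2, 0.6}."""
    grid = [(200, 0.2), (200, 0.6), (500, 0.2), (500, 0.6)]
    return [
        SimCondition(n=n, rho=rho, m=m, n_reps=n_reps, p_out_grid=p_out_grid,
                     seed=seed + 250_000 * i)
        for i, (n, rho) in enumerate(grid)
    ]


@dataclass
class StudyConfig:
    """The full study: conditions, pooling methods, modes, output location."""

    conditions: list[SimCondition] = field(default_factory=lambda: [
        SimCondition(n=200, rho=0.2, seed=101),
        SimCondition(n=200, rho=0.6, seed=202),
        SimCondition(n=500, rho=0.2, seed=303),
        SimCondition(n=500, rho=0.6, seed=404),
    ])
    methods: tuple[str, ...] = METHODS
    modes: tuple[str, ...] = ("mixed",)
    output_dir: str | Path = "study_output"
    n_workers: int = 1
    missing_rate: float = 0.2
    mice_iterations: int = 10
    max_redraws: int = 5

    def __post_init__(self) -> None:
        if not self.conditions or not self.methods:
            raise ValueError("need at least one condition and one method")


def _record(condition: SimCondition, rep: int, mode: str, res: SelectionResult) -> dict:
    return {
        "condition": condition.label,
        "rep": rep,
        "method": res.method,
        "mode": mode,
        "p_out": res.p_out,
        "selected": ";".join(res.final_variables),
        "final_p": {k: float(v) for k, v in res.final_p.items()},
    }


def run_replication(
    condition: SimCondition,
    rep_index: int,
    methods: Sequence[str] = METHODS,
    modes: Sequence[str] = ("mixed",),
    missing_rate: float = 0.2,
    mice_iterations: int = 10,
    max_redraws: int = 5,
) -> tuple[list[dict], int]:
    """Run one replication; returns (records, redraw count).

    The derived seed is ``condition.seed + rep_index``; an unrecoverable fit
    failure re-draws the replication with a fresh offset seed.
    """
    grid = tuple(condition.p_out_grid)
    redraws = 0
    while True:
        seed = condition.seed + rep_index + redraws * _RESEED_STRIDE
        rng = np.random.default_rng(seed)
        try:
            complete = simulate_complete(condition, rng)
            records: list[dict] = []
            comp_engine = SelectionEngine([complete.predictors], complete.outcome, complete.specs)
            for res in comp_engine.backward_path("complete", grid, "complete").values():
                records.append(_record(condition, rep_index, "complete", res))
            missing = ampute_mar(complete, DEFAULT_DRIVER_MAP, rate=missing_rate, rng=rng)
            stack = impute_mice(
                missing,
                m=condition.m,
                iterations=mice_iterations,
                include_outcome=condition.include_outcome_in_imputation,
                rng=rng,
            )
            engine = SelectionEngine(stack.datasets, stack.outcome, stack.specs)
            for mode in modes:
                for method in methods:
                    for res in engine.backward_path(method, grid, mode).values():
                        records.append(_record(condition, rep_index, mode, res))
            for r in records:
                r["seed"] = seed
            return records, redraws
        except FitError:
            redraws += 1
            if redraws > max_redraws:
                raise
            logger.warning(
                "replication %s/%d re-drawn (attempt %d) after fit failure",
                condition.label, rep_index, redraws,
            )


def records_to_frame(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records)


def _run_condition(config: StudyConfig, condition: SimCondition) -> tuple[list[dict], int]:
    runner = Parallel(n_jobs=config.n_workers, prefer="processes") if config.n_workers > 1 else None
    args = dict(
        methods=config.methods,
        modes=config.modes,
        missing_rate=config.missing_rate,
        mice_iterations=config.mice_iterations,
        max_redraws=config.max_redraws,
    )
    if runner is None:
        out = [run_replication(condition, i, **args) for i in range(condition.n_reps)]
    else:
        out = runner(delayed(run_replication)(condition, i, **args) for i in range(condition.n_reps))
    records = [r for recs, _ in out for r in recs]
    redraws = sum(rd for _, rd in out)
    return records, redraws


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Execute every condition and write the evaluation CSVs + manifest.

    Outputs under ``config.output_dir``:

    * ``records.csv`` -- one row per condition x rep x method x p_out;
    * ``selection_frequency.csv`` -- per-variable selection percentages;
    * ``median_log_p.csv`` -- median log10 final p of selected variables;
    * ``agreement.csv`` -- exact-set agreement with the complete reference;
    * ``stability.csv`` -- top-10 unique-model stability, both conventions;
    * ``manifest.yaml`` -- config echo, seeds and redraw counts.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_records: list[dict] = []
    redraw_log: dict[str, int] = {}
    for condition in config.conditions:
        logger.info("running condition %s (%d reps)", condition.label, condition.n_reps)
        recs, redraws = _run_condition(config, condition)
        all_records.extend(recs)
        redraw_log[condition.label] = redraws
    records = records_to_frame(all_records)

    disk = records.copy()
    disk["final_p"] = disk["final_p"].map(json.dumps)
    disk.to_csv(outdir / "records.csv", index=False)

    methods = list(config.methods)
    freq = evaluation.frequency_table(records, methods, REPORT_VARIABLES)
    freq.to_csv(outdir / "selection_frequency.csv", index=False)
    logp = evaluation.median_log_p_table(records, methods, REPORT_VARIABLES)
    logp.to_csv(outdir / "median_log_p.csv", index=False)
    agree = evaluation.agreement_table(records, methods)
    agree.to_csv(outdir / "agreement.csv", index=False)

    stab_rows = []
    for cond in sorted(records["condition"].unique()):
        for p_out in sorted(records["p_out"].unique()):
            for method in methods:
                tab = evaluation.stability_table(records, cond, p_out, method)
                stab_rows.append({
                    "condition": cond,
                    "p_out": p_out,
                    "method": method,
                    "match_count": tab.attrs["match_total"],
                    "n_reps": tab.attrs["n_reps"],
                    "comp_top_total": tab.attrs["comp_top_total"],
                    "pct_of_reps": tab.attrs["pct_of_reps"],
                    "pct_of_comp_top": tab.attrs["pct_of_comp_top"],
                })
    pd.DataFrame(stab_rows).to_csv(outdir / "stability.csv", index=False)

    manifest = {
        "config": {
            "conditions": [asdict(c) for c in config.conditions],
            "methods": list(config.methods),
            "modes": list(config.modes),
            "missing_rate": config.missing_rate,
            "mice_iterations": config.mice_iterations,
            "n_workers": config.n_workers,
        },
        "redraws": redraw_log,
        "specs": [asdict(s) for s in build_default_specs()],
    }
    manifest = json.loads(json.dumps(manifest))  # tuples -> lists for YAML
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return records
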