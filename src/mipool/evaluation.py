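"""Comparison metrics over replication records.

The study driver produces one record per (condition, replication, method,
p_out) holding the final selected variable set and the final pooled
p-values.  This module turns those records into the three comparison
metrics: per-variable selection frequency, the median log-transformed final
p-value of the selected variables, the exact-set agreement with the
complete-data reference, and the model-stability table against the top
unique complete-data models.

Records are plain pandas DataFrames with columns::

    condition, rep, method, mode, p_out, selected, final_p

``selected`` is the semicolon-joined final variable set in canonical order;
``final_p`` maps variable -> pooled p (dict in memory, JSON text on disk).
The complete-data reference rows carry ``method == "complete"``.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "selection_frequency",
    "median_log_p",
    "agreement_rate",
    "stability_table",
    "frequency_table",
    "median_log_p_table",
    "agreement_table",
]

RECORD_COLUMNS = ["condition", "rep", "method", "mode", "p_out", "selected", "final_p"]


def _subset(records: pd.DataFrame, condition, p_out, method) -> pd.DataFrame:
    sub = records[
        (records["p_out"] == p_out)
        & (records["method"] == method)
    ]
    if condition is not None:
        conds = [condition] if isinstance(condition, str) else list(condition)
        sub = sub[sub["condition"].isin(conds)]
    return sub


def _selected_set(cell: str) -> frozenset:
    return frozenset(cell.split(";")) if cell else frozenset()


def selection_frequency(
    records: pd.DataFrame, condition, p_out: float, method: str, variable: str
) -> float:
    """Percentage of replications whose final model contains ``variable``."""
    sub = _subset(records, condition, p_out, method)
    if len(sub) == 0:
        raise ValueError("no replication records for the requested cell")
    hits = sub["selected"].map(lambda s: variable in _selected_set(s)).sum()
    return 100.0 * hits / len(sub)


def median_log_p(
    records: pd.DataFrame,
    condition,
    p_out: float,
    method: str,
    variable: str,
    base: float = 10.0,
) -> float:
    """Median log p-value of ``variable`` over the replications that kept it.

    Defaults to base-10 logs; pass ``base=np.e`` for natural logs.  Returns
    NaN if the variable was never selected.
    """
    sub = _subset(records, condition, p_out, method)
    vals = []
    for _, row in sub.iterrows():
        fp = row["final_p"]
        if isinstance(fp, str):
            fp = json.loads(fp)
        if variable in fp:
            vals.append(np.log(max(fp[variable], 1e-300)) / np.log(base))
    if not vals:
        return float("nan")
    return float(np.median(vals))


def agreement_rate(
    records: pd.DataFrame, condition, p_out: float, method: str
) -> float:
    """Percentage of replications where the method's final set exactly equals
    the complete-data final set (paired within replication)."""
    sub = _subset(records, condition, p_out, method)
    comp = _subset(records, condition, p_out, "complete")
    merged = sub.merge(
        comp[["condition", "rep", "selected"]],
        on=["condition", "rep"],
        suffixes=("", "_comp"),
        validate="one_to_one",
    )
    if len(merged) == 0:
        raise ValueError("no paired method/complete records")
    if len(merged) != len(sub):
        raise ValueError("unpaired replications between method and complete records")
    same = (merged["selected"] == merged["selected_comp"]).sum()
    return 100.0 * same / len(merged)


def stability_table(
    records: pd.DataFrame, condition, p_out: float, method: str, top_u: int = 10
) -> pd.DataFrame:
    """Model-stability summary against the top unique complete-data models.

    Identifies the ``top_u`` most frequent unique final variable sets among
    the complete-data replications, then counts the method replications
    whose final set equals any of them.  Two percentage conventions are
    reported (they use different denominators):

    * ``pct_of_reps``  -- matches / total replications;
    * ``pct_of_comp_top`` -- matches / complete-data replications that fall
      in the top ``top_u`` models.

    Returns a one-row-per-model DataFrame plus aggregate columns.
    """
    comp = _subset(records, condition, p_out, "complete")
    if len(comp) == 0:
        raise ValueError("complete-data records unavailable")
    counts = comp["selected"].value_counts()
    top = counts.iloc[:top_u]
    top_models = list(top.index)
    sub = _subset(records, condition, p_out, method)
    n_reps = len(sub)
    comp_top_total = int(top.sum())
    rows = []
    match_total = 0
    for model_str in top_models:
        n_match = int((sub["selected"] == model_str).sum())
        match_total += n_match
        rows.append({
            "model": model_str,
            "comp_count": int(counts[model_str]),
            "match_count": n_match,
        })
    out = pd.DataFrame(rows)
    out.attrs["match_total"] = match_total
    out.attrs["n_reps"] = n_reps
    out.attrs["comp_top_total"] = comp_top_total
    out.attrs["pct_of_reps"] = 100.0 * match_total / n_reps if n_reps else float("nan")
    out.attrs["pct_of_comp_top"] = (
        100.0 * match_total / comp_top_total if comp_top_total else float("nan")
    )
    out.attrs["n_unique_available"] = int(len(counts))
    return out


# --- wide summary tables (CSV analogues of the study's output tables) ------

def frequency_table(
    records: pd.DataFrame,
    methods: Sequence[str],
    variables: Sequence[str],
) -> pd.DataFrame:
    """Selection-frequency table: one row per condition x p_out x variable."""
    rows = []
    for (cond, p_out), _ in records.groupby(["condition", "p_out"], sort=True):
        for var in variables:
            row = {"condition": cond, "p_out": p_out, "variable": var}
            for meth in list(methods) + ["complete"]:
                row[meth] = selection_frequency(records, cond, p_out, meth, var)
            rows.append(row)
    return pd.DataFrame(rows)


def median_log_p_table(
    records: pd.DataFrame,
    methods: Sequence[str],
    variables: Sequence[str],
    base: float = 10.0,
) -> pd.DataFrame:
    rows = []
    for (cond, p_out), _ in records.groupby(["condition", "p_out"], sort=True):
        for var in variables:
            row = {"condition": cond, "p_out": p_out, "variable": var}
            for meth in list(methods) + ["complete"]:
                row[meth] = median_log_p(records, cond, p_out, meth, var, base=base)
            rows.append(row)
    return pd.DataFrame(rows)


def agreement_table(records: pd.DataFrame, methods: Sequence[str]) -> pd.DataFrame:
    """Exact-set agreement with the complete-data reference, per condition
    and aggregated over all conditions (condition = "all")."""
    conds = sorted(records["condition"].unique())
    rows = []
    for p_out in sorted(records["p_out"].unique()):
        for cond in conds + [None]:
            row = {"condition": cond if cond is not None else "all", "p_out": p_out}
            for meth in methods:
                row[meth] = agreement_rate(
                    records, cond if cond is not None else conds, p_out, meth
                )
            rows.append(row)
    return pd.DataFrame(rows)
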