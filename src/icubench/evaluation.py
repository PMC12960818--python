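"""Scoring of reconstructions on masked entries, seed aggregation and
clinical-agreement analyses.

Errors are computed only on artificially hidden cells with known ground
truth:

    MAE  = (1/n) * sum_i |x_i - y_i|
    RMSE = sqrt((1/n) * sum_i (x_i - y_i)^2)

with x_i the held-out true value and y_i the imputed one.  Standardized
errors back-transform to physical units by a pure scale factor (the
variable's training SD), so RMSE_physical = SD * RMSE_standardized exactly.

Clinical relevance for mean blood pressure is assessed with Bland-Altman
agreement (bias and 95% limits of agreement, bias +/- 1.96 * SD of the
differences, differences oriented imputed - true) and with error strata at
the clinically critical thresholds <65 mmHg (hypotension) and >100 mmHg.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import VAR_INDEX, VARIABLES, Cohort

__all__ = [
    "masked_error",
    "collect_pairs",
    "per_variable_errors",
    "aggregate_seeds",
    "BlandAltmanStats",
    "bland_altman",
    "stratify_errors",
    "render_report",
]


def masked_error(true: np.ndarray, imputed: np.ndarray) -> tuple[float, float]:
    """(MAE, RMSE) over a pair set of held-out truths and reconstructions."""
    true = np.asarray(true, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    if true.shape != imputed.shape:
        raise ValueError("true and imputed must have the same shape")
    if true.size == 0:
        raise ValueError("cannot score an empty pair set")
    diff = imputed - true
    return float(np.mean(np.abs(diff))), float(np.sqrt(np.mean(diff**2)))


def collect_pairs(truth_store: pd.DataFrame, imputed: Cohort) -> pd.DataFrame:
    """Join a mask's ground-truth store with the imputed cohort.

    Returns one row per masked cell: (stay_id, variable, hour, true,
    imputed).  The pair set is keyed by the mask, so unmasked cells cannot
    enter the scoring set.
    """
    srow = {s: i for i, s in enumerate(imputed.stay_ids)}
    si = truth_store["stay_id"].map(srow).to_numpy(dtype=int)
    hi = truth_store["hour"].to_numpy(dtype=int)
    vi = truth_store["variable"].map(VAR_INDEX).to_numpy(dtype=int)
    out = truth_store.rename(columns={"value": "true"}).copy()
    out["imputed"] = imputed.values[si, hi, vi]
    if out["imputed"].isna().any():
        raise ValueError("imputed cohort is missing values at masked cells")
    return out


def per_variable_errors(pairs: pd.DataFrame) -> pd.DataFrame:
    """MAE/RMSE per variable plus an 'all' row, tidy."""
    rows = []
    for v in VARIABLES:
        sub = pairs[pairs["variable"] == v]
        if len(sub) == 0:
            continue
        mae, rmse = masked_error(sub["true"].to_numpy(), sub["imputed"].to_numpy())
        rows.append({"variable": v, "MAE": mae, "RMSE": rmse, "n": len(sub)})
    mae, rmse = masked_error(pairs["true"].to_numpy(), pairs["imputed"].to_numpy())
    rows.append({"variable": "all", "MAE": mae, "RMSE": rmse, "n": len(pairs)})
    return pd.DataFrame(rows)


def aggregate_seeds(per_seed: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-seed error tables into mean +/- SD.

    Each input table must share the same key columns (every column except
    ``value``) and differ only in its ``value`` entries.  SD uses the
    sample (n-1) convention; a single seed reports SD = 0.
    """
    if not per_seed:
        raise ValueError("need at least one seed table")
    keys = [c for c in per_seed[0].columns if c not in ("value", "seed")]
    for df in per_seed[1:]:
        if [c for c in df.columns if c not in ("value", "seed")] != keys:
            raise ValueError("seed tables have mismatched shapes")
    stacked = pd.concat(per_seed, ignore_index=True)
    grouped = stacked.groupby(keys, sort=True)["value"]
    counts = grouped.size()
    if counts.nunique() != 1 or counts.iloc[0] != len(per_seed):
        raise ValueError("seed tables have mismatched shapes")
    agg = grouped.agg(["mean", "std", "size"]).reset_index()
    agg = agg.rename(columns={"std": "sd", "size": "n_seeds"})
    agg.loc[agg["n_seeds"] == 1, "sd"] = 0.0
    return agg


@dataclasses.dataclass(frozen=True)
class BlandAltmanStats:
    """Agreement statistics for imputed-vs-true pairs.

    Differences are oriented imputed - true; limits of agreement are
    bias +/- 1.96 * SD of the differences.
    """

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman(
    true: np.ndarray, imputed: np.ndarray
) -> tuple[BlandAltmanStats, pd.DataFrame]:
    """Bland-Altman agreement between imputed and true values.

    Returns the summary statistics and the per-pair plotting coordinates
    (mean of the two values on x, their difference on y).
    """
    true = np.asarray(true, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    if true.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    diff = imputed - true
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    stats = BlandAltmanStats(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=true.size
    )
    coords = pd.DataFrame({"mean": (true + imputed) / 2.0, "difference": diff})
    return stats, coords


def stratify_errors(
    true: np.ndarray,
    imputed: np.ndarray,
    low: float = 65.0,
    high: float = 100.0,
) -> pd.DataFrame:
    """Errors stratified on the true value at clinical thresholds.

    Strata: below (< low), mid ([low, high], boundaries inclusive), above
    (> high) — matching strict inequalities for the extreme strata.  Empty
    strata report n = 0 with NaN errors.
    """
    true = np.asarray(true, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    masks = {
        f"<{low:g}": true < low,
        f"[{low:g}, {high:g}]": (true >= low) & (true <= high),
        f">{high:g}": true > high,
    }
    rows = []
    for label, m in masks.items():
        if m.sum() == 0:
            rows.append({"stratum": label, "n": 0, "MAE": np.nan, "RMSE": np.nan})
        else:
            mae, rmse = masked_error(true[m], imputed[m])
            rows.append({"stratum": label, "n": int(m.sum()), "MAE": mae, "RMSE": rmse})
    return pd.DataFrame(rows)


def render_report(
    error_table: pd.DataFrame,
    out_dir,
    bland_altman_table: pd.DataFrame | None = None,
    strata_table: pd.DataFrame | None = None,
) -> Path:
    """Write tidy CSV reports plus a human-readable summary.

    ``error_table`` is the seed-aggregated tidy table (method, scenario,
    variable, metric, mean, sd, n_seeds).  Row ordering is deterministic.
    Returns the output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    key_cols = [c for c in ("method", "scenario", "variable", "metric") if c in error_table.columns]
    table = error_table.sort_values(key_cols).reset_index(drop=True) if len(error_table) else error_table
    table.to_csv(out_dir / "errors.csv", index=False)
    if bland_altman_table is not None:
        bland_altman_table.to_csv(out_dir / "bland_altman.csv", index=False)
    if strata_table is not None:
        strata_table.to_csv(out_dir / "strata.csv", index=False)

    lines = ["Imputation benchmark summary", "=" * 28, ""]
    if len(table):
        pivot = table[table["variable"] == "all"] if "variable" in table.columns else table
        if {"method", "scenario", "metric", "mean"} <= set(pivot.columns) and len(pivot):
            for metric in sorted(pivot["metric"].unique()):
                sub = pivot[pivot["metric"] == metric]
                wide = sub.pivot(index="method", columns="scenario", values="mean")
                lines.append(f"{metric} (mean over seeds, variable = all)")
                lines.append(wide.round(4).to_string())
                lines.append("")
    else:
        lines.append("(no results)")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return out_dir
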