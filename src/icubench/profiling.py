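"""Missingness-structure and dependence profiling of hourly cohorts.

Computes the descriptive statistics used to characterise ICU monitoring
gaps: per-hour missing-rate curves, nullity (missing-indicator) correlation
between variables, maximal gap runs with their length-by-variables-involved
histogram, and pooled lagged Pearson correlations of the values themselves.

Applied to a cohort produced by the synthetic overlay, the gap-run
histogram recovers the generator's archetype weights (parameter-recovery
loop).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import N_VARIABLES, VARIABLES, Cohort

__all__ = [
    "GapRun",
    "hourly_missing_rate",
    "nullity_correlation",
    "gap_runs",
    "gap_run_histogram",
    "lagged_correlation",
    "profile_cohort",
    "ProfilingReport",
]


@dataclasses.dataclass(frozen=True)
class GapRun:
    """One maximal missing segment.

    ``variables`` holds every variable missing over exactly the span
    [start, start + length): per-variable maximal runs with identical extent
    are merged into a single multi-variable run, so an all-four monitoring
    dropout is one run.  Runs that overlap only partially stay separate
    per-variable runs.
    """

    stay_id: int
    variables: tuple[str, ...]
    start: int
    length: int

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_cells(self) -> int:
        return self.n_variables * self.length


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean array as (start, length)."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def hourly_missing_rate(cohort: Cohort) -> pd.DataFrame:
    """Per-hour missing percentage, per variable plus an overall curve.

    For hour t the per-variable entry is the percent of stays with that
    cell missing; "overall" is the percent missing across all variable
    cells at t.
    """
    if cohort.n_stays == 0:
        raise ValueError("cannot profile an empty cohort")
    miss = np.isnan(cohort.values)  # (n_stays, n_hours, 4)
    per_var = 100.0 * miss.mean(axis=0)
    overall = 100.0 * miss.mean(axis=(0, 2))
    df = pd.DataFrame(per_var, columns=list(VARIABLES))
    df.insert(0, "hour", np.arange(cohort.n_hours))
    df["overall"] = overall
    return df


def nullity_correlation(cohort: Cohort) -> np.ndarray:
    """4x4 Pearson correlation between binary missingness indicators.

    Pooled over all (stay, hour) cells.  A variable whose indicator is
    constant (never or always missing) has undefined correlations, reported
    as NaN rather than fabricated zeros; its diagonal entry is NaN too.
    """
    ind = np.isnan(cohort.values).reshape(-1, N_VARIABLES).astype(float)
    if ind.shape[0] < 2:
        raise ValueError("need at least two cells per variable")
    out = np.full((N_VARIABLES, N_VARIABLES), np.nan)
    sd = ind.std(axis=0)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(ind[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(ok)
        out[np.ix_(idx, idx)] = sub
    return out


def gap_runs(cohort: Cohort) -> list[GapRun]:
    """Extract all maximal missing segments of a cohort.

    Every missing cell belongs to exactly one returned run.
    """
    runs: list[GapRun] = []
    miss = np.isnan(cohort.values)
    for i in range(cohort.n_stays):
        extent: dict[tuple[int, int], list[str]] = {}
        for j, v in enumerate(VARIABLES):
            for start, length in _bool_runs(miss[i, :, j]):
                extent.setdefault((start, length), []).append(v)
        for (start, length), vs in sorted(extent.items()):
            runs.append(GapRun(int(cohort.stay_ids[i]), tuple(vs), start, length))
    return runs


def gap_run_histogram(runs: list[GapRun]) -> pd.DataFrame:
    """Proportions of gap runs by (length, number of variables involved)."""
    if not runs:
        return pd.DataFrame(columns=["length", "n_variables", "count", "proportion"])
    counts: dict[tuple[int, int], int] = {}
    for r in runs:
        counts[(r.length, r.n_variables)] = counts.get((r.length, r.n_variables), 0) + 1
    rows = [
        {"length": L, "n_variables": k, "count": c, "proportion": c / len(runs)}
        for (L, k), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def lagged_correlation(cohort: Cohort, max_lag: int = 3) -> dict[int, np.ndarray]:
    """Pooled lagged Pearson correlations between vital signs.

    For lag d, entry (a, b) is the Pearson r over all within-stay pairs
    (a_t, b_{t+d}) pooled across stays; pairs with either member missing
    are dropped, and pairs never straddle stay boundaries.  Satisfies
    r(a, b, d) = r(b, a, -d); within-feature lag-0 entries equal 1 by
    construction.  Combinations with fewer than two valid pairs or a
    constant member are NaN.
    """
    if max_lag >= cohort.n_hours:
        raise ValueError("max_lag must be smaller than the window length")
    result: dict[int, np.ndarray] = {}
    T = cohort.n_hours
    vals = cohort.values
    for d in range(0, max_lag + 1):
        mat = np.full((N_VARIABLES, N_VARIABLES), np.nan)
        for a in range(N_VARIABLES):
            for b in range(N_VARIABLES):
                x = vals[:, : T - d, a].reshape(-1)
                y = vals[:, d:, b].reshape(-1)
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                mat[a, b] = np.corrcoef(xs, ys)[0, 1]
        result[d] = mat
        if d > 0:
            result[-d] = mat.T
    return result


@dataclasses.dataclass
class ProfilingReport:
    """Bundle of missingness-profiling outputs with tidy serialization."""

    hourly_rates: pd.DataFrame
    nullity: np.ndarray
    gap_histogram: pd.DataFrame
    overall_missing_pct: float
    per_variable_missing_pct: dict[str, float]
    single_var_1h_pct: float
    all_four_pct: float

    def to_json(self, path) -> None:
        payload = {
            "overall_missing_pct": self.overall_missing_pct,
            "per_variable_missing_pct": self.per_variable_missing_pct,
            "single_var_1h_pct": self.single_var_1h_pct,
            "all_four_pct": self.all_four_pct,
            "nullity": [[None if np.isnan(x) else float(x) for x in row] for row in self.nullity],
            "variables": list(VARIABLES),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        """One row per scalar statistic, tidy."""
        rows = [("overall_missing_pct", "all", self.overall_missing_pct)]
        rows += [
            ("variable_missing_pct", v, p) for v, p in self.per_variable_missing_pct.items()
        ]
        rows.append(("single_var_1h_pct", "all", self.single_var_1h_pct))
        rows.append(("all_four_pct", "all", self.all_four_pct))
        pd.DataFrame(rows, columns=["statistic", "variable", "value"]).to_csv(path, index=False)


def profile_cohort(cohort: Cohort) -> ProfilingReport:
    """Compute the full missingness profile of a cohort."""
    runs = gap_runs(cohort)
    hist = gap_run_histogram(runs)
    miss = np.isnan(cohort.values)
    n_runs = max(len(runs), 1)
    sv1 = sum(1 for r in runs if r.n_variables == 1 and r.length == 1)
    a4 = sum(1 for r in runs if r.n_variables == N_VARIABLES)
    return ProfilingReport(
        hourly_rates=hourly_missing_rate(cohort),
        nullity=nullity_correlation(cohort),
        gap_histogram=hist,
        overall_missing_pct=100.0 * float(miss.mean()),
        per_variable_missing_pct={
            v: 100.0 * float(miss[:, :, j].mean()) for j, v in enumerate(VARIABLES)
        },
        single_var_1h_pct=100.0 * sv1 / n_runs,
        all_four_pct=100.0 * a4 / n_runs,
    )
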