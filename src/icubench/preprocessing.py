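"""Cohort preparation: hourly aggregation, plausibility filtering,
missing-hours exclusion, splitting and train-only standardization.

The preparation protocol mirrors common ICU EHR practice: raw timestamped
measurements are aggregated to hourly bins by the median; implausible values
(non-positive rates or pressures, SpO2 above 100%, values beyond +/-3
train-split standard deviations from the train-split mean) are set to
missing; stays with too many missing hours are excluded; and all modelling
happens in z-scored space with parameters fitted on the training split only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_WINDOW_HOURS,
    N_VARIABLES,
    STREAM_SPLIT,
    VAR_INDEX,
    VARIABLES,
    Cohort,
    substream,
)

__all__ = [
    "StandardizationParams",
    "CohortSplit",
    "DEFAULT_PLAUSIBILITY_BOUNDS",
    "aggregate_hourly",
    "apply_plausibility_filters",
    "filter_stays",
    "split_cohort",
    "fit_standardization",
    "standardize",
]

# Physiological plausibility: rates and pressures must be strictly positive,
# saturation cannot exceed 100%.  Bounds are (exclusive_min, inclusive_max).
DEFAULT_PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "HR": (0.0, np.inf),
    "SpO2": (0.0, 100.0),
    "RR": (0.0, np.inf),
    "MBP": (0.0, np.inf),
}


@dataclasses.dataclass(frozen=True)
class StandardizationParams:
    """Per-variable mean/SD in physical units, fitted on the training split.

    The SD uses the sample (n-1) convention.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    provenance: str = "train"

    def __post_init__(self) -> None:
        for v, s in self.sd.items():
            if not s > 0:
                raise ValueError(f"{v}: SD must be > 0, got {s}")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"mean": self.mean, "sd": self.sd, "provenance": self.provenance}, indent=2
            )
        )

    @classmethod
    def from_json(cls, path) -> "StandardizationParams":
        d = json.loads(Path(path).read_text())
        return cls(mean=d["mean"], sd=d["sd"], provenance=d.get("provenance", "train"))


@dataclasses.dataclass(frozen=True)
class CohortSplit:
    """Disjoint stay-level partition into train / validation / test."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        ids = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(ids)) != len(ids):
            raise ValueError("split groups must be disjoint")


def aggregate_hourly(
    records: pd.DataFrame, window_hours: int = DEFAULT_WINDOW_HOURS
) -> Cohort:
    """Aggregate timestamped measurements to hourly panels by the median.

    ``records`` must carry columns (stay_id, time_hours, variable, value)
    where ``time_hours`` is the offset from ICU admission.  Hour bins are
    half-open [t, t+1); the per-bin value is the median of records in the
    bin (even counts: mean of the middle two); empty bins are missing;
    records at or beyond ``window_hours`` are discarded.
    """
    required = {"stay_id", "time_hours", "variable", "value"}
    if missing := required - set(records.columns):
        raise ValueError(f"records lack columns {sorted(missing)}")
    t = records["time_hours"].to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValueError("negative timestamps are not allowed")
    unknown = set(records["variable"].unique()) - set(VARIABLES)
    if unknown:
        raise ValueError(f"unknown variable names {sorted(unknown)}")

    kept = records.loc[t < window_hours].copy()
    kept["hour"] = np.floor(kept["time_hours"].to_numpy(dtype=float)).astype(int)
    med = kept.groupby(["stay_id", "hour", "variable"], sort=True)["value"].median()

    stay_ids = np.sort(records["stay_id"].unique())
    values = np.full((len(stay_ids), window_hours, N_VARIABLES), np.nan)
    srow = {s: i for i, s in enumerate(stay_ids)}
    for (sid, hour, var), val in med.items():
        values[srow[sid], hour, VAR_INDEX[var]] = val
    native = np.isnan(values)
    return Cohort(values, native, stay_ids)


def apply_plausibility_filters(
    cohort: Cohort,
    params: StandardizationParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_sd: float = 3.0,
) -> tuple[Cohort, dict[str, int]]:
    """Set implausible cells to missing (never clipped).

    A cell is removed when its value falls outside the closed interval
    [mean - n_sd*SD, mean + n_sd*SD] (mean/SD train-fitted), is not strictly
    above the variable's plausibility floor, or exceeds its ceiling (e.g.
    SpO2 > 100%).  Returns the filtered cohort and per-variable counts of
    removed cells.  Removed cells are flagged natively missing.
    """
    bounds = DEFAULT_PLAUSIBILITY_BOUNDS if bounds is None else bounds
    for v in VARIABLES:
        if v not in params.mean or v not in params.sd:
            raise ValueError(f"standardization params missing variable {v}")
    out = cohort.copy()
    removed: dict[str, int] = {}
    for j, v in enumerate(VARIABLES):
        lo_sd = params.mean[v] - n_sd * params.sd[v]
        hi_sd = params.mean[v] + n_sd * params.sd[v]
        floor, ceil = bounds.get(v, (-np.inf, np.inf))
        col = out.values[:, :, j]
        with np.errstate(invalid="ignore"):
            bad = (col < lo_sd) | (col > hi_sd) | (col <= floor) | (col > ceil)
        bad &= ~np.isnan(col)
        removed[v] = int(bad.sum())
        col[bad] = np.nan
        out.native_missing[:, :, j] |= bad
    return out, removed


def filter_stays(
    cohort: Cohort, max_missing_hours: int = 16
) -> tuple[Cohort, pd.DataFrame]:
    """Exclude stays with more than ``max_missing_hours`` missing hours.

    A stay's missing-hour count is the number of hourly time points at which
    at least one variable is missing.  The exclusion is strict: exactly
    ``max_missing_hours`` missing hours is retained.  Returns the retained
    cohort and a log of excluded stays with their counts.
    """
    missing_any = np.isnan(cohort.values).any(axis=2)  # (n_stays, n_hours)
    counts = missing_any.sum(axis=1)
    keep = counts <= max_missing_hours
    log = pd.DataFrame(
        {"stay_id": cohort.stay_ids[~keep], "missing_hours": counts[~keep]}
    )
    retained = Cohort(
        cohort.values[keep], cohort.native_missing[keep], cohort.stay_ids[keep]
    )
    return retained, log


def split_cohort(
    cohort: Cohort, fractions: tuple[float, ...] = (0.6, 0.2, 0.2), seed: int = 0
) -> CohortSplit:
    """Stay-level random partition into train/validation/test.

    Group sizes follow cumulative rounding of the fractions, so e.g.
    (0.6, 0.2, 0.2) over 10 stays yields sizes (6, 2, 2).  Deterministic
    given seed.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must have three entries (train, validation, test)")
    if any(f < 0 for f in fractions) or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    n = cohort.n_stays
    n_groups = sum(1 for f in fractions if f > 0)
    if n < n_groups:
        raise ValueError(f"cannot split {n} stays into {n_groups} non-empty groups")
    rng = substream(seed, STREAM_SPLIT)
    perm = rng.permutation(n)
    ids = cohort.stay_ids[perm]
    cuts = np.round(np.cumsum(fractions) * n).astype(int)
    return CohortSplit(
        train=np.sort(ids[: cuts[0]]),
        validation=np.sort(ids[cuts[0]: cuts[1]]),
        test=np.sort(ids[cuts[1]: cuts[2]]),
        fractions=tuple(fractions),
        seed=seed,
    )


def fit_standardization(cohort: Cohort, provenance: str = "train") -> StandardizationParams:
    """Per-variable mean/SD over observed cells only (sample SD, n-1).

    Raises if any variable has fewer than two observed cells or zero
    variance.
    """
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for j, v in enumerate(VARIABLES):
        col = cohort.values[:, :, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            raise ValueError(f"{v}: need at least two observed cells to standardize")
        s = float(np.std(obs, ddof=1))
        if s == 0.0:
            raise ValueError(f"{v}: zero variance in observed cells")
        mean[v] = float(np.mean(obs))
        sd[v] = s
    return StandardizationParams(mean=mean, sd=sd, provenance=provenance)


def standardize(
    cohort: Cohort, params: StandardizationParams, inverse: bool = False
) -> Cohort:
    """Z-score a cohort (or undo it with ``inverse=True``).

    Missing cells stay missing; the missingness pattern is untouched in both
    directions.
    """
    for v in VARIABLES:
        if v not in params.mean or v not in params.sd:
            raise ValueError(f"standardization params missing variable {v}")
    out = cohort.copy()
    for j, v in enumerate(VARIABLES):
        if inverse:
            out.values[:, :, j] = out.values[:, :, j] * params.sd[v] + params.mean[v]
        else:
            out.values[:, :, j] = (out.values[:, :, j] - params.mean[v]) / params.sd[v]
    return out
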