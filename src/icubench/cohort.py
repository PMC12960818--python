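"""Core container for hourly ICU vital-sign panels.

A cohort is a stack of per-stay panels on a fixed hourly grid (default 48
hours from ICU admission) over the four continuously monitored vital signs:
heart rate (HR, bpm), oxygen saturation (SpO2, %), respiratory rate
(RR, /min) and mean blood pressure (MBP, mmHg).

Missing cells are encoded as NaN in ``values``.  The boolean
``native_missing`` array distinguishes cells that were missing in the source
data (or made missing by plausibility filtering) from cells hidden later by
an artificial masking scenario: a masked cell is NaN in ``values`` but False
in ``native_missing``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

VARIABLES: tuple[str, ...] = ("HR", "SpO2", "RR", "MBP")
UNITS: dict[str, str] = {"HR": "bpm", "SpO2": "%", "RR": "/min", "MBP": "mmHg"}
VAR_INDEX: dict[str, int] = {v: i for i, v in enumerate(VARIABLES)}
N_VARIABLES = len(VARIABLES)
DEFAULT_WINDOW_HOURS = 48

# Stream tags for deriving independent per-purpose random substreams from one
# root seed (see `substream`).  Keeping these distinct guarantees that e.g.
# value generation and missingness overlay never share a stream even when the
# caller passes the same root seed to both.
STREAM_GENERATE = 0
STREAM_OVERLAY = 1
STREAM_SUBHOURLY = 2
STREAM_MASK = 3
STREAM_SPLIT = 4
STREAM_IMPUTE = 5


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a generator for a stable substream of the root ``seed``.

    The substream is identified by an integer key tuple (typically a stream
    tag plus a stay index).  Substreams are independent of one another and of
    how many other substreams are drawn, so e.g. adding stays to a cohort
    never perturbs the values of earlier stays.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclasses.dataclass
class Cohort:
    """Stack of hourly vital-sign panels.

    Parameters
    ----------
    values
        float array of shape ``(n_stays, n_hours, 4)``; NaN encodes missing.
        Variable order follows :data:`VARIABLES`.
    native_missing
        bool array of the same shape; True where the cell is missing in the
        source data (as opposed to hidden by an artificial mask).
    stay_ids
        integer identifiers, one per stay, unique.
    """

    values: np.ndarray
    native_missing: np.ndarray
    stay_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.native_missing = np.asarray(self.native_missing, dtype=bool)
        self.stay_ids = np.asarray(self.stay_ids)
        if self.values.ndim != 3 or self.values.shape[2] != N_VARIABLES:
            raise ValueError(
                f"values must have shape (n_stays, n_hours, {N_VARIABLES}); "
                f"got {self.values.shape}"
            )
        if self.native_missing.shape != self.values.shape:
            raise ValueError("native_missing shape must match values shape")
        if self.stay_ids.shape != (self.values.shape[0],):
            raise ValueError("stay_ids must have one entry per stay")
        if len(np.unique(self.stay_ids)) != len(self.stay_ids):
            raise ValueError("stay_ids must be unique")
        if np.any(self.native_missing & ~np.isnan(self.values)):
            raise ValueError("native-missing cells must hold NaN values")

    # -- basic introspection -------------------------------------------------

    @property
    def n_stays(self) -> int:
        return self.values.shape[0]

    @property
    def n_hours(self) -> int:
        return self.values.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean array, True where a value is present."""
        return ~np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def missing_fraction(self) -> float:
        """Fraction of all cells that are missing (NaN)."""
        if self.values.size == 0:
            return 0.0
        return float(np.isnan(self.values).mean())

    def index_of(self, stay_id) -> int:
        idx = np.flatnonzero(self.stay_ids == stay_id)
        if idx.size == 0:
            raise KeyError(f"unknown stay id {stay_id!r}")
        return int(idx[0])

    def copy(self) -> "Cohort":
        return Cohort(self.values.copy(), self.native_missing.copy(), self.stay_ids.copy())

    def subset(self, stay_ids) -> "Cohort":
        """Return the sub-cohort containing exactly the given stay ids."""
        order = {s: i for i, s in enumerate(self.stay_ids)}
        try:
            rows = np.array([order[s] for s in stay_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"stay id {exc.args[0]!r} not in cohort") from exc
        return Cohort(self.values[rows], self.native_missing[rows], np.asarray(list(stay_ids)))

    # -- long-format interchange --------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Tidy long-format view: one row per (stay, hour, variable) cell."""
        n_s, n_h, n_v = self.values.shape
        stay = np.repeat(self.stay_ids, n_h * n_v)
        hour = np.tile(np.repeat(np.arange(n_h), n_v), n_s)
        variable = np.tile(np.array(VARIABLES), n_s * n_h)
        return pd.DataFrame(
            {
                "stay_id": stay,
                "hour": hour,
                "variable": variable,
                "value": self.values.reshape(-1),
                "native_missing": self.native_missing.reshape(-1),
            }
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, n_hours: int = DEFAULT_WINDOW_HOURS) -> "Cohort":
        """Build a cohort from a long-format table.

        Rows absent from the table are treated as natively missing cells, as
        are rows with NaN values.  A ``native_missing`` column, if present,
        is honoured for rows that carry no value.
        """
        required = {"stay_id", "hour", "variable", "value"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"long-format table lacks columns {sorted(missing_cols)}")
        bad = set(df["variable"].unique()) - set(VARIABLES)
        if bad:
            raise ValueError(f"unknown variables {sorted(bad)}")
        stay_ids = np.sort(df["stay_id"].unique())
        n_s = len(stay_ids)
        values = np.full((n_s, n_hours, N_VARIABLES), np.nan)
        native = np.ones((n_s, n_hours, N_VARIABLES), dtype=bool)
        srow = {s: i for i, s in enumerate(stay_ids)}
        si = df["stay_id"].map(srow).to_numpy()
        hi = df["hour"].to_numpy(dtype=int)
        vi = df["variable"].map(VAR_INDEX).to_numpy(dtype=int)
        if np.any(hi < 0) or np.any(hi >= n_hours):
            raise ValueError(f"hour indices must lie in [0, {n_hours})")
        vals = df["value"].to_numpy(dtype=float)
        values[si, hi, vi] = vals
        native[si, hi, vi] = np.isnan(vals)
        return cls(values, native, stay_ids)

    # -- file I/O ------------------------------------------------------------

    def write(self, path) -> None:
        """Write the cohort in long format (CSV or Parquet, by suffix)."""
        path = Path(path)
        long = self.to_long()
        if path.suffix == ".parquet":
            long.to_parquet(path, index=False)
        else:
            long.to_csv(path, index=False)

    @classmethod
    def read(cls, path, n_hours: int = DEFAULT_WINDOW_HOURS) -> "Cohort":
        path = Path(path)
        if path.suffix == ".parquet":
            df = pd.read_parquet(path)
        else:
            df = pd.read_csv(path)
        return cls.from_long(df, n_hours=n_hours)
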