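"""Real-world-inspired masking scenarios.

Three mechanisms hide observed cells for later reconstruction scoring:

* **MCAR** — cells removed independently and uniformly across stays, hours
  and variables (sporadic isolated gaps).
* **Temporal interruption** — blocks of 1-3 consecutive hours masked across
  all four variables at once (patient transport, procedures).
* **Sensor failure** — one variable masked over a continuous multi-hour
  window (probe displacement, arterial-line issues).

Masks never touch natively missing cells: without a held-out true value a
cell cannot be scored.  Each scenario removes approximately 30% of the
available data by default (for sensor failure, 30% of the target
variable's cells).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import STREAM_MASK, VAR_INDEX, VARIABLES, Cohort, substream

__all__ = [
    "MaskSpec",
    "mask_mcar",
    "mask_interruption",
    "mask_sensor_failure",
    "apply_mask",
]

logger = logging.getLogger(__name__)

DEFAULT_MASK_FRACTION = 0.30


@dataclasses.dataclass
class MaskSpec:
    """One scenario draw: the set of artificially hidden cells.

    ``cells`` has columns (stay_id, variable, hour), unique rows, all
    referring to observed cells of the cohort the mask was drawn on.  After
    :func:`apply_mask`, ``truth`` holds the held-out true values aligned
    with ``cells``.
    """

    scenario: str
    seed: int
    cells: pd.DataFrame
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = ["stay_id", "variable", "hour"]
        if list(self.cells.columns) != expected:
            self.cells = self.cells.loc[:, expected]
        if self.cells.duplicated().any():
            raise ValueError("mask cells must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def write(self, path) -> None:
        """CSV of cells plus a JSON header sidecar."""
        path = Path(path)
        self.cells.to_csv(path, index=False)
        header = {"scenario": self.scenario, "seed": self.seed, "n_cells": self.n_cells}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))


def _index_triples(cohort: Cohort, cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    srow = {s: i for i, s in enumerate(cohort.stay_ids)}
    try:
        si = cells["stay_id"].map(srow).to_numpy()
    except KeyError as exc:  # pragma: no cover
        raise ValueError(f"mask references unknown stay {exc}") from exc
    if np.any(pd.isna(si)):
        raise ValueError("mask references stays absent from the cohort")
    hi = cells["hour"].to_numpy(dtype=int)
    if np.any(hi < 0) or np.any(hi >= cohort.n_hours):
        raise ValueError("mask references out-of-range hours")
    vi = cells["variable"].map(VAR_INDEX).to_numpy()
    if np.any(pd.isna(vi)):
        raise ValueError("mask references unknown variables")
    return si.astype(int), hi, vi.astype(int)


def _cells_frame(cohort: Cohort, triples: np.ndarray) -> pd.DataFrame:
    """Triples of (stay_index, hour, var_index) -> tidy cells frame."""
    return pd.DataFrame(
        {
            "stay_id": cohort.stay_ids[triples[:, 0]],
            "variable": np.array(VARIABLES)[triples[:, 2]],
            "hour": triples[:, 1],
        }
    )


def mask_mcar(
    cohort: Cohort, fraction: float = DEFAULT_MASK_FRACTION, seed: int = 0
) -> MaskSpec:
    """Uniform random cell removal.

    Exactly ``floor(fraction * n_observed)`` observed cells are sampled
    without replacement.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    observed = np.argwhere(~np.isnan(cohort.values))  # rows: (stay, hour, var)
    k = int(np.floor(fraction * len(observed)))
    rng = substream(seed, STREAM_MASK, 0)
    chosen = observed[rng.choice(len(observed), size=k, replace=False)] if k else observed[:0]
    return MaskSpec("mcar", seed, _cells_frame(cohort, chosen))


def _feasible_starts(
    obs_ok: np.ndarray, length: int, placed: list[tuple[int, int]]
) -> np.ndarray:
    """Start hours where a run of ``length`` fits: fully observed, not
    overlapping and not abutting any already placed artificial run (a one
    hour separation keeps distinct runs distinct, so every placed run keeps
    its exact configured length).

    ``obs_ok`` is a 1-D bool array, True where the hour is maskable.
    """
    T = obs_ok.size
    ok = np.array(
        [obs_ok[s : s + length].all() for s in range(T - length + 1)], dtype=bool
    )
    for ps, pl in placed:
        lo = max(0, ps - length)
        hi = min(T - length + 1, ps + pl + 1)
        ok[lo:hi] = False
    return np.flatnonzero(ok)


def mask_interruption(
    cohort: Cohort,
    block_length: int | str = 1,
    blocks_per_stay: int | None = None,
    target_fraction: float | None = None,
    seed: int = 0,
) -> MaskSpec:
    """Temporal-interruption masking: all-four-variable blocks.

    ``block_length`` is 1, 2, 3 or ``"mixed"`` (each block's length drawn
    uniformly from {1, 2, 3}).  Per stay, a block budget is either given
    explicitly or solved from ``target_fraction`` of the stay's observed
    cells (default 30%).  Blocks only cover hours where all four variables
    are observed and never overlap each other; a stay whose feasible starts
    run out before its budget gets as many blocks as fit, with a logged
    warning.
    """
    mixed = block_length == "mixed"
    if not mixed and block_length not in (1, 2, 3):
        raise ValueError("block_length must be 1, 2, 3 or 'mixed'")
    if blocks_per_stay is None and target_fraction is None:
        target_fraction = DEFAULT_MASK_FRACTION
    mean_len = 2.0 if mixed else float(block_length)
    label = "interruption-mixed" if mixed else f"interruption-{block_length}h"

    triples: list[tuple[int, int, int]] = []
    observed = ~np.isnan(cohort.values)
    for i in range(cohort.n_stays):
        rng = substream(seed, STREAM_MASK, 1, i)
        obs_all4 = observed[i].all(axis=1)
        n_obs = int(observed[i].sum())
        if blocks_per_stay is not None:
            budget = blocks_per_stay
        else:
            budget = int(round(target_fraction * n_obs / (4.0 * mean_len)))
        placed: list[tuple[int, int]] = []
        shortfall = 0
        for _ in range(budget):
            L = int(rng.integers(1, 4)) if mixed else int(block_length)
            starts = _feasible_starts(obs_all4, L, placed)
            if starts.size == 0:
                shortfall += 1
                continue
            s = int(starts[rng.integers(starts.size)])
            placed.append((s, L))
            for t in range(s, s + L):
                for j in range(len(VARIABLES)):
                    triples.append((i, t, j))
        if shortfall:
            logger.warning(
                "stay %s: %d interruption block(s) skipped (no feasible start)",
                cohort.stay_ids[i],
                shortfall,
            )
    return MaskSpec(label, seed, _cells_frame(cohort, np.array(triples or np.empty((0, 3), int))))


def mask_sensor_failure(
    cohort: Cohort,
    variable: str,
    duration: int = 4,
    runs_per_stay: int | None = None,
    target_fraction: float = DEFAULT_MASK_FRACTION,
    seed: int = 0,
) -> MaskSpec:
    """Sensor-failure masking: single-variable contiguous windows.

    Per stay, ``runs_per_stay`` non-overlapping runs of exactly
    ``duration`` hours are hidden in the target variable, with start hours
    drawn uniformly among fully observed feasible starts.  By default the
    budget approaches ``target_fraction`` of the variable's window.
    """
    if variable not in VAR_INDEX:
        raise ValueError(f"unknown variable {variable!r}")
    if not 1 <= duration <= cohort.n_hours:
        raise ValueError("duration must lie in [1, window length]")
    j = VAR_INDEX[variable]
    if runs_per_stay is None:
        runs_per_stay = max(1, int(round(target_fraction * cohort.n_hours / duration)))

    triples: list[tuple[int, int, int]] = []
    observed = ~np.isnan(cohort.values)
    for i in range(cohort.n_stays):
        rng = substream(seed, STREAM_MASK, 2, i)
        obs_var = observed[i, :, j]
        placed: list[tuple[int, int]] = []
        shortfall = 0
        for _ in range(runs_per_stay):
            starts = _feasible_starts(obs_var, duration, placed)
            if starts.size == 0:
                shortfall += 1
                continue
            s = int(starts[rng.integers(starts.size)])
            placed.append((s, duration))
            for t in range(s, s + duration):
                triples.append((i, t, j))
        if shortfall:
            logger.warning(
                "stay %s: %d sensor-failure run(s) skipped (no feasible start)",
                cohort.stay_ids[i],
                shortfall,
            )
    return MaskSpec(
        f"sensor-{variable}", seed, _cells_frame(cohort, np.array(triples or np.empty((0, 3), int)))
    )


def apply_mask(cohort: Cohort, mask: MaskSpec) -> tuple[Cohort, pd.DataFrame]:
    """Hide the mask's cells and capture their true values.

    Returns a new cohort with masked cells set to NaN (native-missing flags
    untouched) and a ground-truth store: the mask's cells frame with a
    ``value`` column.  The truth values are also recorded on the mask.
    A mask referring to a natively missing or out-of-range cell is corrupt
    and raises.
    """
    si, hi, vi = _index_triples(cohort, mask.cells)
    vals = cohort.values[si, hi, vi]
    if np.isnan(vals).any():
        raise ValueError("corrupt mask: references a missing cell")
    out = cohort.copy()
    out.values[si, hi, vi] = np.nan
    mask.truth = vals.copy()
    truth_store = mask.cells.copy()
    truth_store["value"] = vals
    return out, truth_store
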