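"""End-to-end benchmark orchestration.

Pipeline: generate (or load) a cohort -> plausibility filter -> exclude
heavily missing stays -> stay-level split -> train-only standardization ->
per run seed: fit every imputer on the MCAR-masked training split, then for
each scenario mask the test split, impute, and score on the masked entries
-> aggregate over seeds -> tidy reports with a reproducibility manifest.

Each run seed governs both mask construction (training and evaluation) and
any stochastic components of the imputers, so rerunning a config reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import VARIABLES, Cohort
from .evaluation import (
    aggregate_seeds,
    bland_altman,
    collect_pairs,
    per_variable_errors,
    render_report,
    stratify_errors,
)
from .imputers import get_imputer
from .masking import apply_mask, mask_interruption, mask_mcar, mask_sensor_failure
from .preprocessing import (
    apply_plausibility_filters,
    filter_stays,
    fit_standardization,
    split_cohort,
    standardize,
)
from .synthetic import MissingnessProfile, generate_cohort, overlay_native_missingness

__all__ = ["RunConfig", "run_benchmark", "DEFAULT_SCENARIOS", "DEFAULT_METHODS"]

DEFAULT_SCENARIOS = (
    "mcar",
    "interruption-1h",
    "interruption-2h",
    "interruption-3h",
    "sensor-RR",
    "sensor-HR",
    "sensor-MBP",
    "sensor-SpO2",
)
DEFAULT_METHODS = ("mean", "median", "locf", "linear", "mice", "missforest")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one benchmark run."""

    n_stays: int = 2000
    cohort_seed: int = 0
    input_path: str | None = None  # long-format CSV/Parquet; overrides synthesis
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    methods: tuple[str, ...] = DEFAULT_METHODS
    method_params: dict = dataclasses.field(default_factory=dict)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    mask_fraction: float = 0.30
    max_missing_hours: int = 16
    evaluate_physical: bool = True  # MBP agreement analyses in mmHg
    out_dir: str = "benchmark_out"

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("need at least one scenario")
        if not self.methods:
            raise ValueError("need at least one method")
        if not self.seeds:
            raise ValueError("need at least one seed")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("split_fractions", "scenarios", "methods", "seeds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("split_fractions", "scenarios", "methods", "seeds"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _make_scenario_mask(name: str, cohort: Cohort, fraction: float, seed: int):
    if name == "mcar":
        return mask_mcar(cohort, fraction=fraction, seed=seed)
    if name.startswith("interruption-"):
        tag = name.removeprefix("interruption-")
        if tag == "mixed":
            return mask_interruption(cohort, "mixed", target_fraction=fraction, seed=seed)
        if tag.endswith("h") and tag[:-1] in ("1", "2", "3"):
            return mask_interruption(
                cohort, int(tag[:-1]), target_fraction=fraction, seed=seed
            )
    if name.startswith("sensor-"):
        var = name.removeprefix("sensor-")
        if var in VARIABLES:
            return mask_sensor_failure(
                cohort, var, duration=4, target_fraction=fraction, seed=seed
            )
    raise KeyError(f"unknown scenario {name!r}")


def _load_or_generate(config: RunConfig) -> Cohort:
    if config.input_path is not None:
        return Cohort.read(config.input_path)
    complete = generate_cohort(n_stays=config.n_stays, seed=config.cohort_seed)
    return overlay_native_missingness(
        complete, MissingnessProfile.default(), seed=config.cohort_seed
    )


def run_benchmark(config: RunConfig) -> Path:
    """Execute the full benchmark described by ``config``.

    Writes per-seed and aggregated error tables, MBP agreement reports and
    a manifest into ``config.out_dir``; returns that directory.
    """
    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = _load_or_generate(config)

    # Preparation protocol: train-fitted filters, exclusion, standardization.
    split0 = split_cohort(cohort, config.split_fractions, seed=config.cohort_seed)
    prelim_params = fit_standardization(cohort.subset(split0.train))
    cohort, removed = apply_plausibility_filters(cohort, prelim_params)
    cohort, exclusion_log = filter_stays(cohort, config.max_missing_hours)
    exclusion_log.to_csv(out_dir / "excluded_stays.csv", index=False)

    split = split_cohort(cohort, config.split_fractions, seed=config.cohort_seed)
    train = cohort.subset(split.train)
    test = cohort.subset(split.test)
    params = fit_standardization(train)
    params.to_json(out_dir / "standardization.json")
    train_z = standardize(train, params)
    test_z = standardize(test, params)

    per_seed_tables: list[pd.DataFrame] = []
    ba_rows: list[dict] = []
    strata_rows: list[dict] = []
    mbp_sd = params.sd["MBP"]
    mbp_mean = params.mean["MBP"]

    for seed in config.seeds:
        # Training protocol: every method fits on the same MCAR-masked train split.
        train_mask = mask_mcar(train_z, fraction=config.mask_fraction, seed=seed)
        masked_train, _ = apply_mask(train_z, train_mask)
        fitted = {}
        for name in config.methods:
            params_kw = dict(config.method_params.get(name, {}))
            imp = get_imputer(name, **params_kw)
            if hasattr(imp, "seed"):
                imp.seed = seed
            fitted[name] = imp.fit(masked_train)

        for scenario in config.scenarios:
            mask = _make_scenario_mask(scenario, test_z, config.mask_fraction, seed)
            masked_test, truth = apply_mask(test_z, mask)
            for name in config.methods:
                imputed = fitted[name].impute(masked_test)
                pairs = collect_pairs(truth, imputed)
                errs = per_variable_errors(pairs)
                for _, row in errs.iterrows():
                    for metric in ("MAE", "RMSE"):
                        per_seed_tables.append(
                            pd.DataFrame(
                                [
                                    {
                                        "method": name,
                                        "scenario": scenario,
                                        "variable": row["variable"],
                                        "metric": metric,
                                        "seed": seed,
                                        "value": row[metric],
                                    }
                                ]
                            )
                        )
                if config.evaluate_physical:
                    mbp = pairs[pairs["variable"] == "MBP"]
                    if len(mbp) >= 2:
                        true_mm = mbp["true"].to_numpy() * mbp_sd + mbp_mean
                        imp_mm = mbp["imputed"].to_numpy() * mbp_sd + mbp_mean
                        stats, _ = bland_altman(true_mm, imp_mm)
                        ba_rows.append(
                            {
                                "method": name,
                                "scenario": scenario,
                                "seed": seed,
                                "bias": stats.bias,
                                "sd": stats.sd,
                                "loa_low": stats.loa_low,
                                "loa_high": stats.loa_high,
                                "n": stats.n,
                            }
                        )
                        strata = stratify_errors(true_mm, imp_mm)
                        for _, srow in strata.iterrows():
                            strata_rows.append(
                                {
                                    "method": name,
                                    "scenario": scenario,
                                    "seed": seed,
                                    **srow.to_dict(),
                                }
                            )

    per_seed = pd.concat(per_seed_tables, ignore_index=True)
    for seed in config.seeds:
        per_seed[per_seed["seed"] == seed].to_csv(
            out_dir / f"errors_seed{seed}.csv", index=False
        )
    seed_frames = [per_seed[per_seed["seed"] == s] for s in config.seeds]
    aggregated = aggregate_seeds(seed_frames)
    render_report(
        aggregated,
        out_dir,
        bland_altman_table=pd.DataFrame(ba_rows) if ba_rows else None,
        strata_table=pd.DataFrame(strata_rows) if strata_rows else None,
    )

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_stays_input": int(config.n_stays),
        "n_stays_retained": int(cohort.n_stays),
        "n_train": int(len(split.train)),
        "n_validation": int(len(split.validation)),
        "n_test": int(len(split.test)),
        "cells_removed_by_filters": removed,
        "runtime_seconds": round(time.monotonic() - t0, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
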