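# icubench

Benchmarking framework for missing-value imputation in multivariate ICU
vital-sign time series under **realistic missingness mechanisms**.

Bedside monitoring data (heart rate, SpO₂, respiratory rate, mean blood
pressure) are riddled with gaps that are anything but random: one-hour
single-channel dropouts, simultaneous interruptions of all monitoring during
patient transport, and multi-hour single-sensor outages. Benchmarks that hide
data *completely at random* (MCAR) systematically flatter every imputation
method and compress the differences between them. `icubench` lets you score
imputers under mechanism-realistic masking, on synthetic cohorts calibrated to
the missingness structure of real ICU monitoring data — no access to a
clinical database required.

The package is aimed at researchers developing or selecting imputation
methods for clinical time series, and at anyone who needs a reproducible,
fully synthetic test bed for missing-data tooling.

## What it does

- **Synthetic cohorts** — 48-hour hourly panels of HR, SpO₂, RR and MBP per
  stay. Per variable, a stationary AR(1) Gaussian latent process
  `z_t = φ z_{t−1} + √(1−φ²) ε_t` with weakly cross-correlated innovations is
  pushed through a marginal transform (affine for HR/RR/MBP; a
  100-minus-lognormal map for the right-skewed SpO₂) and clipped to hard
  physiological bounds. Defaults: HR mean 86.6, SD 18.4 bpm, φ = 0.94 (pooled
  autocorrelation ≥ 0.8 out to 3 h), cross-correlation ≤ 0.2.
- **Native-missingness overlay** — a marked point process of gap events per
  stay (Poisson count, late-stay hazard ramp) drawn from a gap-archetype
  mixture: 53% single-variable 1 h, 18% 2 h, 7% 3 h, 3% up to 4 h, 16%
  simultaneous all-four-variable blocks, 3% two-variable gaps. The event rate
  is solved in closed form so the expected missing-cell fraction is 3.8%.
- **Preprocessing** — hourly median aggregation, ±3 SD and physiological
  plausibility filters (train-fitted), >16-missing-hours stay exclusion,
  stay-level splits, train-only z-scoring with exact back-transformation.
- **Profiling** — per-hour missing-rate curves, nullity (missing-indicator
  Pearson) correlation, maximal gap-run extraction with a
  length-by-variables-involved histogram, pooled lagged correlations. The
  profiler closes the loop: applied to an overlay-generated cohort it
  recovers the generator's parameters.
- **Masking scenarios** — MCAR, temporal interruptions (1–3 h all-variable
  blocks) and sensor failures (4 h single-variable windows), each removing
  ≈30% of the available data, never touching natively missing cells.
- **Imputers** — mean/median, LOCF, linear interpolation, and
  chained-equations loops with ridge (`mice`) or random-forest
  (`missforest`) regressors, all behind one `fit`/`impute` contract
  (observed cells untouched; output complete). Deep models plug in through
  a contract-enforcing adapter.
- **Evaluation** — masked-entry MAE/RMSE
  (`MAE = (1/n) Σ|xᵢ−yᵢ|`, `RMSE = √((1/n) Σ(xᵢ−yᵢ)²)`), mean ± SD over
  seeds, Bland–Altman agreement (bias ± 1.96 SD limits) and MBP error strata
  at < 65 and > 100 mmHg in physical units.

## Worked example

```python
import icubench as ib

cohort = ib.generate_cohort(n_stays=200, seed=0)
observed = ib.overlay_native_missingness(cohort, seed=1)
report = ib.profile_cohort(observed)
print(f"overall missing: {report.overall_missing_pct:.2f}%")
print(f"single-variable 1 h segments: {report.single_var_1h_pct:.1f}%")
print(f"all-four-variable segments:   {report.all_four_pct:.1f}%")

params = ib.fit_standardization(observed)
z = ib.standardize(observed, params)
mask = ib.mask_interruption(z, block_length=2, target_fraction=0.30, seed=2)
masked, truth = ib.apply_mask(z, mask)

for method in ("mean", "locf", "linear"):
    imputed = ib.get_imputer(method).fit(masked).impute(masked)
    pairs = ib.collect_pairs(truth, imputed)
    mae, rmse = ib.masked_error(pairs["true"], pairs["imputed"])
    print(f"{method:>6}: MAE {mae:.3f}  RMSE {rmse:.3f}   (standardized)")
```

Output:

```
overall missing: 3.71%
single-variable 1 h segments: 52.0%
all-four-variable segments:   15.3%
  mean: MAE 0.664  RMSE 0.875   (standardized)
  locf: MAE 0.449  RMSE 0.616   (standardized)
linear: MAE 0.331  RMSE 0.452   (standardized)
```

The profiler recovers the generator's calibration (≈3.8% overall missing,
≈53% single-variable 1 h segments, ≈16% all-four segments), and under 2-hour
interruption blocks the error ordering mean > LOCF > linear reflects the
strong short-lag continuity of monitored vitals: methods that ignore
temporal structure pay for it.

The full pipeline (generate → preprocess → split → fit on MCAR-masked train
data → mask × scenarios × seeds → impute → score → report) runs through
`run_benchmark`:

```python
out = ib.run_benchmark(ib.RunConfig(n_stays=500, seeds=(0, 1, 2), out_dir="run"))
```

or from the shell: `icubench run-all --n-stays 500 --seed 0 --seed 1 --out run`.
Other subcommands: `simulate`, `profile`, `mask`, `impute`, `evaluate`.

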