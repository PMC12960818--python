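# Methods

This note documents the models, conventions and design choices behind
`icubench`: what the synthetic cohorts emulate, how the missingness
mechanisms are defined, what each imputer and metric computes, and where the
design was genuinely open.

## Synthetic vital-sign cohorts

Each stay is a 48 × 4 hourly panel (hours 0–47 from ICU admission; HR in
bpm, SpO₂ in %, RR in /min, MBP in mmHg).

**Latent process.** Per variable, a stationary first-order autoregressive
Gaussian process with unit marginal variance:

    z_t = φ z_{t−1} + √(1−φ²) ε_t,   z_0 ~ N(0, 1),

with innovations ε_t correlated across the four variables at a common
coefficient ρ (default 0.15). The lag-k within-feature autocorrelation of
the latent process is exactly φᵏ. Defaults: φ = 0.94 (HR), 0.88 (SpO₂),
0.88 (MBP), 0.80 (RR). HR is deliberately the most persistent signal
(pooled autocorrelation ≥ 0.8 through lag 3: 0.94³ ≈ 0.83) and RR the least
predictable; cross-feature correlations stay ≤ 0.2, reflecting the weak
instantaneous redundancy between monitored vitals.

**Marginal transforms.** Approximately normal variables (HR, RR, MBP) map
affinely: x = μ + σz. SpO₂ is right-skewed against its 100% ceiling and
maps as x = 100 − exp(m − s·z), i.e. the deficit (100 − SpO₂) is lognormal
with (m, s) moment-matched to deficit mean 3.1 and SD 2.6, so the SpO₂
mean/SD targets (96.9 / 2.6) are met exactly while no value can exceed 100.
All values are clipped to hard physiological bounds (HR [31, 143],
SpO₂ [32, 100], RR [3, 37], MBP [29, 132]). The clip affects ≈0.25% of the
mass at ±3 SD, attenuating the realized SD by well under the calibration
tolerance.

Monotone transforms and clipping slightly attenuate Pearson
autocorrelations relative to φᵏ; the HR settings keep the pooled lag-3
value above 0.8 with margin.

**Randomness contract.** One root seed; each stay draws an independent
substream keyed by (stream tag, stay index) via `numpy` `SeedSequence`
spawn keys. Generating a larger cohort therefore never perturbs earlier
stays, and generation, overlay, sub-hourly emission and masking never share
streams even under equal root seeds.

## Native-missingness overlay

Native gaps are generated as a marked point process per stay:

- event count ~ Poisson(λ), default λ = 3.8 events/stay;
- event archetype ~ categorical over {single-variable 1/2/3/4 h,
  all-four-variable block (default length 1 h), two-variable 1 h} with
  default weights 0.53 / 0.18 / 0.07 / 0.03 / 0.16 / 0.03 — the two-variable
  archetype carries the residual 3% mass so the weights form a distribution;
- start hour ~ hazard-ramped distribution: relative intensity 2× for hours
  ≥ 30 (gaps accumulate late in the window); the ramp is configurable
  because only the qualitative shape of the late-stay accumulation is
  known;
- affected variables drawn uniformly for the 1- and 2-variable archetypes.

**Rate calibration.** λ is solved in closed form so that the expected
missing-cell fraction, Σ(weight × variables × length) × λ / 192, equals the
3.8% target.

**Hard-core placement.** An event may only start where every variable is
still fully observed over the block plus a one-hour buffer on each side.
Without this, independently placed events merge: adjacent same-variable
events fuse into longer runs and coincident cross-variable events change a
segment's variable count, which biases the recovered segment taxonomy by
several percentage points (measured at 2000 stays: single-variable-1 h
share 48.4% instead of ≈53%, all-four share 13.0% instead of ≈16%). With
hard-core placement the run-level taxonomy equals the event mixture up to
multinomial noise, and the closed-form rate calibration is exact rather
than overlap-biased. If a stay is so gappy that no clean start exists
(possible only at user-set extreme rates), the event falls back to the
plain hazard draw and overlapping events merge.

**What the generator does not emulate:** physiologic state dynamics
(sepsis, interventions, circadian structure), demographic covariates,
waveform-resolution signals, measurement-modality mixtures, and any
dependence of missingness on the values themselves (the native mechanism is
ignorable by construction). Passing calibration tests therefore shows that
the pipeline recovers what it is calibrated to — not that conclusions
transfer to any particular clinical dataset.

## Gap-run bookkeeping

A gap run is a maximal contiguous missing segment. Per-variable maximal
runs within a stay that share an identical (start, length) extent merge
into a single multi-variable run; partial overlaps stay separate
per-variable runs. This makes an all-four monitoring dropout one segment,
keeps two-variable events identifiable, and partitions every missing cell
into exactly one run. Histograms are stratified by (length, number of
variables involved).

Undefined correlations (a variable never or always missing, or fewer than
two valid pairs) are reported as NaN sentinels, never as 0: fabricating
independence would corrupt downstream interpretation.

Lagged correlations pool within-stay pairs across stays and never straddle
stay boundaries; by this pooled-pairs construction the within-feature lag-0
entry is identically 1. (Estimators that report within-feature lag-0 values
below 1 — e.g. 0.90 for HR in some published profiling — must be computed
differently, e.g. per-stay with averaging; the pooled-pairs definition is
used here because it is explicit and reproducible.)

## Preprocessing conventions

- Hour bins are half-open [t, t+1) from admission, 0-based; the per-bin
  value is the median (even counts: mean of the middle two); empty bins are
  missing; records at or beyond the window are discarded.
- The ±3 SD filter uses train-split mean/SD, treats the interval as closed
  (a value exactly at mean ± 3 SD is retained), and sets offending cells to
  missing rather than clipping. It is applied after hourly aggregation.
- Plausibility floors/ceilings: rates and pressures strictly positive;
  SpO₂ ≤ 100%. Configurable per variable.
- Stay exclusion: a stay is dropped iff the number of hours at which at
  least one variable is missing exceeds 16 (strictly); 16/48 ≈ 33% of the
  window. Counting hours (not cells) matches that interpretation of the
  threshold.
- Standardization: per-variable sample mean/SD (n−1 denominator) over the
  training split's observed cells only; zero-variance or near-empty
  variables raise. Back-transformation is exact, so physical-unit errors
  are the standardized errors scaled by the variable's training SD.
- Splits are stay-level (never cell-level), sized by cumulative rounding of
  the fractions, deterministic given the seed. Default 60/20/20; the
  validation split exists for protocol fidelity (hyperparameter tuning of
  plug-in deep models) and is unused by the in-package imputers.

## Masking scenarios

All scenarios only hide observed cells — a natively missing cell has no
ground truth and cannot be scored — and capture the hidden true values at
application time.

- **MCAR**: exactly ⌊0.30 × n_observed⌋ cells, uniform without replacement.
- **Temporal interruption**: all-four-variable blocks of 1, 2, 3 or mixed
  1–3 h. Per stay the block budget is solved from the 30% target
  (⌊0.30 × n_obs / (4·E[L])⌉ blocks).
- **Sensor failure**: single-variable 4-h windows; the default budget of 4
  runs per stay removes ≈30% of the *target variable's* window (30% of all
  cells is unattainable within one variable).

Blocks are placed by direct enumeration of feasible starts (fully observed
over the block, neither overlapping nor abutting an already placed block —
the one-hour separation keeps each placed run at its exact configured
length), drawn uniformly. Enumeration replaces bounded rejection sampling:
it is exact, terminates by construction and leaves the distribution over
feasible placements uniform. A stay whose feasible starts run out gets as
many blocks as fit, with a logged warning.

The 30% removal target applies per scenario (scenarios are independent
draws, not a joint budget).

## Imputers

All imputers operate in standardized space and obey one contract: `fit`
on a training cohort (by benchmark protocol, with a 30% MCAR mask applied),
`impute` returns a complete cohort with observed cells untouched. The
contract is re-checked on every output.

- **mean / median**: per stay-variable central value of observed hours;
  stay-variables with no observations fall back to the training-cohort
  statistic.
- **LOCF**: nearest earlier observation; leading gaps backfill from the
  first observed value (default; configurable), since 48-h windows
  frequently begin inside a gap.
- **linear**: straight-line interpolation on the hour grid between nearest
  anchors; edge gaps extend the nearest anchor (constant). Exact on
  affine-in-time series for interior gaps; LOCF is exact on constant
  series.
- **mice / missforest**: chained equations on the flat representation (one
  row per stay, 192 columns). Initial fill = column means; columns visited
  in order of increasing training missingness; each column regressed on all
  others over rows where it is observed; sweeps stop when the mean absolute
  change of imputed entries falls below 1e-3 or at the sweep cap (5 for
  the linear variant, 2 for the forest variant, which converges almost
  immediately and dominates compute). The entire per-sweep sequence of
  fitted column regressors is stored and replayed in order at impute time;
  replaying only the final-sweep models lets the chained feedback loop
  amplify when large correlated blocks are jointly missing (observed as
  divergent reconstructions under sensor-failure masking), while sequence
  replay reproduces the stable training trajectory and is deterministic
  given the fitted state. The linear variant uses an evidence-tuned
  Bayesian ridge regressor because the 192-column design is strongly
  collinear and a fixed weak penalty leaves the coefficients dominated by
  noise (an explicit `ridge_alpha` pins the penalty instead when wanted);
  the forest variant uses modest trees
  (10 trees, feature subsampling 0.2, depth ≤ 12) — a desk-scale setting
  chosen so the full benchmark stays tractable on one CPU; accuracy
  conclusions for the forest variant are therefore conservative. Columns
  observed nowhere are mean-filled and excluded as predictors.
- **Deep adapters**: external models (e.g. the PyPOTS implementations of
  SAITS/BRITS/US-GAN/GP-VAE) register through `register_deep_adapter`,
  which wraps any handle exposing fit/impute on (stays × hours × variables)
  tensors and enforces the contract on every output. Both native and
  artificial missingness reach the model as NaN; how the model's training
  loss weights them is the model's own convention. The package does not
  re-implement these architectures.

## Evaluation

Masked-entry MAE and RMSE, computed only over the masked pair set (the
pair set is keyed by the mask, so unmasked cells cannot enter). Seed
aggregation reports elementwise mean and sample SD (n−1); a single seed
reports SD = 0. Bland–Altman statistics use differences oriented
imputed − true, with 95% limits of agreement at bias ± 1.96 × SD. MBP
strata are defined on the true value: < 65 mmHg, [65, 100] (boundaries to
the middle stratum), > 100 mmHg; empty strata report n = 0 with NaN errors.

## Benchmark orchestration and problem sizes

`run_benchmark` wires the stages end to end with full determinism: each run
seed governs both mask construction and imputer stochastic components;
training MCAR masks are redrawn per seed; imputers are fitted once per seed
and reused across scenarios; no stage reads test-split values during
fitting. The manifest (config, config hash, package version, split sizes,
filter counts, runtime) suffices to reproduce a run bit-for-bit.

Default problem sizes were chosen as desk-scale stand-ins for a
database-scale study: 2000 synthetic stays for profiling calibration (gap
statistics stabilize to within ±1–2 percentage points), 500 stays for
dependence checks, and 5 seeds for aggregation. The test suite uses smaller
cohorts (40–300 stays) with the same structure.

## Known limitations

- The hazard ramp and the all-four block-length distribution are
  qualitative approximations; neither is fit to a tabulated curve.
- Native gap generation is ignorable (independent of values); informative
  (MNAR) mechanisms are out of scope.
- Single-variable native gaps are capped at 4 h by default; longer native
  outages only appear through user configuration.
- The archetype's variable choice is uniform across the four vitals, so
  per-variable native missing rates are equal in expectation, unlike real
  cohorts where e.g. blood-pressure gaps are more common.
- Forest-variant defaults trade accuracy for tractability (see above).
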