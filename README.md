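# migstops

Hourly-scale stopover detection for migratory GPS tracks, with event-aligned
weather-change analysis and mixed models — plus a synthetic track+weather
generator with known ground truth so the whole pipeline is testable offline.

## What it does

1. **Track model & I/O** (`track_model`): Movebank-dialect CSV reader (one
   `Track` per individual, extra numeric columns kept as per-fix weather
   covariates), a migration table, and a regular-sampling filter (mean fix
   interval < 3 h).
2. **Regularization** (`regularize`): linear interpolation to exact
   top-of-hour fixes (longitude unwrapped across the antimeridian), per-step
   haversine speeds, gap splitting.
3. **First passage time** (`fpt_core`): symmetric FPT (backward entry to
   forward exit of a circle centred on each fix) with crossing instants
   solved on the interpolated path, and radius selection by maximum
   variance of log FPT over a 2500–6000 m sweep.
4. **Solar clock** (`solar_clock`): self-contained NOAA solar position —
   sunrise/sunset (zenith 90.833°), daylight flags, and the 17:00–08:00
   local-solar roosting window.
5. **Stopover segmentation** (`stopover_segmentation`): per-migration
   log-FPT threshold (mean + c·sd), candidate runs, 95th-percentile
   endpoint trimming, the 08:00 roost-start rule, duration (≥ 2 h) and
   daylight (≥ 25 %) rejection filters, buffer rescue of slow stopovers
   (> 30 fixes within a 15 km running-centroid buffer), and merging.
6. **Activity metrics** (`activity_metrics`): proportion of non-roost hours
   with speed > 1 km/h, total distance, and exclusion of the most active
   third of stopovers.
7. **Event-aligned weather** (`event_aligned_weather`): hourly change of
   each weather variable in ±7 h windows around stopover starts/ends,
   two-stage (stopover→individual) averaging with 95 % CIs, loess
   smoothing, and peak-lag extraction.
8. **Inferential models** (`inferential_models`): greedy correlation
   pruning of predictors (|r| > 0.6), a Gaussian LMM for stopover counts
   per migration (statsmodels MixedLM), and a binomial GLMM for activity
   with random intercepts for population and individual-within-population —
   fit by an own Laplace/PIRLS implementation (`glmm`) that matches
   R lme4's `glmer` to ~3 decimals on shared fixtures.
9. **Synthetic data** (`synthetic_data`): correlated-walk migrations with
   diurnal roosting, precipitation-front events (2 h–11 d) that ground the
   simulated birds, optional slow foraging bouts, coupled weather series,
   and per-event ground truth for recovery scoring (`evaluation`).

## CLI

```bash
migstops simulate --seed 1 --out out/          # synthetic dataset + truth
migstops detect   --seed 1 --out out/          # stopovers.csv + report.json
migstops activity --seed 1 --out out/          # activity metrics + exclusion
migstops align    --seed 1 --out out/          # aligned curves + peak lags
migstops models   --seed 1 --out out/          # LMM + GLMM coefficient CSVs
migstops all      --seed 1 --out out/          # everything
```

All commands accept `--config config.yaml` (sections `simulation`,
`segmentation`, `analysis`; flat keys per section — see
`migstops/config.py` for the schema) plus flag overrides such as
`--radius-min/--radius-max/--radius-step`, `--threshold-c` and `--span`.
Runs are deterministic under a fixed seed; `report.json` records counts at
every filtering stage (candidates, rejected by duration/daylight,
buffer-rescued, merges, exclusions) so the bookkeeping is auditable.

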