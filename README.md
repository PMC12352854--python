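# pm-gapfill

Gap filling, quality control and exceedance assessment for hourly PM2.5
exposure time series.

The package implements a complete workflow for sensor-derived particulate
data:

* **`pm_gapfill.preprocessing`** — minute-level QC: spike and IQR outlier
  flagging (values become NaN, never deleted), timeline regularization,
  delayed-timestamp correction, short-gap linear interpolation, hourly
  aggregation with a minimum-coverage rule, and a secondary hourly outlier
  filter.
* **`pm_gapfill.gaps`** — detection and description of contiguous missing
  runs (start, length, available context on each side).
* **`pm_gapfill.baselines`** — global/local mean and median fills, linear /
  cubic-polynomial / B-spline window interpolation, and AR(1) forecast
  extrapolation.
* **`pm_gapfill.windowed`** — fixed-context supervised imputers:
  autoregressive (recursive one-step) and sequence-to-sequence framings,
  unidirectional and bidirectional, univariate and multivariate, over
  pluggable regression backends (`rf` = random forest, `gbrt` =
  histogram gradient boosting). Bidirectional predictions are fused with
  linearly decaying distance weights.
* **`pm_gapfill.dynamic`** — a single model for gaps of arbitrary length:
  gap-length-dependent context sizing (3× rule capped at 32), position-aware
  zero padding, gap metadata features, unified multi-length training, and
  chunked filling (72-step chunks plus remainder) for over-length gaps.
  Negative predictions are clipped to zero.
* **`pm_gapfill.evaluation`** — synthetic-gap benchmarking harness:
  identical injected gap patterns for all methods within a run, MAE / RMSE /
  MAPE / R² on the raw scale, mean ± SD aggregation over seeded runs, and a
  paired t-test for method comparison.
* **`pm_gapfill.assessment`** — WHO-threshold exceedance banding (15 µg/m³,
  bands at 1–2×, 2–4×, 4–8×, >8×), piecewise-linear AQI with a configurable
  breakpoint table (US EPA PM2.5 defaults), and descriptive statistics by
  month or season.
* **`pm_gapfill.synthetic`** — a deterministic generator of PM2.5-like
  hourly series (bimodal diurnal cycle, winter-elevated seasonality, AR(1)
  log-scale noise, negatively coupled wind speed) plus controlled
  missingness injection, so the whole stack is testable offline.

## Command line

```sh
pm-gapfill simulate   --hours 8760 --seed 1 --out series.csv
pm-gapfill preprocess --in raw.sqlite --out hourly.csv
pm-gapfill gaps       --in hourly.csv --out gaps.csv
pm-gapfill fill       --method dynamic-multi --in hourly.csv --out filled.csv --report report.json
pm-gapfill benchmark  --in hourly.csv --out results/ --methods global-mean,local-mean,gbrt-seq2seq-bi --gap-lengths 5,12 --runs 5
pm-gapfill assess     --in filled.csv --out assessment/
```

Hourly series travel as CSV with an ISO-8601 `timestamp` column; missing
values are empty fields.

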