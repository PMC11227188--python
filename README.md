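# dendrokit

Tree-ring chronology construction, climate–growth correlation and drought
resilience analysis, with a synthetic-forest generator so the whole pipeline is
testable without any external data.

## What it does

- **`dendrokit.rwl`** — Tucson decadal `.rwl` ring-width I/O (both the 0.01 mm /
  `999` and 0.001 mm / `-9999` terminator dialects), monthly climate CSV tables
  (`year,jan..dec`) and chronology CSV export.
- **`dendrokit.detrend`** — standardization with a cubic smoothing spline
  parameterized by its frequency response (default: 50% amplitude at a 30-year
  wavelength), optional AR prewhitening (AIC order selection), Tukey biweight
  robust-mean site chronologies, and the quality statistics MS (mean
  sensitivity), Rbar (mean interseries correlation) and EPS (expressed
  population signal).
- **`dendrokit.climate`** — Pearson correlations of a chronology against monthly
  climate over a previous-June → current-September window (16 months), with
  case-bootstrap percentile confidence intervals.
- **`dendrokit.resilience`** — per-tree, per-year resistance / recovery /
  resilience ratios, per-event decline statistics
  (`DecU = (Pre5 − Min) / Dt`) with latest-minimum decline-phase detection,
  low-growth-period detection on chronologies, and Gaussian-KDE/skewness
  summaries of indicator distributions. A built-in calendar of severe historical
  drought events (1750–2022) is the default.
- **`dendrokit.simulate`** — synthetic forests with known ground truth: a
  negative-exponential age curve, lognormal AR(1) noise, a shared
  growing-season climate signal, and calendar-driven drought reductions with a
  configurable recovery lag. Used by the test suite for parameter recovery.
- **`dendrokit.pipeline` / `dendrokit.cli`** — one-config orchestration of
  simulate → detrend → stats → climate correlation → resilience.

## CLI

```sh
# generate a synthetic forest: lw.rwl, six climate CSVs, truth.json
dendrokit simulate --out-dir data/ --seed 42

# detrend and build the site chronology
dendrokit detrend --rwl data/lw.rwl --out chron.csv

# chronology quality statistics
dendrokit stats --rwl data/lw.rwl

# bootstrap climate-growth correlations (16-month dendro window)
dendrokit climcorr --chron chron.csv --climate data/prec.csv --var Prec \
    --nboot 1000 --seed 42 --out resp.csv

# per-tree resilience records and decline statistics
dendrokit resilience --rwl data/lw.rwl --events default \
    --out records.csv --declines-out declines.csv

# everything from one YAML config
dendrokit run-all --config run.yaml
```

A minimal `run.yaml`:

```yaml
seed: 42
output_dir: out
simulate:           # or use paths: {rwl: ..., climate_dir: ...}
  n_trees: 15
  year_range: [1700, 2022]
detrend:
  spline_wavelength: 30
  cutoff_response: 0.5
  prewhiten: true
resilience:
  pre_window: 2
  post_window: 2
  flank: 5
bootstrap:
  n_boot: 1000
  alpha: 0.05
```

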