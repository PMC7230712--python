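# chrononut

Chrononutrition analytics for rotating-shift work schedules. The package
turns timestamped meal, work and sleep logs into per-day dietary metrics
and day-type statistics:

* **intake events** — meal records of the same type logged within 15 min
  are merged into single intake events (timestamp of the last record,
  summed calories and macronutrients);
* **day windows** — analysis days run wake-to-wake: from the wake of the
  main sleep (the longest sleep of a calendar day) preceding a shift/rest
  day to the wake of the following main sleep. Shifts are classified as
  morning / evening / night by their timing, and atypical durations
  (>13.5 h or <4.5 h) are excluded;
* **metrics** — Mifflin–St Jeor BMR, day-length-weighted %BMR totals and
  macro components, first-meal latency and last-meal-to-sleep (nap-adjusted
  time awake), eating window, kcal-weighted circular mean intake time /
  resultant length / circular SD, night (2300–0600) and at-work caloric
  fractions, 4-h clock-time and time-awake caloric bins;
* **statistics** — goodness-of-fit chi-square with arbitrary expected
  weights, Welch's t from group summaries, the Watson–Williams circular
  ANOVA, REML mixed-effects day-type models (sex and age covariates,
  subject random intercept, pairwise contrasts), and Benjamini–Hochberg
  adjustment per table family;
* **synthetic data** — a generator producing full shift-worker datasets
  (35-day and 28-day rosters, day-type-conditional sleep anchors, von
  Mises mixture meal timing, lognormal calories, Dirichlet macros) with
  ground truth, so the whole pipeline is testable without external data.

## Command line

```bash
# generate a synthetic dataset (meals/work/sleep/subjects/ground-truth CSVs)
chrononut simulate --subjects 31 --seed 1 --out data/

# run the full pipeline; simulates inputs by default, or point a YAML
# config at existing CSVs
chrononut run --seed 1 --out results/run1
chrononut run --config config.yaml --out results/run2

# re-print the human-readable summary of a finished run
chrononut report --out results/run1
```

A YAML config may set `meals_path / work_path / sleep_path /
subjects_path` for real inputs, or a `simulate:` block with generator
settings, plus analysis knobs (`min_kcal`, `min_events`, `night_window`,
`alpha`, `seed`).

The report bundle contains intermediate CSVs (`intake_events.csv`,
`day_windows.csv`, `day_metrics.csv`), statistics (`stats_results.csv`,
`contrasts.csv`), summary tables (subjects, per-day-type %BMR intake,
distribution percentages overall/at-night/at-work, timing, circular
means), an exclusion log accounting for every input meal record, and a
`run_log.json` with config, seed, versions and stage row counts.

## Python API

```python
from chrononut import synth, pipeline

cfg = pipeline.PipelineConfig(simulate=synth.default_config(n_subjects=31, seed=1))
result = pipeline.run_pipeline(cfg, "results/run1")
result.day_metrics.groupby("day_type")["total_pct_bmr"].mean()
```

Individual stages are importable from `chrononut.schedule`,
`chrononut.intake`, `chrononut.metrics` and `chrononut.stats`.

## Conventions and limitations

* Timestamps are timezone-naive local clock times; DST transitions are
  out of scope.
* Night/bin intervals are half-open `[a, b)`; work-interval membership is
  closed; the `>5 kcal` threshold for timing metrics is strict.
* Epoch-level sleep scoring from actigraphy is out of scope — the
  pipeline consumes resolved sleep intervals.
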