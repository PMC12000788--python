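# shiftsleep

A tested pipeline for analyzing physician-assisted sleep advice for hospital
shift workers. It simulates a shift-worker cohort with wearable + survey
structure, engineers daily physiological/behavioral features, characterizes
behavior clusters, and trains, evaluates, and explains per-message
advice-prediction models.

Because no real cohort data are distributed, the package ships a first-class
synthetic cohort generator whose defaults are calibrated to published
population statistics (mean daily sleep duration, step counts, heart rate,
7-day sleep regularity, advice-selection frequencies and response behavior).
Every downstream stage is testable against it.

## Package layout

| Module | Role |
| --- | --- |
| `shiftsleep.synthetic_cohort` | Cohort generator: Markov shift roster with rotation bias, shift-conditioned sleep, surveys, minute heart-rate/steps, threshold-rule advice policy with per-message responses. |
| `shiftsleep.sequences` | 1-min sleep/nap grids, 30-min work grids, sleep regularity index (trailing 3/5/7-day windows), work-hour features, sleep–work overlaps and gaps. |
| `shiftsleep.features` | Daily feature inventory (heart-rate stats + sample entropy, step segment-duration entropies, sleep, survey, work, well-being) and 4-day-window advice samples with 23 response features and per-message labels. |
| `shiftsleep.advice` | 23-message catalog, six categories, selection/category/response statistics of advice logs. |
| `shiftsleep.clustering` | Ward-linkage clustering of standardized daily features, threshold cuts, PCA(95%)+t-SNE embedding, cluster profiles. |
| `shiftsleep.advice_models` | User-dependent/independent 70/30 splits, random oversampling + SMOTE, three tree-ensemble families, random-search tuning with stratified (participant-grouped) CV. |
| `shiftsleep.evaluation` | Step-wise average-precision AUPRC, uniform-random baselines, one-sided Welch tests, CV F1-threshold optimization, 9-voter majority ensembles. |
| `shiftsleep.importance` | Permutation importance (AUPRC decrease) and permutation-sampling Shapley attributions with exact per-sample additivity; joint top-5 reports with 0.01 floors. |
| `shiftsleep.cli_io` | CSV schemas + validation, pipeline configuration, end-to-end orchestration. |

## Data model

Six plain-CSV tables (ISO dates/timestamps, timezone-naive local time):

- `participants.csv` — id, hospital, enroll_order, start_date, study_days
- `minutes.csv` — participant, timestamp, heart_rate, steps (minute resolution)
- `sleep_periods.csv` — participant, start, end, duration_min, efficiency
- `morning_survey.csv` — sleep times and naps, sleep quality Likerts (1–5),
  behaviors (caffeine/alcohol/bath/phone/brightness), morning well-being
  (1–100 scales, sleepiness 1–9)
- `evening_survey.csv` — 48-bin work bitstrings for today/yesterday/day-before,
  extra-work indicator, evening well-being
- `advice.csv` — participant, date, pipe-delimited message ids (1–5 of 23),
  response ∈ {none, eager, difficult}

`features.daily_features` documents the full daily column inventory in
`shiftsleep.features.ALL_DAILY_FEATURES` (with `MODEL_FEATURES` and
`CLUSTER_FEATURES` subsets).

## CLI

```bash
shiftsleep simulate --seed 0 --out out/              # write synthetic tables
shiftsleep features --input-dir out/tables --out out # daily features + samples
shiftsleep cluster --daily out/daily_features.csv --out out
shiftsleep run-all --seed 0 --out out                # full pipeline
shiftsleep run-all --config pipeline.yaml            # YAML-configured run
```

`run-all` executes simulate → features → cluster → train → evaluate → explain
and writes `daily_features.csv`, `advice_samples.csv`, cluster artifacts
(labels/profiles/embedding/dendrogram), `evaluation_report.csv` (per message ×
family × balancing AUPRC with Welch comparison against random guessing),
`ensemble_report.csv` (thresholded 9-voter sensitivity/specificity/precision/
F1 vs the always-positive baseline), and `importance_report.csv`. Every
artifact directory carries a `manifest.json` with the config hash and seed.

Note: the full default protocol (7 messages × 9 configurations × 10 seeds ×
100 random-search iterations, both split modes) is compute-heavy; trim
`seeds`, `n_search`, `messages`, or `split_modes` in the config for desk-scale
runs (the test suite does exactly that).

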