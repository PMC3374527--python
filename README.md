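# activeq

Scoring and validation pipeline for a MET-based physical-activity
questionnaire, with a doubly-labeled-water (DLW) reference method and the
agreement statistics used in method-validation studies.

The package provides:

- **activity_catalog** — the built-in MET compendium (34 activities across
  transportation, leisure and sport, plus a 5-rank occupation effort scale),
  shipped as a swappable YAML data file.
- **questionnaire** — data model for responses (categorical
  frequency/duration answers, one free-entry occupation-hours answer),
  category-midpoint maps, response validity flags, and the study exclusion
  filter.
- **scoring** — energy expenditure per activity
  (`MET x weight x hours/day x 4.184` kJ/day), per-domain and crude totals,
  and the 24-hour adjustment (8 h sleep plus a signed MET-2.0 filler).
- **dlw_kinetics** — reference total energy expenditure from urine isotope
  enrichment series: log-linear elimination fits over the day-1–3 and
  day-8–10 windows, dilution spaces from dose and intercept, two-pool
  CO₂ production, and a Weir-type energy conversion (RQ 0.85). All
  equation constants are configurable.
- **agreement_stats** — Spearman correlation (midranks), Bland-Altman
  agreement (limits at ±2 SD of the differences), and the one-way ANOVA
  intraclass correlation with F-bound confidence interval, all implemented
  from first principles and cross-checked against brute-force oracles.
- **synthetic_cohort** — a generator that inverse-scores questionnaire
  answers from a known per-participant true energy expenditure and inverts
  the isotope kinetics, so the full pipeline can be exercised and validated
  end-to-end with a known ground truth.
- **pipeline_cli** — the `activeq` command line and `run_study`
  orchestration producing the full validity/reproducibility report.

## CLI

```sh
activeq simulate --seed 1 --n 37 --out-dir data/        # synthetic inputs
activeq score --responses data/responses.csv --profiles data/profiles.csv --out scored.csv
activeq dlw --series data/enrichment.csv --out dlw.csv
activeq agreement --a scored_i.csv --b dlw.csv --out agreement.csv \
    --bland-altman-out ba.csv
activeq run --profiles data/profiles.csv --responses data/responses.csv \
    --enrichment data/enrichment.csv --out-dir study/
```

Every subcommand accepts `--config <file>`, a YAML file overriding any part
of the default configuration (category midpoints, sleep MET, DLW constants,
ICC model, cohort generator spec); see
`src/activeq/data/default_config.yaml` for the full schema and defaults.

## Notes on conventions

- Category answer sets are configurable: the questionnaire's predefined
  frequency/duration options are not fixed by the method, so the defaults
  (a 0.25 h duration grid and weekly frequency midpoints) live in the config
  file, and `resolve_daily_hours` = frequency midpoint × duration midpoint / 7.
- The sleep MET defaults to 0.9 (compendium sleeping value) and is
  configurable; limits of agreement use the factor 2 (not 1.96); the ICC is
  the one-way random-effects ANOVA estimator by default with a two-way
  variant behind a config flag.
- The DLW two-pool constants (1.007/1.041 fractionation adjustments, 2.078
  divisor, 0.0246 × 1.05 fractionated-loss correction, Weir coefficients
  3.941/1.106) are documented defaults, not claims — override them in the
  config if your laboratory used a different equation dialect.
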