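# cohortval

Statistics toolkit for validating virtual (synthetic) patient cohorts
against real cohorts and for analysing validated cohorts in simple
in-silico trial designs.

Four validation views compare a real/virtual CSV pair with identical
variable structure:

- **univariate** — mean, standard deviation, minimum, maximum per cohort;
  Tukey boxplot statistics; scatter point sets for variable pairs;
- **bivariate** — Spearman rank-correlation matrices per cohort and their
  difference, rendered as heatmaps;
- **multivariate** — per-record standardized quadratic forms
  `d_i = (x_i − x̄)ᵀ S⁻¹ (x_i − x̄)` against each cohort's own sample mean
  and covariance (divisor n−1, so `Σd = p(n−1)` exactly), with a QQ pairing
  between the cohorts and a chi-squared reference (df = p−1 by default,
  df = p in `classical` mode);
- **variability** — bootstrap resamples of the virtual cohort produce a
  pointwise confidence band on Gaussian-kernel density estimates; the
  fraction of grid points where the real-data density leaves the band is
  reported as the out-of-band statistic, and a deviation is flagged above a
  configurable threshold.

Trial-application analyses cover one-group and two-group designs:
frequencies plus chi-square tests for discrete variables, summaries,
boxplots and Welch/pooled t-tests for continuous variables, Kaplan–Meier
product-limit curves and the two-group log-rank test for censored
time-to-event variables. Sample-size planning for a two-group continuous
comparison with common standard deviation uses the normal-approximation
closed form and propagates effect-size uncertainty through scenario
simulation (required-size summary plus power-shortfall probabilities).

A synthetic fixture generator draws paired real/virtual cohorts from a
known model (multivariate-normal continuous block, categorical variables,
censored-exponential time-to-event) with optional mean-shift/covariance
perturbations, so every analysis is testable without external data.

## Command line

```sh
# generate a paired fixture (CSV pair + YAML sidecar with kinds and seed)
cohortval generate-fixtures --out-dir fixtures --n-real 200 --n-virtual 200 --seed 1

# validation views (CoU/QoI text is required; --no-context to skip)
cohortval validate-univariate   --real fixtures/real.csv --virtual fixtures/virtual.csv \
    --config fixtures/fixtures.yaml --cou "..." --qoi "..." --out report.json
cohortval validate-bivariate    ... --out corr.json --figures-dir figs
cohortval validate-multivariate ... --df-mode paper --out mv.json
cohortval validate-variability  ... --variables x1 --replicates 500 --seed 1 --out band.json

# trial application (analysis chosen by the variable's declared kind)
cohortval apply-one-group --data fixtures/real.csv --variable x1 \
    --config fixtures/fixtures.yaml --no-context --out one.json
cohortval apply-two-group --data-a a.csv --data-b b.csv --variable time \
    --config fixtures/fixtures.yaml --no-context --out two.json

# sample size with effect-size uncertainty scenarios
cohortval sample-size --mean1 0 --mean2 0.5 --sd 1 --alpha 0.05 --power 0.8 \
    --lower 0.5 --upper 1 --n-scenarios 100 --seed 1 --out ss.json
```

Reports render to JSON (canonical: sorted keys, timestamp omitted, so
identical seeds give identical bytes), Markdown or HTML via `--format`;
figures (PNG) are written when `--figures-dir` is given. Cohort CSVs use a
comma separator, UTF-8, a mandatory header row, and `""`/`NA` for missing
cells; variable kinds (`continuous`, `discrete`, `time_to_event`) and
time/event-indicator pairings are declared in the YAML config.

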