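# loudadapt

Simulation and analysis pipeline for 2AFC loudness-discrimination
experiments with a central-tendency (regression-to-the-mean) observer.

The package covers the full chain needed to study how loudness judgements
regress toward an internal anchor:

- **`loudadapt.design`** — seeded trial schedules: block-wise method of
  constant stimuli (5 probe levels 40–80 dB, 7 comparison levels at a
  2 dB step, 10 repetitions → 350 trials), cued variants (continuous
  bar cue, flashed fixation cue), and biased-context sessions (two
  70-trial baselines, a 70-trial adaptation block, then a 280 + 70
  majority/minority test phase at a 3 dB step).
- **`loudadapt.observer`** — a generative observer whose probe percept is
  `w · stimulus + (1 − w) · anchor`, with an exponential-moving-average
  anchor, Gaussian sensory noise and a lapse rate. Closed-form response
  probabilities, session simulation, and truncated-normal cohort
  sampling.
- **`loudadapt.psychometrics`** — per-subject response aggregation,
  cumulative-Gaussian fits (least squares on proportions by default,
  Bernoulli ML optional), PSE extraction, and the catch-trial exclusion
  rule (error rate > 25 % at the extreme comparison levels).
- **`loudadapt.regression_analysis`** — PSE deviations, the adaptation
  index (OLS slope of deviation vs probe level; equals `−(1 − w)` for a
  fixed anchor), the first/second-half ordering contrast, and the
  majority/minority context-effect table.
- **`loudadapt.inference`** — mixed within-between ANOVA (classical and
  partial η², optional Greenhouse–Geisser), one-way ANOVA, pooled
  two-sample t with Cohen's d, and the two-sample JZS Bayes factor
  (Cauchy(0, r = 0.707) effect-size prior) by adaptive quadrature.
- **`loudadapt.pipeline_cli`** — trial/fits/summaries CSV formats, YAML
  run configuration, one-command synthetic replications, a
  parameter-recovery harness, and the `loudadapt` CLI.

## CLI

```sh
# simulate two baseline subjects and fit their psychometric functions
loudadapt simulate --experiment 1 --group baseline --subjects 2 --seed 3 --out trials.csv
loudadapt fit --trials trials.csv --out fits.csv
loudadapt analyze --fits fits.csv --out stats.json

# full synthetic replication (trials/fits/summaries CSVs + stats JSON)
loudadapt replicate --experiment 1 --seed 1 --out runs/exp1

# parameter recovery over a grid of true prior weights
loudadapt recover --w 0.8 --w 0.9 --subjects 55 --reps 20 --seed 1 --out recovery.csv
```

`replicate` accepts `--config cfg.yaml` with keys `experiment`, `seed`,
`groups` (name → cohort size), `w_by_group`, `fit_method`, `anchor_lr`.

## Python API

```python
import loudadapt as la

design = la.make_exp1_design("active", seed=1)
params = la.observer.default_observer_params()
records = la.simulate_session(design, params, seed=2, subject="s0")
table = la.aggregate_proportions(records, "s0", probe_db=60.0)
fit = la.fit_cumulative_gaussian(table)   # fit.pse_db, fit.sigma_db
```

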