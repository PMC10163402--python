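# stepdyn

Person-specific dynamical modeling of physical-activity responses to
digital motivational messages, as a tested, reusable pipeline:

1. **`synthetic_cohort`** — generates virtual participants: minute-level
   step/heart-rate tables, message logs (0–6 messages/day from libraries of
   54 affective / 54 social-cognitive / 27 inspirational-quote messages,
   ≥15-minute spacing, ≥10-hour availability windows), with step dynamics
   driven by known ground-truth ARX coefficients (distinct weekday/weekend
   models) plus heart-rate dropout and nonwear blocks.
2. **`preprocessing`** — merges streams by timestamp, pads the availability
   window by ±2 h (clipped at midnight; days are independent), classifies a
   minute as missing iff it has zero steps and no heart-rate signal,
   linearly interpolates missing runs ≤3 minutes, excludes longer runs,
   and aggregates to quarter-hour epochs with binary message indicators.
3. **`system_identification`** — fits the order-5 ARX model (intercept,
   5 output lags, 3 input channels × lags 0–5; 24 coefficients) by least
   squares, separately for weekdays and weekends (switched structure),
   with coefficient covariance and flagged column-dropping on rank
   deficiency.
4. **`response_analysis`** — simulates impulse and cumulative step
   responses over a 600-minute horizon, attaches parametric-bootstrap 95%
   error bands, and extracts seven features: initial delay, peak magnitude,
   peak delay, steady state, rise time, settling time, effective time.
5. **`feature_statistics`** — descriptives, two-way repeated-measures
   ANOVA (message × day type) with Mauchly-gated Greenhouse–Geisser
   correction and generalized η², Friedman tests with Kendall *W* for
   non-normal features, Bonferroni pairwise post hocs, and a per-participant
   best-message-type heterogeneity summary.
6. **`pipeline`/`cli`** — a YAML-driven orchestrator with strict config
   validation, input validation, and a checksum manifest for reproducible
   reruns.

## Command-line usage

```sh
# full pipeline from a config file
stepdyn run --config cohort.yaml

# or stage by stage
stepdyn simulate  --out runs/raw --seed 1 --participants 3 --days 28
stepdyn preprocess --in runs/raw --out runs/epochs
stepdyn fit        --in runs/epochs --out runs/models
stepdyn respond    --models runs/models --out runs/responses --bootstrap 500 --seed 1
stepdyn stats      --features runs/responses/features.csv --out runs/stats
stepdyn validate   --in runs/raw
```

Example config:

```yaml
out_dir: runs/demo
seed: 1
simulate: {n_participants: 3, n_days: 28, noise_sd: 25.0}
fit: {order: 5}
respond: {bootstrap: 500, horizon: 40}
stats: {alpha: 0.05, correction: auto}
```

All artifacts are plain text: per-participant CSV minute tables
(`timestamp,steps,hr_present`), CSV message logs
(`timestamp,library,delivered`), JSON availability windows and
ground-truth coefficients, per-day epoch CSVs
(`epoch_start,y,u_affective,u_social_cognitive,u_quote,valid`),
model JSONs, a feature CSV, and stats tables.

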