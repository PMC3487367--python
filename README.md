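# scampqi

Analysis toolkit for quantifying how a standardized clinical assessment and
management plan (SCAMP) changes practice variation and resource utilization
in outpatient pediatric chest-pain evaluation.

The package provides:

- **`scampqi.cohort`** — validated encounter records (demographics, clinical
  feature flags, tests performed, provider, deviation reason) with a strict
  CSV dialect and age banding (7–11 / 12–16 / 17–21).
- **`scampqi.rules`** — the echocardiogram-indication rule (exertional pain,
  pertinent past medical/family history, abnormal exam, abnormal ECG),
  adherence accounting with 95% CIs, the appropriateness table, and the
  deviation-reason table.
- **`scampqi.variation`** — the 16-pattern testing census over
  {echo, exercise stress test, Holter, event monitor} and a seeded
  resampling test (pooled-bootstrap null, permutation variant available) for
  a change in pattern richness.
- **`scampqi.inference`** — exact two-sided Fisher test for 2×2 tables
  (integer hypergeometric enumeration), Wald binomial CIs, a Wilcoxon
  rank-sum test (exact for small untied samples), demographics and
  utilization table builders, and a charge-based cost-savings estimator.
- **`scampqi.synth`** — a fully seeded synthetic cohort generator: marginal
  feature prevalences, age-band/sex mixes, skewed provider loads, and either
  an explicit testing-pattern distribution (to plant a target richness) or a
  rule-based ordering model with a tunable adherence parameter.  The
  canonical fixture plants two cohorts (n=406 / n=364) with pattern richness
  13 vs 8.

## CLI

```sh
# write the canonical seeded two-era fixture
scampqi generate-canonical cohorts/ --seed 20120424

# generate a cohort from a YAML/JSON spec
scampqi generate spec.yaml cohort.csv

# testing-pattern census (data behind the variation figure)
scampqi census cohorts/historical.csv --out census.csv

# resampling test for the change in pattern richness
scampqi variation cohorts/historical.csv cohorts/scamp.csv --seed 1 --resamples 10000

# adherence to the echo recommendation, by indication stratum
scampqi adherence cohorts/scamp.csv

# demographics / appropriateness / deviation / utilization tables
scampqi report cohorts/historical.csv cohorts/scamp.csv --out-dir tables/
```

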