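# bpref — paediatric blood-pressure reference percentiles from office BP data

Identifying abnormal blood pressure in children requires normative data:
whether a reading is "high" depends on the child's age, sex and height.
`bpref` implements the full workflow for deriving such references from
longitudinal office BP measurements of the kind held in electronic health
records, and for comparing a newly derived reference against an established
one. It is aimed at biostatisticians and clinical-informatics researchers
who want a tested, reproducible version of this pipeline that runs end to
end on synthetic data — no patient-level data are required or included.

## The model

For each sex × BP-type stratum (systolic/diastolic), the conditional mean is
a polynomial in centred age and height Z-score,

```
μ(a, h) = β₀ + Σₖ βₖ (a − 10)ᵏ + Σₖ γₖ hᵏ ,   k = 1…4,
```

fitted as a linear mixed model by maximum likelihood. Two variance forms
are supported:

* **random intercept** — one per-child intercept b₀ᵢ; the reference SD is the
  pooled constant σ = √(σ²_int + σ²_obs), and the ICC σ²_int/(σ²_int + σ²_obs)
  measures how much variance is between children;
* **random slopes** (final form) — per-child intercept and random coefficients
  on (age − 10) and height Z with unstructured covariance Σ, giving an
  age- and height-dependent SD

```
σ(a, h) = sqrt( σ²_obs + vᵀ Σ v ),   v = (1, a − 10, h).
```

A child's BP Z-score is z = (observed − μ)/σ and the percentile is 100·Φ(z).
Around this core the package provides: a synthetic EHR-encounter generator
with the same generative structure (plus tagged contamination records), the
13-step cohort attrition cascade and measurement cleaning (same-day
averaging, ±5 Z plausibility screen), backward AIC pruning of polynomial
terms, quantile-regression centiles as a cross-check, and an agreement suite
(squared-weight Cohen's kappa over ordinal BP categories, Z-vs-Z regression,
reclassification fractions, calendar-drift and subgroup-ECDF diagnostics).

Two read-only coefficient bundles transcribed from a published EHR-derived
reference (≈292k children, ≈1.1M measurements) ship with the package:
`ehr_random_intercept` and `ehr_random_slopes`.

## Worked example

The standard scenario: a 12-year-old boy at the 90th height percentile
(height Z = 1.28) with an observed systolic BP of 120 mmHg.

```sh
$ bpref zscore --bundle ehr_random_slopes --sex M --type sbp \
      --age 12 --height-z 1.28 --bp 120
{"expected_bp": 109.31842, "sd": 9.66254, "z": 1.10546, "percentile": 86.552, "category": "normal"}
```

The model expects 109.32 mmHg for this child; the measurement SD at his age
and height is 9.66 mmHg, so 120 mmHg sits 1.11 SD above expectation — the
86.6th percentile, below the 90th-percentile "elevated" cutoff, hence
classified normal.

The same engine is available from Python:

```python
from bpref import load_bundled_model
model = load_bundled_model("ehr_random_slopes")
model.expected_bp("M", "sbp", 12, 1.28)     # 109.318...
model.conditional_sd("M", "sbp", 12, 1.28)  # 9.6625...
model.percentile("M", "sbp", 12, 1.28, 120) # 86.55...
```

## The analysis

Numbered drivers under `analysis/` run the study end to end on a synthetic
2,000-child cohort and write their tables under `results/analysis/`:

1. `01_simulate_cohort.py` — simulate encounters (27% single-encounter
   children, median age span 2.2 y, tagged contamination, 5.6% duplicated
   readings);
2. `02_build_cohort.py` — attrition cascade, mean-vs-min diagnostic,
   same-day averaging, ±5 Z plausibility screen;
3. `03_fit_models.py` — 70/30 split by child, both mixed-model forms,
   random-effect likelihood-ratio chain, coefficient recovery report;
4. `04_reference_tables.py` — worked example and full percentile tables;
5. `05_quantile_check.py` — quantile-regression centiles vs the mixed model;
6. `06_agreement.py` — kappa, Z-vs-Z regression, reclassification, drift,
   subgroup ECDFs.

The same stages are exposed as a CLI (`bpref simulate | build-cohort | fit |
tables | zscore | qreg | compare | run`); `bpref run` executes the whole
pipeline from one config with full seed logging.

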