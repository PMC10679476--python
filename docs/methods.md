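# Methods

## Scope and design

`bpref` derives age-, sex- and height-specific blood-pressure references
from longitudinal office BP measurements and compares reference models with
one another. Patient-level EHR data cannot be redistributed, so the package
is built around a synthetic-cohort generator whose generative model is
exactly the statistical model the analysis assumes; every downstream stage
(cohort cleaning, model fitting, centile construction, agreement metrics) is
exercised and tested against that known truth.

## Reference model

For each stratum (sex × systolic/diastolic) the conditional mean is an
intercept plus first- through fourth-order polynomials of centred age
(`age − 10`, years) and of height Z-score. Ages are fractional years;
height Z is an input covariate (no growth-chart computation is performed).
Models are fitted separately per stratum; sex enters by stratification, not
as a regression term.

Two variance forms:

* **Random intercept.** One Gaussian per-child intercept plus i.i.d.
  residual. Reported as a single total SD σ = √(σ²_int + σ²_obs) and the
  ICC = σ²_int/(σ²_int + σ²_obs).
* **Random slopes (final form).** Per-child random vector
  b = (b_int, b_age, b_height) ~ N(0, Σ), Σ unstructured (parameterised by
  three SDs and three correlations, Σᵢⱼ = ρᵢⱼσᵢσⱼ), plus residual σ_obs.
  The SD of a *new* measurement at covariates v = (1, age − 10, heightZ) is
  σ(age, h) = √(σ²_obs + vᵀΣv); this is the SD used for Z-scores, so the
  reference width varies with age and height. Since Σ is PSD,
  σ(age, h) ≥ σ_obs everywhere.

Z = (observed − μ)/σ; percentile = 100·Φ(Z); BP at percentile p is
μ + Φ⁻¹(p/100)·σ. Height percentiles convert to Z at full double precision
(90th → 1.2816; printed references round this to 1.28). Percentile tables
evaluate at exact integer ages.

Ordinal classification supports three schemes: `banker5` (<10th, 10–90th,
90–95th, 95th to 95th + 12 mmHg, and above; the +12 is applied in mmHg to
the child's 95th-percentile BP), `aap4` (merging the bottom two), and
`adult_absolute` fixed cutoffs for ages ≥ 13 (systolic 120/130/140,
diastolic 80/90; the diastolic scale has no separate "elevated" band).
Category boundaries are lower-bound inclusive; the tie at exactly the
95th-percentile BP classifies as stage 1.

Two read-only bundles ship with the package, transcribed from a published
EHR-derived reference: `ehr_random_intercept` (σ = 9.644/9.514/7.312/7.261
mmHg; ICC 0.34/0.34/0.27/0.28) and `ehr_random_slopes` (the final model).
Published coefficient values are stored as strings exactly as printed and
parsed on load, so bundle round-trips preserve them verbatim. The two
published worked-example footnotes contain internal arithmetic
inconsistencies (a cubic-term sign/value differing from the table body);
the bundles follow the table bodies, which reproduce the printed 109.32 mmHg
result, and the worked-example helper `z_from_mean_sd` reproduces the
footnote arithmetic from its stated inputs. The engine itself always pairs
a model's own μ and σ.

## Synthetic cohort generator

Each child draws, per BP type, a random-effect vector from the truth
bundle's Σ; every reading is μ_fixed(age, h) + b·v + ε with ε ~ N(0, σ_obs).
Systolic and diastolic random effects are drawn independently (a documented
simplification; the real within-child SBP–DBP correlation is not modelled).
Defaults are the study conditions the package targets:

* encounter counts {1: 27%, 2: 21%, 3: 14%, 4: 10%, 5: 7%, 6+: 21%}, the 6+
  tail drawn as 6 + Poisson(2.8) so the mean is ≈3.7 BP encounters/child;
* per-child age spans log-normal with median 2.2 y (IQR 1.2–4.4), realised
  exactly as the child's first-to-last visit window, interior visits
  uniform; visits fall on distinct days; ages 3–17, recorded to 4 decimals
  (BP is generated at the recorded covariates, so noise-free configurations
  reproduce μ exactly);
* height Z: baseline ~ N(0,1) plus a linear within-child drift whose span
  is log-normal with median 0.4 (IQR 0.2–0.7), clipped to the ±5 evaluation
  domain — no growth-chart (LMS) machinery, height Z is treated as given;
* calendar years 2009–2021, advanced with age from a uniform base year and
  independent of BP, so the truth is time-stationary and the calendar-drift
  regression has expected slope 0;
* 53% girls; eight site labels; race/ethnicity frequencies matching the
  published cohort table.

Children with one BP encounter still have ≥ 2 qualifying *care* visits
(rows with vitals but no BP), resolving the apparent tension between the
27% single-encounter share and the two-visit inclusion rule: visit-count
and continuity rules count qualifying visits, the analysis table counts BP
encounters. Children whose span exceeds 3 years are gap-filled with non-BP
care visits so that the generated cohort satisfies its own 18-month
continuity rule — the published structural targets describe the *final*
cohort, so the generator emulates a post-attrition population.

Contamination is injected at configurable per-rule rates (default 2% of
children per rule, disjoint subsets): overweight flag, chronic-condition
flag, BP-medication flag, an inpatient encounter, an implausible-BP day, and
a missing-vitals record. Every contaminated record carries exactly one
hidden `should_be_excluded_by` tag, which the attrition tests consume as
ground truth. Implausible-BP days are placed at |Z| ≈ 5.5–7.8 relative to a
population-average SD proxy (closed-form E[vᵀΣv] under ages ~ Uniform and
height Z ~ N(0,1)), so they land safely beyond the ±5 screen of the fitted
constant-SD preliminary model; systolic outliers go up and diastolic down,
preserving SBP > DBP.

Same-day duplicate readings (digital-device first-reading inflation) are a
separate operation: a fraction of BP days gains a second reading equal to
the first + 4 mmHg, so daily mean exceeds daily minimum by 2 mmHg on those
days; the mean-vs-min diagnostic recovers the configured rate.

## Cohort derivation

The shipped cascade has 13 named steps: input bookkeeping; exact-row dedup;
age window [3, 18); outpatient-only (child-level — any inpatient/ED
encounter excludes the child); ≥ 2 qualifying care visits (general
paediatrics, family medicine, APRN, physician assistant); 18-month
continuity (if last − first age > 3 y, every inter-visit gap ≤ 1.5 y,
child-level); BMI < 85th percentile flag; no chronic-condition flag; no
BP-medication flag; vitals present (height and both BP types, row-level);
valid reading values (positive, SBP > DBP); at least one remaining BP day;
and the ±5 Z plausibility screen. The rule list is configuration-ordered
and auditable; counts of children and BP measurements are recorded after
every step and can only decrease. Independent child-level rules commute:
permuting their order changes per-step counts but not the final cohort.

Same-day readings are averaged (arithmetic mean per child-day; the
operation is idempotent), and child-days missing either BP type are dropped
so the analysis table always pairs systolic and diastolic. The plausibility
screen is a single pass: a preliminary random-intercept model is fitted
once on the unfiltered rows, rows with |Z| > 5 for either BP type are
removed, and downstream models are refitted; on clean Gaussian data the
expected removal rate is 4n·Φ(−5) ≈ 0, and refitting moves coefficients
negligibly.

## Estimation

Mixed models are fitted with statsmodels `MixedLM` by **maximum likelihood**
(not REML) throughout, because AIC and likelihood-ratio comparisons across
random-effect structures require it; reported coefficients come from the
same ML fits. Fits are warm-started from OLS fixed effects with a modest
diagonal random-effect covariance — this makes the profiled-likelihood
optimisation converge reliably and 3–5× faster than the library default —
and fall back through lbfgs/bfgs/cg; non-convergence is flagged in the fit
summary, never silent. Optimizer settings are deterministic given data.
Train/test splitting is by child (all rows of a child on one side) at a 70/30
ratio. Fixed-effect R² is reported on both sides.

The random-effect likelihood-ratio chain (intercept-only → + age slope →
+ both slopes) uses naive χ² reference distributions with the parameter-count
difference as df; boundary effects make these conservative, and the AICs are
reported alongside.

Backward AIC pruning greedily removes, each round, the polynomial term whose
removal lowers AIC most, stopping when no removal helps; linear age and
linear height are never dropped, and non-hierarchical gaps (e.g. keeping h⁴
without h²) are allowed, matching the blank cells in published coefficient
tables. Whether random-effect terms should also be pruned is left out: only
fixed terms enter the candidate set.

Quantile centiles minimise the pinball loss (statsmodels `QuantReg`) over
the full 8-term design without pruning, separately per stratum and
τ ∈ {0.50, 0.75, 0.90, 0.95}. Quantile-curve crossing on the evaluation
grid is reported, not repaired. The comparison grid is ages 3–17 (half-year
steps) × height Z at the {5, 10, 25, 50, 75, 90, 95}th percentiles; under
the Gaussian model the τ-curve should track μ + Φ⁻¹(τ)·σ.

## Agreement suite

Squared-weight Cohen's kappa uses wᵢⱼ = (i − j)², expected agreement from
the product of marginals; it is 1 exactly on identical assignments, ≈ 0
under independence, and undefined (NaN, warned) when both raters use a
single category. "Overall" kappa pools systolic and diastolic
classifications as separate observations. Z-vs-Z comparison is OLS of one
model's Z on the other's. Reclassification reports, among child-days at or
above the comparator's 95th-percentile curve, the fraction below the primary
model's, per BP type and age band over [3, 13) (ages ≥ 13 are excluded
because absolute adult cutoffs govern there); empty strata are reported as
absent, not zero. Calendar drift is the OLS slope of Z on year with
**cluster-robust (by child) standard errors** — repeat measurements share a
child's random effects, and i.i.d. SEs overstate precision roughly
four-fold on this design. Subgroup ECDFs of Z are sampled on a fixed grid
(−4…4, step 0.05) per sex/race/site group.

## Problem sizes and what the tests show

The test suite runs on cohorts of 150–8,000 children and one 100,000-row
cross-sectional sample; the analysis drivers use 2,000 children. The
parameter-recovery study fits 20 independent 5,000-child all-boys cohorts
(~18,500 child-days each). At that size the intercept (SE ≈ 0.16 mmHg) and
residual SD (SE ≈ 0.05 mmHg) are recovered well within ±0.5 mmHg and ±2%
respectively, but the linear age slope has SE ≈ 0.05 mmHg/yr: with narrow
per-child age windows (median span 2.2 y) the age trend is identified mostly
between children against the intercept SD of 5 mmHg, so a ±0.05 band is
about one standard error and cannot be hit in ≥90% of seeds at this n —
that would need roughly four times as many children, or the wide
within-child age coverage of a designed (non-EHR) study. This is a
sample-information limit of the study conditions, not an estimator defect;
the recovery test states the bands it checks and reports per-quantity hit
rates.

Passing tests demonstrate correctness of the pipeline under its own
generative assumptions (Gaussian random effects and residuals, linear
random-effect structure, time-stationarity, independent SBP/DBP effects).
They do not validate those assumptions against real paediatric BP data, and
cohort-scale published quantities (kappas, Z-vs-Z R², reclassification
fractions, calendar slopes measured on ~292k real children) are not
reproducible here; direction checks (e.g. a comparator whose 95th-percentile
curve sits below the primary model's must yield downward reclassification,
increasing with the gap) stand in for them.

## Numerical choices

* Optimizer: profiled ML, warm start as above, maxiter 500, tolerance at
  statsmodels defaults (relative log-likelihood ~1e-8).
* Tiny negative eigenvalues (≥ −1e-8) of printed/estimated random-effect
  covariances are tolerated as rounding and clipped to zero when factoring.
* Estimated correlations are clipped to [−1, 1]; boundary fits are flagged.
* Bundle JSON stores numbers as full-precision strings; evaluation after a
  save/load round-trip is identical to 1e-12.
* Category ties: lower-bound inclusive everywhere.
* Degenerate inputs rejected with named errors: empty tables, unknown rules,
  missing columns (named), out-of-domain age/height, non-PSD covariances,
  percentiles outside (0, 100), single-year drift regressions, rank-deficient
  quantile designs, single-category kappa marginals (NaN + warning).

## Known limitations

* No seasonal/diurnal BP structure, no site-level random effects, and no
  real coding systems (chronic conditions and medications are boolean flags).
* SBP and DBP random effects are independent in the generator.
* The generator calibrates realised age spans to the published quartiles by
  placing first/last visits at the window edges; the interior visit process
  is uniform, which is a modelling choice, not an observed schedule.
* The LRT chain's χ² p-values ignore boundary mixtures (conservative).
* The adult-absolute scheme covers the standard systolic/diastolic cutoffs
  only; it does not implement full guideline diagnosis logic (repeat-visit
  confirmation, ambulatory monitoring).
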