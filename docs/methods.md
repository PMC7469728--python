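# Methods

This note documents the model implemented by `riskmeta`, its assumptions,
the numerical choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## The meta-model

Case–control studies of the same disease rarely report comparable
quantities: they use different subsets of risk factors, different level
partitions, different statistical models, and different summaries of
uncertainty. A conventional meta-analysis can pool odds ratios for one
factor; it cannot synthesize several factors jointly. The meta-model sidesteps
this by keeping each study's risk equation intact and pooling *predicted
risks* instead of effect sizes.

For study *k* with odds ratios OR_jk over its non-reference factor levels
*j*, and population prevalences prev_j of those levels, the reference
patient's risk is calibrated as

    R0k = R0 / exp( Σ_j prev_j · ln OR_jk )

where R0 is the population probability of disease over the modelled age
range (default 0.000094: cervical cancer among Chinese women aged 18–85).
The divisor is the relative risk of the population-average woman versus the
reference patient, so every study satisfies the *calibration identity*
R0k · exp(Σ prev·ln OR) = R0 exactly (asserted to 1e-12 in the tests;
it holds to machine precision because it is algebraic, not fitted). A
patient's study-specific risk is R_ik = (Π OR_jk) · R0k over the odds
ratios matching her levels.

Assumptions worth stating plainly:

* odds ratios are treated as relative risks of the modelled outcome (the
  rare-disease approximation; the outcome probability is ~1e-4);
* factors combine multiplicatively within a study (no interactions);
* a level absent from a study means "not estimated", never OR = 1 — the
  per-study product simply skips factors the study does not model;
* `not_applicable` profile entries (e.g. gestational factors for a
  never-pregnant woman) contribute a multiplier of 1, like reference
  levels;
* R0 is a constant, not resampled in the Monte Carlo; age is not a model
  factor (only indirectly through age-linked factors such as menopause).

## Standard-error imputation

Estimates enter the model only if the standard error of their log-OR is
recoverable. Four routes fire in order of decreasing information content
(reported SE > 95 % CI > p-value > χ² + totals); exactly one route fires
per estimate and is recorded in an `ImputationTrace`:

* **reported** — σ given directly (also the only usable form for a bare
  regression coefficient, whose OR point estimate is the unbiased mean
  exp(μ + σ²/2); Monte Carlo still samples ln OR ~ Normal(μ, σ)).
* **from_ci** — the interval bounds are modelled as
  exp(μ + σ²/2 ∓ 1.96 σ), giving σ = (ln hi − ln lo)/3.92 and
  μ = (ln hi + ln lo)/2 − σ²/2. The inversion is exact (round-trips to
  1e-10).
* **from_pvalue** — Altman–Bland: z = −0.862 + √(0.743 − 2.404 ln p)
  (natural log), σ = |μ/z|. The approximation tracks the exact normal
  quantile within 0.02 for p ∈ [1e-3, 0.5] and drifts to ~0.07 by
  p = 1e-6; the tests assert both bands. Undefined at OR = 1 (μ = 0).
* **from_chi2** — the 2×2 table (a, b, c, d) is reconstructed from the
  four equations a+c = cases, b+d = controls,
  [a/(a+b)]/[c/(c+d)] = ratio, and the Pearson χ² identity; then
  σ² = 1/a + 1/b + 1/c + 1/d (Woolf). Fractional cells are allowed —
  rounded summary statistics generally admit no integer solution.

The χ² system deserves a note: the ratio equation makes b a closed-form
function of a, leaving a one-dimensional root search (dense grid + Brent,
with the domain edges where b = 0 or d = 0 added analytically, and a
bounded refinement for roots at the maximum of χ²(a), where the two
solution branches merge). The system is genuinely underdetermined:
generically *two* tables satisfy all four equations, both on the same side
of OR = 1 when the ratio is. After discarding roots whose odds-ratio
direction contradicts the reported sign, the implementation returns the
table whose odds ratio is closest on the log scale to the supplied ratio,
the reported value being an odds ratio in origin. All four residuals of
the returned table are below 1e-8 relative.

Missing prevalences are imputed by the unweighted mean of the
control-group prevalences the other studies report for that level (tier 4
provenance), then by an external population table with its own tier
(1 = national database … 5 = non-local source); a level with no source
anywhere raises an exclusion signal for the factor. Prevalence tables are
renormalised to an exact simplex per factor (input sums may be off by up
to 1e-3 from rounding; larger discrepancies are errors).

## Monte Carlo propagation

Within-study uncertainty is estimated by simulation: per replicate, each
log-OR is drawn Normal(μ_jk, σ_jk) and each level prevalence Beta with
mean p and SD = cv·p (method-of-moments parameters; infeasible when
cv² ≥ (1−p)/p, which raises with advice to lower the CV). Prevalences are
renormalised within each factor after sampling so the simplex constraint
survives. The baseline and the patient's log risk are recomputed per
replicate; σ_ik is the sample SD (ddof = 1) of the simulated log risks.
The point estimate is *not* the Monte Carlo mean — it is the plug-in value
from the reported/imputed ORs and mean prevalences; simulation feeds only
the SE.

Defaults: 10,000 replications, prevalence CV 0.1, 95 % intervals. In the
single-binary-factor case with fixed prevalence p the propagation is
analytic — ln R_ik = ln R0 + (1−p)·ln OR-draw, so σ_ik = (1−p)·σ — and
the simulation reproduces it within 2 % at the default size.

Randomness is structured for removal stability: every (study, factor)
pair draws from its own substream derived from (seed, crc32(study),
crc32(factor)). Leave-one-study-out and leave-one-factor-out scenarios
therefore reuse bit-identical draws for everything retained, so
sensitivity metrics measure the removal, not simulation noise. Draws do
not depend on the profile, so batch prediction shares one set of
replicate matrices across profiles.

## Random-effects pooling

Study log-risks are pooled with DerSimonian–Laird: τ² from the
fixed-effect Q statistic, weights 1/(σ_ik² + τ²), Wald interval on the
log scale, back-transformed. REML estimation of τ² is available via
`ModelConfig(re_method="reml")` (bounded maximisation of the restricted
likelihood). A single study passes through with τ² = 0 and a flag;
degenerate all-zero within-study variances fall back to an unweighted
mean with a flag. The interval is a Wald confidence interval for the mean
effect, not a prediction interval.

## Ranking

For reporting (not for the risk engine), each factor's level ORs are
pooled by an inverse-variance weighted arithmetic mean on the OR scale,
with ORs below 1 replaced by reciprocals first so protective and
deleterious factors rank comparably (the log-OR variance is unchanged by
inversion; a log-scale geometric variant sits behind `scale="log"`). The
lower CI bound comes from the pooled weight sum on the log scale.
Prevalence pooling weights non-reference levels by their estimates' total
inverse variance when available, else equally.

## Synthetic data

`default_spec()` mirrors the scale of the cervical-cancer evidence base:
11 studies over 17 risk factors (30 non-reference levels), per-factor
coverage probabilities tuned so studies report partially overlapping
subsets (~140 estimate rows in expectation; frequently-reported factors —
smoking, sexual debut, deliveries, HPV — appear in most studies), true
ORs between 0.35 and 2.8 except HPV infection at 15 (a dominant binary
factor, so qualitative sensitivity findings are testable as properties),
and between-study log-OR noise with SD 0.15. Each estimate's variability
is censored into one reporting pattern (55 % full CI, 20 % p-value only,
15 % χ²+totals only, 10 % coefficient+SE), with per-level 2×2 tables
constructed from study sizes and population prevalences so that χ²-only
rows carry internally consistent summaries. χ²-only rows report the
constructed table's cohort-style ratio labelled RR, exercising the
RR-as-OR relabelling the ingestion applies to case–control reports.

Patient profiles are drawn from the population prevalences with
dependency handling: factors in a *linked group* share one uniform
variate (comonotonic coupling), which keeps every categorical marginal
exact while making constrained chains consistent — screening history with
screening interval, contraception with IUD-years, pregnancies with
deliveries, and the age chain sexual debut → first pregnancy → first
delivery. Age-like factors carry continuous attributes drawn uniformly
within the chosen bin; the default bin layouts are arranged so the
coupled quantile functions can never violate the minimum-gap constraints
(first delivery ≥ sexual debut + 0.75 years; ≥ first pregnancy + 0.75
years). Violations under user-specified layouts trigger whole-profile
rejection with a bounded retry. A never-pregnant block (probability 0.17)
sets the four gestational factors to `not_applicable`. Profiles depend
only on (seed, index), so generation order is irrelevant.

What the generator does **not** emulate: real publication bias,
correlated odds ratios within a study, misclassified or harmonization-
mismatched level partitions beyond the deliberate study-specific
discretisation of ages, secular drift across study eras, and the actual
values of any published study. Passing tests therefore demonstrate the
machinery's correctness and the model's qualitative behaviour, not the
accuracy of any real-world risk estimate.

`table1_fixture()` packages eight fixed hypothetical profiles spanning
low- to high-risk women (three HPV-positive), used for face-validity
runs; their continuous source values (ages, cigarette index, IUD years)
ride along in `attributes`.

## Problem sizes in the test suite

The suite favours the smallest sizes at which each property is already
decisive: the analytic Monte Carlo check runs at the default 10,000
replications (its 2 % tolerance needs them); the sensitivity mirror uses
12 profiles × 500 replications (factor dominance is an order statistic
and stable at this size); ordering-recovery uses 100 profiles with 300
replications, since the plug-in points that drive the ordering do not
depend on the replication count; the parameter-recovery harness removes
*all* generator distortions (zero between-study SD, full-CI reporting,
full factor coverage), under which recovery is exact to ~1e-15 — with
partial coverage the pooled prediction is intrinsically a
coverage-diluted estimand and profile-ordering correlation with the full
generative truth caps near 0.95 regardless of implementation.

## Known limitations

* Mixing adjusted and unadjusted estimates (unavoidable with sparse
  reporting) can double-count dependent factors such as pregnancies and
  deliveries.
* The Wald interval ignores uncertainty in τ² (no
  Hartung–Knapp/Sidik–Jonkman adjustment) and is not a prediction
  interval for a new study.
* Level partitions are taken as given; harmonizing "age < 17" against
  "age < 18" across studies is the table author's responsibility.
* The Altman–Bland route loses accuracy for very small p-values; a CI,
  when available, always takes precedence.
* Absolute risks inherit whatever biases the underlying studies carry;
  the model's validation is face validity and internal consistency, not
  predictive accuracy against patient-level outcomes.
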