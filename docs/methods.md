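# Methods

This note documents the statistical machinery implemented in `bcmort`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-data validation does and does not establish.

## Cohort model

A cohort is a table of women diagnosed with invasive breast cancer: age at
diagnosis (integer, 15–84), calendar year of diagnosis, stage (I–IV or
missing), hormone-receptor status (positive/negative/unknown), follow-up time
in years, vital status, and an ICD-10 cause of death for those who died.

**Truncation.** Follow-up is administratively truncated at a 10-year horizon:
a death after the horizon becomes a censoring at the horizon and its cause is
discarded. Intervals are half-open `[0, t)`; a death at exactly the horizon
counts as an event, censoring applies strictly beyond it. Truncation is
idempotent.

**Cause classification** is two-level: a four-category partition used by the
competing-risks analysis (breast cancer = C50; other cancer = C00–D49 except
C50; CVD = I00–I99; everything else = other causes) and an ICD-10
chapter-group partition used for cause-specific SMRs (infectious A00–B99,
tumours C00–D49, blood D50–D89, endocrine E00–E89, mental F00–F99, nervous
system and sense organs G00–H95, circulatory I00–I99, respiratory J00–J99,
digestive K00–K95, skin L00–L99, musculoskeletal M00–M99, genitourinary
N00–N99, congenital Q00–Q99, ill-defined R00–R99, external V01–Y98, plus a
catch-all for chapters outside these ranges). Both partitions are total
functions on syntactically valid codes. In chapter-level SMR tallies the
index disease (C50) is excluded: it is the disease defining the cohort, not a
competing cause, and the "tumours" SMR row means tumours other than breast.

**Lexis expansion.** Each subject's follow-up is split exactly across the
(age band × calendar year) cells she traverses, ageing continuously from her
integer age at diagnosis. Diagnosis dates are known to the year only, so
entry is placed at mid-year by default (`entry_offset=0.5`), the unbiased
convention for year-resolution registry data; the offset is a parameter and
0 reproduces aligned-origin traversal. Default bands are 1 year on both axes;
coarser reference-rate bands are handled at lookup time. Cell sums conserve
total person-time to floating-point accuracy, which is asserted rather than
assumed.

## Expected deaths and SMR inputs

E_c = Σ person-years × rate over Lexis cells, where each 1-year cell must lie
inside a rate row's age band (default reference granularity: 5-year age bands
by single calendar year; the granularity of real reference tables varies and
is configurable). Calendar years are matched exactly with a nearest-year
fallback at table edges; a cell with no covering rate row is an error that
lists the orphan cells rather than silently dropping exposure. Women dying of
breast cancer contribute person-years up to death to every E_c — the standard
indirect-standardisation convention; breast cancer is excluded only as a
cause. The all-cause aggregate is "all causes except breast cancer", the sum
of the non-index broad causes. A zero expected count invalidates an SMR and
is refused at construction.

## Bayesian hierarchical SMR

For cause c: `O_c ~ Poisson(mu_c)`, `log mu_c = log E_c + theta_c`,
`theta_c ~ N(0, tau)`, `sigma ~ Uniform(1, 5)`, `tau = 1/sigma^2`. The prior
lower bound of 1 on sigma is kept deliberately: it is a published device for
stabilising SMR posteriors with few or zero observed deaths, at the price of
a very diffuse prior on the log-SMR (with E of a few hundred the likelihood
dominates and the prior is immaterial).

**Pooling.** The hierarchical notation admits two readings: one sigma shared
by all causes (partial pooling) or an independent (theta, sigma) pair per
cause. Both are implemented; `per_cause_sigma` is the default because
cause-by-cause SMR tables read as independent fits, and `shared_sigma` is
available for joint fits. Neither is asserted to be the historically "right"
one.

**Sampler.** A bespoke adaptive random-walk Metropolis-within-Gibbs on
(theta, sigma): theta updates are Gaussian random walks with per-chain scales
adapted during burn-in toward 44% acceptance; sigma proposals are reflected
into [1, 5] (a symmetric, volume-preserving kernel). Adapted scales are
capped (theta scale at 25, sigma scale at the prior width) — beyond that the
kernel is effectively an independence sampler and unbounded growth only
degrades the floating-point reflection arithmetic. Defaults: 4 chains, 5,000
iterations, 2,000 burn-in, thinning 1, all seeded; identical seeds give
bit-identical draws. The model is two parameters per cause, so heavier
machinery (HMC, external engines) would buy nothing and cost repo
self-containedness. Convergence is monitored with split-chain R-hat and ESS
(via arviz); R-hat > 1.05 flags the result and emits a warning rather than
failing silently.

Summaries: posterior median SMR, equal-tailed (percentile) 95% credible
interval — not HPD, matching common practice for SMR reporting — and
P(SMR > 1), with significance flagged when P > 0.95 (strict).

**Period comparison.** Ratio = SMR_2/SMR_1 between diagnostic periods
(2000–2004 vs 2005–2009) is formed by resampling each period's posterior
draws with replacement to a common length and dividing elementwise; the
independent resampling breaks any residual within-chain ordering. Reported
like the SMR (median, CrI, P(Ratio > 1)). A plug-in ratio of rounded medians
is also provided, since published tables are sometimes computed that way;
the rendered table prints the resampled median.

**Validation.** The sampler is checked against a deterministic 2-D grid
quadrature of the same posterior (trapezoidal over an 8001 × 401 grid), an
oracle that shares no code with the sampler: medians agree within 2%
relative (absolute floor 0.01 for near-zero medians, where the Monte-Carlo
error of an extreme-tail median exceeds any fixed relative band at
practical chain lengths) and P(SMR > 1) within 0.02, over
(O, E) ∈ {0, 1, 5, 20, 100} × {0.5, 2, 10, 50}. Frequentist recovery:
requested SMRs in {0.8, 1.0, 1.5, 2.5} are covered by the 95% CrI in ≥ 90%
of 100 seeded synthetic cohorts of 50,000 patients.

## Competing risks

**Nonparametric estimator.** At each distinct event time t_i with n_i at
risk, d_ki deaths of cause k and d_i = Σ_k d_ki: the all-cause survivor is
the product limit S_i = Π(1 − d_j/n_j), and P_k accumulates S_{i−1} d_ki/n_i.
Censorings at an event time remain at risk at that time. The identity
S + Σ_k P_k = 1 holds to 1e-10 at every grid point and is asserted at
construction, every P_k is nondecreasing, and collapsing all causes into one
reproduces 1 − Kaplan–Meier exactly. Pointwise variances use an Aalen-type
delta-method estimator, computed in O(grid) via cumulative sums; it is a
close variant of the counting-process form used by the standard R
implementation (agreement within a few percent on fixtures where the point
estimates agree to 1e-8).

**Cause-specific-hazard (CSH) regression.** One Cox model per cause,
treating deaths from competing causes as censored at their death time.
Partial-likelihood maximisation (Efron tie handling — simulated times are
continuous but registry times tie at coarse resolution — and Wald 95%
intervals) is delegated to `lifelines.CoxPHFitter`; the Breslow baseline
cumulative hazard is recomputed in-package from the fitted coefficients,
which makes the null model collapse exactly (to 1e-8) onto the nonparametric
estimator. An empty covariate list is accepted and yields that null model
without a regression step. Zero events of the target cause, or a failed
maximisation (e.g. separation), raise errors naming the cause.

**Profile prediction.** Given one CSH fit per cause and covariate values x,
cause-k increments are Breslow baseline increments × exp(beta_k·x); the
survivor is the product limit over the summed increments and P_k accumulates
S(t−) h_k — the same scheme as the nonparametric estimator, so the
normalisation identity is structural. If summed increments ever exceed 1
(possible at extreme profiles) they are rescaled with a warning. Pointwise
uncertainty for model-based curves comes from a seeded nonparametric
bootstrap (default 200 resamples; degenerate resamples are skipped);
nonparametric curves carry the analytic variance above.

**Covariates and relative risks.** Age enters either as three groups
(≤49, 50–68, ≥69 — the default for profile-probability tables) or as a
continuous covariate (the default for relative-risk tables); both appear in
published practice and both are exposed. Relative risks for HR− vs HR+
within a stage stratum come from three age-adjusted fits on patients with
known HR status: all-cause Cox, and a two-cause CSH decomposition into
breast-cancer vs aggregated non-breast-cancer mortality. Stage is always a
stratification variable, never a regression covariate. Profile-probability
tables are computed from stage-stratified CSH fits at each
(HR × age-group) profile; continuous-age profiles use representative ages
45/59/75.

**Rounding.** Probabilities are rendered as percentages to 2 dp and ratios
to 2 dp, ratios always computed from unrounded values.

## Synthetic cohort generator

The generator defines the study conditions for all validation. Defaults
emulate a two-registry cohort of 6,758 women diagnosed 2000–2009 (uniform
over years), ages from a Normal(59.1, 14.3) truncated to [15, 84] and
rounded, stage frequencies from the registry counts (2257/2478/1080/463/484,
normalised), and HR status drawn as 70.4%/15.8%/4.8%
positive/negative/unknown for diagnoses from 2005 on — earlier diagnoses are
recorded as unknown, reproducing the registry's measurement history.

Within each (stage, HR) stratum the four causes act as constant competing
hazards; a subject draws one all-cause exponential time with rate
Λ = Σλ_k and a cause with probability λ_k/Λ (equivalent to the minimum of
independent exponentials), truncated at 10 years. Default hazards are
derived by closed-form inversion (`hazards_from_probabilities`) from 10-year
probability vectors per stratum chosen to match the stage/HR mortality
gradient of such cohorts (e.g. stage I HR+: 1.7% BC, 3.6% other cancer,
1.4% CVD, 3.2% other; stage IV HR−: 86.8% BC); observed-unknown strata use
the positive/negative mixture. ICD-10 codes within each broad cause are
drawn from fixed pools (colon/lung/pancreas/endometrium/ovary dominating
second cancers; heart failure, infarction and stroke dominating CVD; a
spread over the remaining chapters otherwise), which induces a realistic
chapter-level death structure.

The emitted reference rate table is constant over 5-year age bands and
calendar years and scaled so the cohort's true SMR per broad cause equals a
requested value: rate_k = h̄_k/s, with h̄_k the person-year-weighted marginal
cohort hazard (stratum weights × expected truncated person-years
(1 − e^{−10Λ})/Λ). Chapter-level rates split h̄_k by the code-pool shares.

Closed-form ground truth accompanies every cohort:
P_k(t) = (λ_k/Λ)(1 − e^{−Λt}), S(t) = e^{−Λt}, true SMRs as requested.

**What the generator does not emulate** — and hence what passing tests do
not establish about real registry data: age- and calendar-dependence of the
cause-specific hazards (real CVD mortality rises steeply with attained age;
here rates are flat within stratum, so the Lexis/rate-lookup machinery is
exercised but age-gradient misspecification is not), non-proportional or
time-varying hazards, treatment effects, incidence trends, dependent
censoring, cause-of-death miscoding, and loss to follow-up (the only
censoring is administrative at 10 years, matching a design in which every
subject has a full decade of potential follow-up). Validation demonstrates
internal correctness of the estimators under the stated model, not
robustness to these violations.

## Descriptive summaries

Cohort characteristics are tabulated with a period split; every percentage
is derived from its printed numerator and denominator (a property the tests
assert). Categorical sections are compared across periods with a chi-square
test and continuous ones with a Welch t test; pairwise per-level proportion
comparisons use Holm's correction. These are descriptive aids, not the
inferential core.

## Pipeline, determinism, problem sizes

`run_pipeline` chains input (load or simulate) → truncation/classification →
descriptive table → Lexis/expected counts per period → SMR fits and period
ratios → relative risks and profile probabilities → per-stage curve exports
and a manifest recording seed and configuration. All randomness descends
from one seed via a seed sequence; reruns are byte-identical. Any stage
failure aborts with the stage named.

Validation problem sizes were chosen to make sampling error small relative
to the tolerances asserted — 50,000 subjects × 100 replicates for CrI
coverage, 5,000–12,000 for competing-risks and hazard-ratio recovery,
20-point (O, E) grids for the quadrature comparison — while keeping the full
suite and the acceptance script each within a few minutes on one CPU.

## Known limitations

- Constant per-stratum hazards make the generator's ground truth exact but
  idealised; a piecewise-constant extension point exists in the design but
  is not implemented.
- The Aalen-type variance is a variant, not a replica, of the
  counting-process estimator in the reference R implementation; agreement is
  within a few percent, and bootstrap SEs are available where exactness
  matters.
- The Breslow baseline is paired with Efron tie handling in the regression;
  with heavily tied data the combination is mildly inconsistent (continuous
  simulated times make it exact here).
- Chapter-level SMRs for rare chapters rest on single-digit counts; the
  Uniform(1, 5) prior keeps them proper but their credible intervals are
  dominated by the prior.
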