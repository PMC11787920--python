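# Methods

This note documents the statistical models implemented in `phenotyper`,
the design choices made where several reasonable options existed, and the
limits of what the synthetic cohorts can demonstrate.

## Composites and dynamics features

Each prompt yields four 0–10 items. The passive composite is the mean of
the reverse-coded desire-to-live item (10 − value) and the desire-to-die
item; the active composite is the mean of the thoughts and intent items.
When exactly one constituent is present, the composite equals the
available (reverse-coded where applicable) item — this keeps partially
answered prompts usable and is configurable only in the sense that both
items missing always yields a missing composite.

Ten per-person features feed the profile analysis, five per outcome:

* mean *M* and within-person SD *S* of completed ratings (the n−1
  denominator is a fixed convention here, chosen for reproducibility);
* peak *K* (maximum recorded value);
* frequency *F* = 100 × (#ratings > 0)/(#completed) — the denominator is
  completed ratings only;
* RMSSD *R* = √(mean of (xₜ₊₁ − xₜ)²) over consecutive *scheduled* slots
  with both values present. Missed prompts stay in the grid, so a
  difference is never formed across a gap; the overnight transition from
  the last prompt of one day to the first of the next is treated as an
  ordinary lag-1 pair, and unequal real-time gaps are treated as equal
  lags. A time-aware instability metric is deliberately out of scope.

Self-initiated (non-scheduled) entries are loaded and retained but
excluded from feature computation by default; `--include-self-initiated`
merges them into the slot sequence by timestamp.

Participants with any undefined feature (fewer than two completed ratings,
or no adjacent pair) are excluded from the profile analysis and logged.

## ICC

The intraclass correlation of each composite comes from the
intercept-only random-effects model yᵢₜ = μ + uᵢ + eᵢₜ with
uᵢ ~ N(0, σ²ᵦ), eᵢₜ ~ N(0, σ²𝓌): ICC = σ²ᵦ/(σ²ᵦ + σ²𝓌). The REML
estimator profiles μ and σ²𝓌 out of the restricted likelihood, leaving a
bounded scalar optimization over log(σ²ᵦ/σ²𝓌); this is exact for
unbalanced person counts. A one-way ANOVA method-of-moments estimator
(Searle's unbalanced form, truncated at zero) serves as an independent
cross-check; on balanced data with interior estimates the two agree to
numerical precision, and the implementation is verified against
`statsmodels` MixedLM in the test suite.

## Latent profile analysis

Profiles are components of a G-component multivariate Gaussian mixture
over the ten features (unstandardized by default; a standardize flag
exists). EM details:

* initialization by k-means++ centers (nearest-center hard labels), best
  of 10 restarts, convergence when the relative objective change falls
  below 10⁻⁶ (500 iteration cap);
* six covariance families, in increasing order of complexity: shared
  spherical, per-component spherical, shared diagonal, per-component
  diagonal, shared full, per-component full (EII/VII/EEI/VVI/EEE/VVV in
  the common model-based-clustering nomenclature);
* an eigenvalue floor of 10⁻⁶ × mean marginal variance on every
  covariance update, and a weak conjugate variance prior — one
  pseudo-observation of the marginal variance scaled by G^(−2/d) — in
  every M-step. The prior matters: cohorts genuinely contain point-mass
  subgroups (persons whose frequency is exactly 100 or exactly 0, or
  whose active series is all zero), and without regularization every
  good varying-variance solution collapses onto the floor, where its
  likelihood is an artifact. `prior_weight=0` gives pure maximum
  likelihood; the EM-monotonicity guarantee applies to the optimized
  objective and is tested in that configuration;
* a converged restart whose covariance still rests on the floor is
  treated as degenerate and discarded; a fit fails only if every restart
  degenerates.

Model choice reports BIC = 2·logL − k·ln n (maximize), the normalized
entropy E = 1 − Σᵢ Σ_g(−p̂ᵢ_g ln p̂ᵢ_g)/(n ln G) (defined as 1 for G = 1)
together with the raw total Shannon entropy, and the BLRT. Two selection
rules beyond "BIC argmax" are applied:

* **Identifiability.** Candidates with k ≥ n free parameters are fitted
  and reported but excluded from selection — their BIC carries no
  evidence. At n ≈ 82 and d = 10 this rules out all full-covariance
  mixtures with G ≥ 2 and per-component-diagonal models with G ≥ 4.
* **Default family set.** The default search runs the per-component
  diagonal family (the classical latent-profile model with class-varying
  variances) plus the two spherical baselines. Equal-variance families
  are not searched by default: with indicators on strongly heterogeneous
  scales (percentages next to 0–10 means) and dispersion that differs
  sharply between profiles, a homoscedasticity constraint is compensated
  by spurious extra profiles — on calibrated synthetic cohorts the
  equal-variance BIC keeps rising to the top of the G range while label
  agreement with ground truth collapses. All six families remain
  available via the `families` argument and are exercised in tests.

The BLRT compares G against G−1 within one family: B parametric
resamples from the fitted null, both models refitted per resample with 3
EM restarts, observed statistic Λ = max(0, 2(logL_G − logL_{G−1})),
p = (1 + #{Λ_b ≥ Λ_obs})/(B + 1). The observed models are refitted with
the same 3-restart budget as the bootstrap refits: optimizing the
observed statistic harder than the bootstrap ones would inflate it and
make the test anti-conservative. Type-I calibration at the nominal 5 %
level is verified on null data in the test suite, using a sequential
early-stop that terminates a replicate once non-rejection is certain.

Reported profiles are permuted into a canonical order — descending mean
active ideation — so "phenotype 1" is always the highest-intensity
profile; posterior ties break toward the lower component index.

## Group comparisons and the prospective analysis

Continuous variables: one-way fixed-effects ANOVA across phenotypes;
categorical variables: Pearson chi-square without continuity correction.
Per-variable compact letters come from all pairwise tests (Welch t for
continuous, 2×2 chi-square for categorical; Tukey HSD available) at an
unadjusted α = 0.05 — no multiple-testing correction is applied by
design — via greedy insert–absorb, so groups share a letter exactly when
their pairwise test is not significant.

The phenotype × any-attempt table is restricted to participants eligible
for prospective analysis: those who reported an attempt, or responded in
at least one of the final 4 follow-up weeks (the operationalization of
completing the follow-up; the window is configurable). Losses to
follow-up without a reported attempt are excluded rather than counted as
non-attempters. The table is tested with the exact conditional test
(two-sided by the "probability no larger than the observed table" rule,
the r×c generalization of Fisher's exact test), enumerated exhaustively
when the candidate-table bound stays below 10⁷ and otherwise estimated by
seeded Monte-Carlo over fixed-margin tables (Patefield sampling, add-one
rule). Effect size is Cramer's V. The default table keeps one row per
phenotype (a pooled high-risk-vs-lowest 2×2 variant is available), and an
optional stratified summary reports repeat-attempt rates among
participants with a past attempt history.

## Synthetic cohort generator

For person i with phenotype g and outcome o the latent process is

    y*(t) = μᵢₒ + e(t),  μᵢₒ ~ N(m₀, τ₀²),  e(t) = φ₀ e(t−1) + σ₀ z(t),

with stationary initialization; the observed rating is y* rounded to the
nearest 0.5 (mimicking the two-item composite) and clamped to [0, 10].
This is the minimal observation model that jointly controls the person
mean (m), the ICC (τ against σ), the within-person SD, the RMSSD/SD ratio
(via φ: the mean squared successive difference of a stationary AR(1) with
deviation variance s² is 2s²(1 − φ)), and the frequency of non-zero
ratings (via floor censoring, which also produces the zero-inflation
visible in real low-intensity series). Item pairs are back-solved from
each composite so scoring the generated items reproduces the composite
exactly. Missingness is missing-completely-at-random at rate
1 − compliance (default 0.78). Prompts sit in four equal windows between
07:00 and 22:00 with uniform jitter; overnight transitions are generated
as ordinary lag-1 steps, matching how the RMSSD treats them. Self-
initiated entries (Poisson, mean 3/person) are drawn around the person
intercept without serial dependence.

Default phenotype parameters are produced by `calibrate_defaults`, which
moment-matches simulation against the three-profile feature-table targets
(mixing weights 0.24/0.33/0.43) plus cohort ICC targets of 0.70 (passive)
and 0.67 (active): damped fixed-point updates of (m, s, φ) per phenotype
and outcome against the target mean/SD/RMSSD, alternating with a
between-person-SD (τ) update against the ICC targets. The ICC targets
are themselves study-scale random-intercept estimates, so the calibrated
quantity is the mean REML ICC over replicate cohorts at the configured
size, phenotype composition and compliance — for these skewed, censored
composites that statistic sits visibly below the asymptotic moment ICC,
and calibrating to the asymptote would leave the study-scale estimate
short. Because floor censoring blocks most of τ's effect in
low-intensity profiles, the τ update measures each phenotype's
"pass-through" by finite difference and allocates the required
between-person variance proportionally, under a cap (default τ ≤ 2.0)
that keeps profiles separable; unmet demand redistributes to other
phenotypes across iterations. The active-outcome demand saturates the
cap, leaving the study-scale active ICC mean near 66.4 % against the
67 % target — the residual is the price of keeping profiles separable. Calibration problem
sizes (400 persons per phenotype per inner step, 84 slots) keep the whole
procedure under a minute; the resulting parameters are frozen as package
defaults and the calibration report is regenerated on demand.

Achieved moments match 22 of the 24 targets within ±10 % relative or
±0.15 absolute. The two misses are frequencies, which are emergent rather
than directly controlled: the lowest-intensity profile's passive
frequency comes out near 66 % against an 81 % target — with its mean,
SD and the between-person spread required by the ICC all pinned, a
censored-normal process cannot simultaneously push the non-zero share
that high (achieved: ≈ 68 % at the frozen defaults). This is a structural property of the observation model, noted
here rather than hidden by loosening the other targets.

Follow-up outcomes: attempter status is Bernoulli with phenotype-specific
probabilities (defaults 4/11, 3/11, 0), attempters receive a uniform 1–5
attempt weeks (always reported), and ordinary weekly response combines
88 % study participation, a constant weekly dropout hazard of 0.013 and
90 % per-week response while active — together reproducing ~66 % weekly
response among participants and ~44 % prospective-analysis inclusion. A
flat independent response rate cannot reproduce that inclusion pattern
(the chance of missing all of the final four weeks would be ~1 %), which
is why dropout is modeled explicitly.

### What the generator does and does not emulate

It emulates: the schedule and compliance level, the per-phenotype feature
moments, zero-inflation, the between/within variance split, approximate
posterior-classification sharpness, and phenotype-graded attempt risk.
It does not emulate: non-stationary trends or event-triggered spikes,
missingness related to symptom state (MNAR), cross-outcome correlation
within a moment, unequal real-time prompt gaps, or heavy-tailed/irregular
within-profile feature distributions. Passing recovery tests on these
cohorts therefore shows that the pipeline is correct and well-calibrated
under its own assumptions — not that three profiles, or these particular
profiles, would emerge from any real dataset.

## Numerical and degenerate-input conventions

* RMSSD with no valid adjacent pair is undefined (missing), never zero.
* ICC requires ≥2 persons and positive total variance; zero within-person
  variance with between-person differences gives ICC = 1; negative
  variance estimates truncate at zero.
* ANOVA with zero within- and between-group variance is an error; zero
  within-group variance with distinct means reports F = ∞, p = 0.
* Exact-test ties in table probabilities are grouped with a 1 + 10⁻⁷
  relative tolerance before summation.
* All randomness flows from a single seed through independent
  per-stage `numpy` seed streams (generator, EM restarts, BLRT, Monte-
  Carlo exact tests), so identical configuration + seed reproduces every
  artifact byte-for-byte (timestamps excluded).

## Problem sizes used in validation

The shipped validation suite simulates cohorts at the study scale
(N = 82, 84 slots): 20 replicates for the ICC checks and 5 full pipeline
replicates for profile-recovery checks (the acceptance script uses 40 and
20 replicates respectively, trading a couple of minutes of runtime for
tighter Monte-Carlo error on the reported means), 200 null replicates at
B = 199 for BLRT type-I calibration, exhaustive missingness patterns to
length 12 for the RMSSD oracle, and all 2×2 tables with n ≤ 40 for exact-
test equivalence. The BLRT default of B = 1000 resamples is used for
reported analyses; validation uses B = 199 with the sequential stopping
rule described above.
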