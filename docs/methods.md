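# Methods

`pgscohort` implements a complete, self-contained emulation of a
family-informed type-2-diabetes (T2D) polygenic-score study: a generative
cohort model with known ground truth, a clumping+thresholding (C+T) score
builder, percentile risk stratification, screening-guideline evaluation, and
an adjusted-regression suite comparing family history (FH) with the polygenic
score (PGS). Because individual-level data from large consumer-genomics T2D
cohorts are not publicly available, every analysis here runs against
synthetic cohorts whose generative parameters are chosen to echo the
qualitative structure of such studies; the package's test surface is
*parameter recovery* against the generator's known truth, not replication of
any proprietary cohort's estimates.

## Generative model

### Genotypes

Each simulated participant is the offspring of a simulated mother/father
pair. For SNP *j* with effect-allele frequency *p_j* (drawn uniformly inside
a configurable MAF window, default 0.05–0.5), each parent draws a dosage
Binomial(2, *p_j*) and transmits one allele Bernoulli(dosage/2). Dosages are
independent across SNPs — there is no linkage disequilibrium beyond physical
position, which is why score construction uses distance-window clumping
rather than r²-based pruning. Positions are cumulative random gaps of
1–100 kb, giving a realistic marker density for windowed clumping.

### Liability

Disease liability is the standard threshold-model sum

    L = G + C + E,   Var(G) = h², Var(C) = c², Var(E) = 1 − h² − c²,

where `G = Σ_j β_j (x_j − 2p_j)` with exactly `n_causal` nonzero effects
rescaled so Var(G) = h² under Hardy–Weinberg; `C` is a family-shared
environment term identical for the parents and the offspring of one family;
`E` is independent noise. Defaults h² = 0.3, c² = 0.1 sit inside the broad
range of published T2D heritability estimates while leaving most variance
unexplained, which is what makes FH and the PGS complementary rather than
redundant predictors.

### Disease, covariates and threshold calibration

Age is truncated-normal (mean 47.6, SD 15.8, range 20–79), sex is female
with probability 0.604, and BMI is log-normal (median ≈ 27 kg/m², clipped to
18.5–69) — the demographic profile of a large adult research cohort. Case
status follows a probit-style rule: affected iff

    S = L + 0.35·age_std + 0.35·logBMI_std > t,

with *t* = Φ⁻¹(1 − prevalence) · sd(S) calibrated against the realized
spread of S so the marginal prevalence matches the target (default 3.2%).
The covariate weights of 0.35 per SD translate to roughly a 1.8–1.9-fold
odds increase per SD of log-BMI in the fitted logistic models, matching the
magnitude such studies report. Parents receive their own age (offspring age
plus ≈ N(28, 6) years, capped at 95), their own BMI draw, the same shared
term C, and the same threshold; **family history** is positive iff at least
one parent is affected. Parent-only FH is a deliberate simplification
(affected siblings/children are not simulated by default); a configurable
fraction (default 30%) of FH responses is set missing to emulate the smaller
analytic subsample that FH survey questions produce.

### Downstream phenotypes

All secondary outcomes are driven by the same latent liability, so one
mechanism produces every gradient the analyses probe:

* **Age of diagnosis (AOD)** for cases: `aod = 49 − 1.37·L + N(0, 8²)`,
  truncated to [20, 79]. The reported *current* age of a case is
  `min(aod + |N(0, 12²)|, 79)` — AOD plus a half-normal reporting delay.
  Making the delay independent of liability matters: an earlier design that
  reused the case's original age draw made the >40-year-duration
  eligibility filter select against low-liability early-onset cases and
  biased the within-case AOD slope by ≈ −0.2 yr/SD (verified by Monte
  Carlo). With the delay model, durations beyond 40 years occur at the
  ~0.1% level — the frequency a three-SD outlier rule implies — and the
  OLS slope of AOD on L is recovered unbiased.
* **Prediabetes** (controls only): Bernoulli with logit `a + log(1.23)·L`,
  the intercept root-solved so the control-wide prevalence hits its target
  (default 2.5%).
* **One-year incident conversion**: a random subset of controls (default
  35%) carries a follow-up interval of N(446, 102²) days clipped to
  (365, 730]. Conversion is Bernoulli with logit `a + log(1.43)·L`, the
  intercept solved so expected events per person-year equal the target
  rate (default 4.86 per 1,000 PY). The conversion probability is a pure
  logistic in liability — follow-up length enters only the rate
  denominator — so the generator's truth is exactly a log-odds slope per
  liability SD, the scale on which the recovery tests operate.
* **Treatment and complications** (cases only): six independent Bernoulli
  outcomes with logit `a_o + b_o·L + d_o·years_since_dx`, intercepts solved
  per outcome for target base rates (insulin 25%, metformin 55%,
  lifestyle-only 25%, neuropathy 15%, nephropathy 5%, retinopathy 6%);
  default liability slopes log(1.14) for insulin and log(1.10) for
  neuropathy, small or zero elsewhere. Outcomes are modelled marginally
  (no treatment-regime logic), mirroring one-model-per-outcome analyses.

Eligibility filters applied after generation (and available for external
cohorts): age 20–79, BMI 18.5–69, AOD ≥ 20, AOD ≤ current age, duration
≤ 40 years; exclusion counts are tallied per rule.

One global seed expands into named substreams (model, genotypes,
phenotypes, partition, bootstraps, splits), so every stage is independently
reproducible and the full pipeline is bit-for-bit deterministic.

## Score construction (C+T)

The association scan fits one maximum-likelihood logistic regression per SNP
(intercept + dosage + optional covariates) with Wald tests, using a compact
Newton–Raphson solver; monomorphic SNPs return β = 0, p = 1, flagged, and
non-converging fits (e.g. separation) are flagged rather than fatal. An
inverse-variance fixed-effect combiner is provided for scans run per
ancestry stratum.

Clumping is greedy and deterministic: SNPs with p ≤ threshold are visited in
ascending (p, position, id) order and accepted iff no accepted SNP lies
within ± window bp. The default grid {1e-2, 1e-4, 1e-6} × {50, 250, 500 kb}
yields nine candidate variant sets; both grids are configurable. Candidate
weights are the raw per-SNP log-odds estimates. Selection maximizes AUC of
the raw score on a tuning cohort whose participant ids are verified disjoint
from the GWAS cohort (overlap is a protocol error); ties break toward fewer
SNPs, then the smaller p-threshold, then the smaller window. Tuning uses the
score alone (no demographic covariates) — the simplest defensible reading of
a "best-performing variant set" rule. The tuning-set raw-score mean/SD are
frozen into the scoring file as the standardization reference, so scored
cohorts are expressed in tuning-set SD units and drift between evaluation
cohorts cannot silently re-center the score.

Scores are weighted allele counts; weight SNPs absent from a target cohort
are imputed at their expected dosage 2f (frequency from the scoring file),
with a configurable ceiling (default 20%) on the absent fraction.

AUC is Mann–Whitney concordance with ties counted ½ (computed via the ROC
trapezoid, which is identical), with percentile-bootstrap CIs over
individuals (default 2,000 replicates, seeded).

## Stratification

Percentile ranks use average ranks for ties mapped through
`100·(rank−1)/n`, so *n* distinct scores spread uniformly over [0, 100) and
20 ventiles of a tie-free vector have exactly n/20 members. Intervals are
half-open [lo, hi), closed at 100; ties share a rank and therefore a bin.
Per-bin outputs: (i) the unadjusted odds ratio of the outcome in the bin
versus the **total** population — the point estimate uses the raw
overlapping-group ratio, while the 95% CI uses the Woolf log-OR SE from the
non-overlapping bin-versus-complement table (a conservative stand-in, tagged
`woolf-complement`, since bin-vs-total groups overlap and have no standard
closed-form SE); zero cells receive the Haldane–Anscombe 0.5 correction for
the CI only and are flagged; (ii) per-bin means/proportions with seeded
percentile-bootstrap CIs; (iii) crude incidence per 1,000 person-years with
exact Poisson CIs. A privacy floor (default 5 in pipeline outputs)
suppresses statistics for bins below the minimum count. A logistic-score
trend test (outcome on bin index) summarizes monotone gradients.

## Screening rules

Rules are disjunctions of conjunctive criteria over age interval, BMI
interval, FH requirement, and minimum PGS percentile. Built-ins:

* `uspstf`: 35 ≤ age ≤ 70 AND BMI ≥ 25;
* `ada_simplified`: age ≥ 45, OR (age ≥ 18 AND BMI ≥ 25 AND FH positive) —
  a deliberately reduced model using only age, BMI and FH;
* PGS augmentation: adds a disjunct for normal-BMI ([18.5, 25)) adults at or
  above the 90th score percentile, from age 35 (USPSTF variant, no upper
  bound by default, since the augmentation is defined as "35 or older"; an
  age-70 cap is available) or age 18 (ADA variant, kept literal even though
  the simulator's age floor is 20).

Evaluation tests a case's age criterion at its age of *diagnosis* and a
control's at current age — screening aims to catch cases before onset —
with cases missing AOD excluded and counted. Sensitivity/specificity carry
Wilson CIs. Because an augmented rule's criteria are a superset of its
base's, Δsensitivity ≥ 0 and Δspecificity ≤ 0 hold exactly for every cohort;
the comparison report also characterizes the newly screened subgroup. Score
percentiles are computed within the evaluation cohort unless a precomputed
percentile column or external reference is supplied. A single
cross-sectional application is evaluated; repeat-screening intervals are out
of scope.

## Regression suite

Binary outcomes use statsmodels maximum-likelihood logistic fits (perfect
separation yields a flagged non-converged result, not a crash); AOD uses
OLS. Adjusted models condition on decade of age (age/10, continuous —
matching a single per-decade coefficient; categorical decades are a
caller-side option), female sex, standardized log-BMI, and FH. The model
comparison fits four nested prevalence models (base covariates; +FH; +PGS;
+both) on a seeded 75/25 split stratified by outcome (stratification
stabilizes small synthetic runs); log-BMI and PGS are standardized on the
training subset and those constants are applied to test rows. Cox–Snell
pseudo-R² = 1 − exp((2/n)(ll_null − ll_model)) is computed on the training
set against the intercept-only null (the computation set is labelled in the
output, since either choice is defensible); held-out AUC carries a
percentile-bootstrap CI. Nesting guarantees the likelihood ordering
base ≤ {FH-only, PGS-only} ≤ combined on any data set, and Cox–Snell
inherits it at fixed n.

Specialized fits: FH-on-PGS logistic association (OR per score SD, with the
coefficient and the exponentiated OR both reported, since rounding either
first gives slightly different printed values); AOD OLS among cases on PGS,
log-BMI and FH; prediabetes logistic among controls; incident-conversion
logistic among baseline controls followed 365–730 days (window inclusive on
the right); six severity logistics among cases, the complication models
additionally adjusted for years since diagnosis. The `standardize_score`
switch lets recovery analyses pass a score already on its natural scale
(e.g. the true liability) without re-standardization inside a selected
subsample, which would silently rescale the estimand.

Study-wise significance uses a Bonferroni threshold of α/28 ≈ 0.0018 over a
28-comparison registry (FH association; the four comparison-model terms;
AOD, prediabetes, incidence, treatment and complication terms; one
replication-stratum association). The registry is a reconstruction — the
set of "28 independent comparisons" is not enumerable from public
information — and is fully replaceable by the caller.

## What the synthetic data does and does not show

The generator reproduces, from one latent variable, the qualitative
phenomena the analyses target: FH–PGS association, monotone prevalence and
incidence gradients across score ventiles, earlier diagnosis and higher
prediabetes/severity odds at higher genetic risk, and the
sensitivity/specificity trade-off of PGS-augmented screening. It does not
contain linkage disequilibrium, rare large-effect variants, cross-ancestry
allele-frequency or effect-size differences (ancestry labels mark subcohorts
for stratified re-runs but share one generative model), survey biases,
X-chromosome dosages, or time-to-event structure for complications. Passing
tests therefore demonstrate the *correctness of the machinery* (estimators
recover known truths; rule algebra and orderings hold exactly), not that any
particular real-cohort effect size would be reproduced. Per-PGS-SD effects
in pipeline output are attenuated relative to the per-liability-SD generator
truths by the score–liability correlation, which at desk-scale training
sizes is substantially below the values attainable with hundreds of
thousands of training samples; the recovery analyses therefore fit against
the true liability, and the C+T score's behaviour is checked for direction,
calibration under the null, and ordering properties instead.

## Numerical and design choices

* Logistic Newton/IRLS tolerance 1e-10 (scan) / statsmodels defaults
  (models); divergence and separation are flagged.
* Percentile bootstrap defaults to 2,000 replicates in library calls;
  pipeline configs may reduce it (the acceptance script uses 400) —
  problem sizes there (tens of thousands of participants, hundreds of
  SNPs) are chosen to keep a full run in the low minutes on one core while
  leaving every estimate's sampling error small relative to the effects
  probed.
* Intercept calibrations use Brent root-finding on [−30, 30] with 1e-10
  tolerance; an infeasible prevalence target raises a parameter error.
* Clumping and selection tie-breaks are fixed (documented above) so the
  whole pipeline is deterministic; manifests contain content hashes and no
  timestamps.
* Cohort tables are TSV with empty fields for missing values; treatment and
  complication sets are encoded as boolean flag columns; scoring files use
  the PGS Catalog column layout with `#key=value` headers carrying the
  standardization reference.

## Known limitations

Distance-only clumping is the correct match to LD-free simulated data but
will over-prune real densely-genotyped regions; the GWAS scan is
single-cohort (the meta-analysis combiner is provided but not a full
multi-ancestry pipeline); crude incidence rates ignore censoring beyond the
follow-up window; complication models are cross-sectional logistic, not
survival; all liability relationships are linear on the probit/logit scale
by construction, so the suite cannot detect non-linear age or BMI effects.
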