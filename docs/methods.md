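# Methods

## The question and the estimand

A clinical 10-year CVD risk score flags a subject as *high risk* when it
crosses a guideline threshold (QRISK2 ≥ 10%; PCE ≥ 7.5%; SCORE2 age-banded
2.5/5/7.5%). The integrated risk tool (IRT) updates the clinical risk with a
standardised polygenic score on the log-odds scale and is read against the
*same* threshold. The estimand is the difference in sensitivity among
incident cases between the union rule (high by clinical score or IRT) and
the clinical score alone. Because the union rule can only add positives,
its down-classified cell is structurally zero and the uplift equals b/n,
where b is the number of up-classified cases. Inference uses the standard
Wald variance for a paired difference of proportions computed from the
discordant counts, `var = (b + c − (b−c)²/n)/n²`; single sensitivities get
Clopper–Pearson exact intervals (this choice reproduces published intervals
of this design exactly at printed precision, which Wilson intervals do not).

## The integrated risk tool

`IRT = expit( logit(p_clin) + β·z − β²/2 )`, with z the ancestry-standardised
PRS and β the log-odds per SD. β is **not** published for the original
tool; the package default is `log(1.6)` per SD — a typical validated effect
for genome-wide CVD scores — and it is an explicit, documented assumption
exposed in `IRTConfig`. The offset β²/2 makes the update mean-preserving
when z ~ N(0,1) independent of the clinical score (E[e^{βZ−β²/2}] = 1), so
the population-mean event odds are unchanged; it can be set to 0 to mimic an
uncalibrated combination. A single global offset is used (no age/sex
strata). The IRT inherits the clinical score's threshold scheme unchanged.

## Synthetic cohort generator

The generator defines the study conditions for every test:

* **Covariates** (independent draws; only marginals are specified): age
  N(57.5, 9.4) truncated to [40, 74]; 62% male; 76.5% white ethnicity
  (non-white labelled South Asian, the dominant group in the population
  emulated); smoking current/ex/never = 0.31/0.19/0.50; SBP N(133, 16);
  BMI N(27.9, 5.3); total cholesterol N(5.5, 1.1) and HDL N(1.4, 0.4)
  mmol/L; diabetes 2.4%; baseline statin use 10.5%.
* **Clinical score**: a logistic *surrogate* of QRISK2 (QRISK2 itself is a
  licensed algorithm and is treated as data everywhere else), with
  hand-chosen plausible log-odds coefficients (age 0.085/yr, male 0.45,
  current smoking 0.55, SBP 0.016/mmHg, BMI 0.025, TC/HDL ratio 0.18,
  diabetes 0.9, South Asian 0.30). Its intercept is calibrated by 1-D root
  finding so the population-mean 10-year risk equals the configured
  `baseline_event_rate` (default 0.10, a typical mean 10-year risk for this
  age range). `risk_model="constant"` puts every subject exactly at the
  baseline rate, which makes closed-form and quadrature oracles available.
* **Genotypes**: Binomial(2, af) hard calls — exactly Hardy–Weinberg at the
  drawn frequency (af uniform on (0.05, 0.5) by default), no LD, no
  imputation uncertainty. `inject_qc_violations` plants variants that fail
  exactly one QC filter each (extra missingness; monomorphic; all-
  heterozygote) for planted-truth recovery tests.
* **Events**: `P(event) = expit( logit(p_clin) + β·z − β²/2 )` — the exact
  generative inverse of the IRT, so parameter-recovery and sign-recovery
  experiments are well-posed. Event types are drawn from the configurable
  hierarchy mix (CVD death 5.6%, MI/ACS 57.9%, PCI/CABG 12.8%, stroke
  23.5%).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium and imputation error,
correlated covariates, time-to-event structure and censoring, miscoded GP
records, true QRISK2 scores, and genuine population stratification (the PC
structure of synthetic genotypes is noise).

## Genotype QC

Filters run in the fixed order call rate → MAF → HWE with defaults 0.98 /
0.005 / 1e-6; each removed variant is attributed to the first filter it
fails, so the report's lists are disjoint and counts are conserved. MAF is
computed from non-missing dosages folded to the minor allele; HWE uses the
two-sided conditional exact test (tail sum over heterozygote counts with
conditional probability ≤ the observed one, built by outward recurrences
from the modal count) on hard-called genotypes of **all** subjects — the
original description does not say controls-only, and all-subjects is the
pre-imputation array-QC convention. `apply_qc` is idempotent.

## PRS scoring and standardisation

Weights follow the PGS-Catalog column contract. Alignment matches by
variant id with a chrom:pos fallback, flags direct vs flipped orientation
(flipped contributes `w·(2−d)`), and excludes strand-ambiguous A/T and C/G
pairs because no strand information is modelled. Missing dosages are
imputed as twice the effect-allele frequency of the variant's observed
calls (a skip-and-renormalise policy is available); subjects missing every
scored variant are flagged, never silently scored 0. Standardisation
regresses the raw score on K principal components fitted on a reference
sample and divides by the homoscedastic residual SD, so reference subjects
have ≈0 mean and unit variance; K=0 degenerates to plain z-scoring. A
PC-dependent variance model was considered and not implemented as default
because the source description states only "approximately zero mean and
unit variance". PCs come from an input table or the truncated-SVD helper;
in the synthetic analyses the cohort is its own reference.

## Clinical risk equations

PCE and SCORE2 are evaluated from their published coefficient tables,
shipped as CSV data files with provenance headers (race/sex-specific
ln-scale proportional-hazards terms with `risk = 1 − S0^exp(lp − mean_lp)`
for PCE; centred sex-specific Cox terms with baseline survival and the
four-region double-log recalibration for SCORE2). Both are validated in the
test suite against independent re-evaluations of the shipped tables and
against their published worked examples. Cholesterol is accepted in mmol/L
(converted internally, factor 38.67) or mg/dL. Defaults: non-black
ethnicities use the white PCE coefficients (the equation authors'
fallback); SCORE2 uses the low-risk region, configurable. SCORE2's age
bands for "high risk" default to <50y: 2.5%, 50–69y: 5%, ≥70y: 7.5%; the
"low" category below a banded threshold is taken as half the band value.
High-risk boundaries are closed (≥) throughout.

## Case-control construction

Cases take one label by the fixed hierarchy (CVD death > MI/ACS > PCI/CABG
> stroke). The propensity of case status is a main-effects logistic model
on the six design covariates (age, sex, ethnicity, smoking, BMI, clinical
score). Matching is greedy nearest-neighbour on the logit propensity,
without replacement, in `ratio` passes (each case gets its k-th control
before any case gets its (k+1)-th); case order is randomised under the run
seed; the caliper defaults to 0.2×SD of the logit propensity (standard
practice; the original study states none). Cases with no in-caliper
neighbour keep fewer (possibly zero) controls and are flagged — "approximate
2:1". SMD is `|m₁−m₀|/√((s₁²+s₀²)/2)` for continuous covariates and the
maximum over per-level binary SMDs for categorical ones; zero pooled
variance with unequal means reports infinity.

## Headline statistics

All are driven by the paired 2×2 reclassification counts (a, b, c, d).
Relative uplift is b over the clinically flagged count; case-NRI is
100·(b−c)/n. The odds ratio of up-classification (low-risk cases vs
low-risk controls) uses the cross-product point estimate with a conditional
exact CI obtained by inverting the noncentral hypergeometric tails, and a
Fisher exact p. Percentile enrichment reports, for each upper-tail mass q
in {20, 10, 5, 3, 1}%, the fraction of cases at or above the reference
(1−q)-quantile divided by q. Baseline tables use Student's t (equal
variances) for continuous rows and Pearson χ² for categorical rows, with
the Yates correction applied to 2×2 tables only — the convention that
reproduces published df=2 p-values of this design exactly. All p-values
are two-sided; no multiplicity adjustment. Reports round percentages to one
decimal; machine outputs keep full precision. The preventable-events model
is deliberately parameterised (newly-flagged fraction × uptake × relative
risk reduction × annual event rate × 10⁵ patient-years) because its
original inputs are supplementary and unpublished here.

## Numerical choices and problem sizes

All randomness flows from a single integer seed per run; identical
config+seed gives identical output. Degenerate inputs raise rather than
propagate: clinical risks at exactly 0 or 100% (logit undefined), zero
residual SD in standardisation, separated propensity models, empty pools.
The heavy test experiments use sizes chosen as the package's own defaults:
matching-balance replicates at n=5000, end-to-end sign recovery over 200
replicates at n=3000 with 40 variants, Monte-Carlo IRT calibration at 10⁶
draws, HWE enumeration cross-checks for all tables of ≤50 subjects, and the
demonstration analysis at n=20 000 with 150 variants.

## Known limitations

* **Matching balance at small cohort sizes.** The acceptance suite encodes
  a design target of post-match SMD < 0.1 on all six covariates in ≥95% of
  replicates at n=5000. This target is not met, and the failure is
  structural rather than a defect of the matcher: with a realistic 10%
  event rate the control pool is only ~9:1 against cases, its
  high-propensity tail cannot supply two controls per case, and greedy
  without-replacement matching (with-replacement and optimal matching are
  out of scope) necessarily leaves a one-directional 0.1–0.18 SMD on the
  clinical score — tighter calipers or different processing orders make it
  worse, not better. With rarer events the pool deepens but the
  max-over-six-covariates SMD becomes noise-bound below ~200 cases.
  Balance improves with cohort size: the n=20 000 demonstration analysis
  achieves all six SMDs < 0.1. The corresponding test is left failing by
  design as an honest record of this limit.
* The surrogate clinical score is a stand-in with invented coefficients;
  absolute risks from it are only as meaningful as its calibration step.
* β is an assumed constant, not estimated; training it is out of scope.
* No LD, no imputation, no time-to-event modelling; the event indicator is
  a single 10-year Bernoulli draw.
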