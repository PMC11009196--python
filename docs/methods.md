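# Methods

## The question the pipeline answers

Deficit-accumulation frailty indices (FIs) summarize many weakly
informative health measurements into one score: the proportion of
considered deficits an individual carries. A recurring proposal is to
replace the index with a single "frailty biomarker". This package
implements the analysis that adjudicates that proposal: for each biomarker
in a panel, four nested logistic models of mortality are compared by their
discrimination (AUC), asking whether the biomarker adds to an age-sex
model, whether the FI does, whether the FI adds on top of the biomarker,
and whether the biomarker adds on top of the FI.

## Deficit coding

Each biomarker maps to the deficit scale [0, 1] through one of three rule
kinds: a binary normal range (0 inside, 1 outside), ordinal cut-points
(value maps to the level of the highest cut-point it reaches), or min-max
normalization between two reference values with a direction flag. Three
conventions are fixed here because the usual verbal description leaves
them open: normal-range bounds are inclusive; an ordinal value equal to a
cut-point takes the higher deficit level (left-closed intervals on the
deficit-increasing axis); normalized values beyond the reference window
are clamped rather than rejected. Non-numeric raw entries are coerced to
missing with a warning, not an error, because field data routinely contain
stray annotations.

The default dictionary catalogues a 23-item blood panel and a 47-item
examination panel (5 physical performance, 9 cognitive, 7 anthropometric,
2 spirometry, 9 hearing/vision, 15 cardiac). The concrete cut-points are
plausible placeholders on clinically familiar scales (e.g. albumin normal
range 35-50 g/L); they are *not* validated clinical thresholds, and any
real analysis should supply its own dictionary file.

## Frailty index

FI = (sum of deficit values) / (number of non-missing considered items),
e.g. 20 of 40 deficits = 0.5. A score is defined only when at least 80% of
the considered items are non-missing; the threshold is inclusive and is
evaluated against the considered set, so a 22-item leave-one-out FI needs
ceil-free 0.8 × 22 = 17.6, i.e. at least 18 items with data. No rounding
is applied to the threshold. An undefined FI is an explicit sentinel (NaN
in vector output), never silently zero, so downstream sample restriction
is auditable.

Leave-one-out variants exclude the biomarker under study from the
considered set (22-item blood FI, 46-item examination FI), so that the FI
covariate in models 3 and 4 does not contain the focal biomarker.

## Prognostic models

Per biomarker, the four models are M1: age + sex; M2: age, sex, biomarker;
M3: age, sex, leave-one-out FI; M4: age, sex, biomarker, leave-one-out FI.
All four are restricted to one common sample — non-missing demographics,
weight, outcome and focal biomarker, plus a defined leave-one-out FI — so
their AUCs are directly comparable. Analytic weights multiply each
observation's Bernoulli log-likelihood contribution (statsmodels GLM with
variance weights; IRLS, relative tolerance 1e-8, at most 100 iterations).
Coefficients are therefore invariant to rescaling the weights. Separation
is detected by a diverging coefficient norm and reported via the
convergence flag rather than silently truncated.

The biomarker enters models 2 and 4 as a single linear term on its raw
scale. This is a documented assumption, not a claim about the best
functional form: AUC is invariant to monotone recalibration of the linear
predictor, and a single-df term keeps the four models strictly nested. Sex
is coded female = 0, male = 1; age enters in years untransformed.

No coefficient-level inference is produced: the inferential surface is
the AUC comparison, and the weights are treated as importance weights in
the likelihood, not as a survey design.

## Weighted AUC and the equality test

The weighted AUC is the weighted probability that a random event outranks
a random non-event, ties half-credited:

    AUC = Σ_i Σ_j w_i w_j ψ(s_i, s_j) / (Σ_i w_i)(Σ_j w_j)

computed in O(n log n) via sorted cumulative weights (placements), not the
double sum; the double sum is retained in the test suite as the oracle.
Equality of correlated AUCs on one sample is tested with structural
components in the style of DeLong, DeLong and Clarke-Pearson: the paired
AUC covariance is assembled from weighted covariances of event-side and
non-event-side placements, and a pair is compared by
chi2 = (AUC_a − AUC_b)² / var(AUC_a − AUC_b) on 1 df. A joint k-sample
version is provided but the pipeline uses pairwise contrasts throughout.

Weight semantics: weights are normalized to mean 1 internally; effective
class sizes are then plain weight sums, and the within-class covariances
use a reliability-weights Bessel correction (Σw − Σw²/Σw), which reduces
to the classical m − 1 with unit weights and remains positive whenever a
class has two or more members. With unit weights the whole procedure is
exactly the classical unweighted one. Because no closed-form reference
exists for analytic-weight DeLong variances, the estimator is validated
against a 2,000-replicate bootstrap (15% agreement band) and a simulated
null (type-I error within binomial tolerance of 0.05) in the test suite.
Degenerate cases: identical score vectors give chi2 = 0, p = 1; zero
estimated variance with unequal AUCs raises an error rather than claiming
infinite evidence.

Confidence intervals are Wald on the AUC scale, truncated to [0, 1]; a
logit-scale alternative (`auc_ci_logit`) is available when an AUC sits
near the boundary.

## Multiple testing

Benjamini-Hochberg step-up screening at FDR q = 0.05: rank-i critical
value i/m × q, reject the k smallest p-values where k is the largest rank
with p(k) at or below its critical value; tied p-values share a fate. The
default family is one contrast type within one panel (m = 23 or 47), the
narrowest grouping consistent with per-contrast significance columns; a
pooled all-comparisons family is available as a sensitivity switch. The
implementation is cross-checked against the adjusted-p formulation in the
tests.

## Synthetic cohort generator

The generator emulates the statistical structure of a large
community-dwelling cohort aged 45-85, so the full pipeline can be
exercised and tested without restricted data. What it reproduces, with
default values:

| quantity | default target |
| --- | --- |
| cohort size | 30,000 |
| age mean (SD), range | 59.4 (9.9), 45-85 years |
| % female | 50.3 |
| death prevalence | 3.1% |
| FI-Blood mean | 0.15 |
| FI-Examination mean | 0.27 |
| fully missing blood panels | 10% |
| additional per-cell missingness | 2% |

Mechanics and the reasoning behind them:

* **Ages** are truncated-normal. The configured mean/SD are the moments of
  the *realized* (truncated) distribution: the underlying location and
  scale are solved numerically (for the defaults: location 47.2, scale
  18.5), because truncating N(59.4, 9.9²) to [45, 85] would realize mean
  60.8 and SD 8.4 and miss the targets.
* **A single latent vulnerability factor** (standard normal) is shared by
  all deficits and by mortality. This is the simplest structure that
  produces the premise under study — many weakly informative items whose
  aggregate is strongly informative. Per item the deficit propensity is
  logit-linear: intercept + 0.4 per decade of age + 0.5 per SD of the
  latent factor, plus N(0, 1) item noise for graded items.
* **Per-item intercepts** are calibrated by deterministic midpoint-
  quadrature root-finding so each item's expected coded deficit hits its
  target; targets are spread evenly across 0.08-0.22 (blood) and 0.17-0.37
  (examination), making the panel means 0.15 and 0.27 exactly.
* **Raw values invert the coding rule**: binary items draw inside the
  normal range (no deficit) or above it (deficit), keeping the raw-risk
  relation monotone; normalized/ordinal items place the graded severity on
  the rule's raw scale. Re-coding a generated table reproduces the
  simulated deficit process exactly.
* **Mortality** is logistic in age (0.9 per decade), male sex (0.45) and
  the latent factor (0.8), with the intercept calibrated to the target
  prevalence (quadrature default −4.355; `calibrate_mortality_intercept`
  re-solves it on a smooth pilot criterion for any configuration). The
  age and sex coefficients were chosen once so that decedents are about a
  decade older and clearly more often male than survivors, the familiar
  qualitative pattern in such cohorts.
* **Missingness is MCAR**: a 10% chance the whole blood panel is absent
  (no blood draw), then independent 2% per-cell missingness. No real
  missingness mechanism is claimed; MCAR keeps FI means unbiased.
* **Analytic weights** default to 1; a switch draws light random weights
  (uniform on [0.5, 2], normalized to mean 1) to exercise weighted code
  paths. The real survey weights of any target study are consumed, never
  derived, by this package.
* **Seeding**: one root seed, with independent named substreams (age, sex,
  latent, each biomarker, mortality, missingness), so adding an item does
  not perturb other columns and identical configs are bit-reproducible.

What the generator does **not** emulate: survey sampling design and
inflation weights, informative missingness, time-to-event structure
(the outcome is binary death by a censoring date), item-specific
measurement error models, or real clinical cut-points. Passing tests on
synthetic cohorts therefore demonstrate the correctness and internal
consistency of the machinery and the qualitative index-vs-biomarker
asymmetry, not any quantitative claim about a real cohort. In particular
the realized FI standard deviations (≈0.10 for both panels) are a
consequence of the single-factor structure, and per-biomarker AUC values
depend on the chosen loadings.

## Problem sizes used in the checks

The calibration checks run the generator at its default n = 30,000; the
end-to-end panel checks run both full panels at that size (about half a
minute per panel). Monte-Carlo suites use 1,000 random instances for the
AUC oracle, 2,000 bootstrap replicates (n = 2,000) for the variance check,
and 2,000 simulated nulls (n = 400) for the type-I error check — sizes at
which the binomial tolerance bands in the tests are meaningful.

## Known limitations

* The default dictionary's cut-points are placeholders; results on
  synthetic data say nothing about which real biomarkers matter.
* The weighted DeLong variant treats weights as relative frequencies;
  design-based inference (stratification, clustering) is out of scope.
* Binary-coded items lose any dose-response information in models 2 and 4,
  where the raw value enters linearly; with the default generator this
  makes single blood biomarkers weak predictors by construction.
* The BH family definition (per contrast × panel) is an interpretation;
  the pooled alternative is provided because the "right" family depends on
  the scientific question.
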