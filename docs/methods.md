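# Methods

## The model being audited

The baseline predictor is a multinomial (baseline-category) logistic
regression of PAM50 subtype on five clinical covariates. With Luminal A as
the reference class, each non-reference class k has a linear predictor

    eta_k(x) = beta_k0 + beta_k1*age + beta_k2*er + beta_k3*pr
               + beta_k4*her2 + beta_k5*stage

and P(k|x) = exp(eta_k) / sum_l exp(eta_l) with eta_ref = 0. Receptor
statuses are dummy-encoded (positive = 1), stage enters as a single
ordinal numeric 1–3 (substages collapse to their parent; stage IV and
unstageable records are excluded with a warning so the ordinal covariate
stays well-defined), and age enters in raw years (a centering flag
exists; raw years keep the intercepts interpretable). The reference class
defaults to Luminal A, the most prevalent subtype; fits are invariant to
this choice up to the standard coefficient transformation, which the test
suite verifies through predicted probabilities.

The likelihood is maximized by full Newton–Raphson with step-halving
(the log-likelihood never decreases along iterations), gradient max-norm
tolerance 1e-8, at most 100 iterations, and no regularization by default.
Standard errors come from the inverse observed information. Two
degenerate regimes fail loudly rather than silently:

* rank-deficient designs are rejected with the collinear columns named;
* quasi-complete separation — coefficients diverging with a
  still-improving likelihood at the iteration cap, or apparent gradient
  convergence with |beta| > 15 after the probabilities saturate — raises
  an error that suggests the optional small ridge penalty. Empirically
  the synthetic default truth separates frequently below n ≈ 500 (the
  rare Normal-like × HER2+ cell is often empty), which is why the
  statistical test fixtures use n ≥ 600.

Diagnostics follow the conventional screens: McFadden pseudo-R² =
1 − l(fitted)/l(intercept-only); per-covariate VIF from OLS of each
covariate on the rest (flagged above 5, infinite sentinel on exact
collinearity); per-coefficient Wald z tests with two-sided normal
p-values and deliberately no multiplicity adjustment (a documented caveat
— families of 24 tests at alpha = .05 will contain false positives). The
a-priori power helper uses the one-sample z-approximation
n = ceil(((z_{1-alpha/sides} + z_{power})/d)^2); for d = 0.25,
alpha = .05, 80% power it returns 99 one-sided and 126 two-sided — a
sometimes-quoted figure of 98 for these settings is reproduced by
neither convention, and the function returns the formula string so the
discrepancy is visible rather than papered over.

## Perturbation attribution (pseudo-SHAP)

The attribution of covariate j to class k is the cohort mean of
dP_ijk = P(k | perturb(x_i, hi)) − P(k | perturb(x_i, lo)). Perturbation
conventions, chosen where some convention is required:

* **binary_contrast** (default for ER/PR/HER2): hi sets the dummy to 1
  for every patient, lo to 0. The score is the full negative-to-positive
  effect, undiluted by the feature's prevalence.
* **binary_toggle_up**: hi sets to 1, lo keeps the observed value, so
  already-positive patients contribute exactly zero and the mean is the
  contrast mean diluted by the negative prevalence (an identity the test
  suite checks on identical-row designs). Retained behind a flag because
  the two readings of "toggled from negative to positive" differ for
  already-positive patients; tables always record which mode produced
  them and the two are never mixed.
* **ordinal_shift** for stage: +1 grade, clamped to the 1–3 range.
* **continuous_shift** for age: +1 observed standard deviation (some
  scale is needed to make a continuous effect comparable to a binary
  toggle; one SD is the conventional standardized choice).

Probabilities sum to one, so each feature's dP vector sums to zero over
classes for every patient; the `AttributionTable` enforces the cohort
version of this conservation law at 1e-10 and refuses to construct
otherwise. Interactions and higher-order attributions are out of scope by
design: the method is a first-order, additive audit.

With multiply imputed data the attribution runs on each completed cohort
and the m tables are averaged (`average_attribution_tables`); running on
complete cases only is equally supported by passing that cohort instead.

## Exact Shapley oracle

The validation oracle is the interventional (marginal) Shapley value with
an empirical background: v(S) is the mean prediction over background rows
with the features in S pinned to the explained patient's values, and

    phi_j = sum_{S subset F\{j}} |S|!(p-|S|-1)!/p! [v(S u {j}) - v(S)]

is enumerated exactly over all 2^5 coalitions (guard at p = 12). Per
observation and class, efficiency holds by construction:
sum_j phi_j = P(k|x) − mean background prediction, verified at 1e-10, as
is agreement with an independent permutation-form implementation.

**Comparing the oracle with dP.** Raw signed phi_j(x), averaged over the
same cohort that supplies the background, cancels toward zero by the law
of total expectation — a positive patient's positive phi offsets a
negative patient's negative phi — so cohort-mean raw phi carries no
directional signal and cannot be meaningfully rank-correlated with mean
dP. The comparable quantity is the **Shapley contrast**: for feature j,
phi_j evaluated at the perturbed-hi instance minus phi_j at the
perturbed-lo instance, averaged over patients. This is the
coalition-weighted counterpart of dP (only coalitions containing j
survive the difference), reduces to dP exactly for a two-class model with
a single binary feature, and preserves the per-feature class conservation
law. `mean_shapley` defaults to this contrast mode; the raw average is
available as `mode="observed"` and every table records its mode. The
background is a seeded 200-row subsample of the design (all rows when the
design is smaller), balancing the 2^5 × background × cohort evaluation
count against Monte-Carlo noise in v(S).

Concordance between attribution table and oracle is Spearman rank
correlation over the 25 flattened feature × class means (the granularity
at which directional importance is reported); per-observation pooling is
available and labeled. Ties get average ranks; the p-value is the
t-approximation, replaced by an exact permutation computation for n ≤ 8.

## Synthetic cohort generator

The generator emulates the structure of a TCGA-BRCA-like complete-case
clinical cohort so that every downstream stage is testable without any
download, and its defaults are the study conditions of the test suite:

* n = 691 patients by default;
* ER+ prevalence 0.75, PR+ 0.65, HER2+ 0.18; ER–PR association via a
  configurable odds ratio (default 4, biologically motivated — PR
  expression is largely ER-dependent);
* age ~ Normal(58, 13) truncated to (18, 95) years; stage probabilities
  (0.18, 0.57, 0.25) for I/II/III;
* subtype labels drawn from the softmax of a known coefficient matrix
  beta* on the same design scale the fitted model uses. The default
  beta* encodes the qualitative clinical directions — PR positivity
  raises the luminal logits and strongly suppresses Basal-like
  (pr coefficients +0.3 LumB, −2.8 Basal), HER2 positivity drives the
  HER2-enriched logit (+3.2), ER/age/stage contribute little — with
  intercepts placing a typical patient (age 58, ER+/PR+/HER2−, stage II)
  at a Luminal-A-dominant profile. Magnitudes were chosen once for sign
  structure and a realistic subtype mix (~45% LumA); they are not
  calibrated to reproduce any particular published attribution values,
  precisely so that sign-level agreement is a genuine prediction of the
  audit rather than a circular one.
* MAR missingness confined to HER2 (rate 0.10) and age (rate 0.05): the
  per-row deletion probability is a logistic function of standardized,
  fully observed drivers (stage, ER), with the intercept calibrated by
  root-finding so the marginal rate is exact. The subtype label is never
  deleted, and a driver may not itself be a deletion target.

What the generator does **not** emulate: gene expression, batch/site
effects, measurement error in receptor assays, informative (MNAR)
missingness, and any real ER–stage–age dependence structure beyond the
ER–PR odds ratio. Passing tests therefore demonstrate correctness of the
pipeline's statistics under an additive-logit, MAR world — not that a
real cohort's attributions would match.

## Multiple imputation

Chained equations with m = 5 imputations and 10 sweeps (conventional and
cheap at this scale), per-column methods being the standard defaults of
chained-equation implementations: a logistic draw for binary HER2
(fit on currently observed/imputed predictors, then Bernoulli draws from
the predicted probabilities) and predictive mean matching with k = 5
donors for age (so imputed ages are always observed donor values).
Predictors are all other clinical columns plus the subtype label —
including the outcome in imputation models is standard MI practice.
Initial fill is a random draw from each column's observed values; each
chain is independently seeded from the configured seed. Pooling follows
Rubin's rules: Qbar = mean estimate, W = mean squared SE, B = between
variance (divisor m−1), T = W + (1+1/m)B, small-sample
df = (m−1)(1 + W/((1+1/m)B))², with B = 0 reported as infinite df. With
zero missingness the m completed cohorts equal the input exactly, so
pooled estimates coincide with the complete-case fit — an identity the
tests assert bitwise.

## Numerical conventions and degenerate inputs

* Softmax evaluations subtract the row max before exponentiating;
  log-likelihood terms clip probabilities at 1e-300.
* Argmax label-shift ties resolve to the earlier class in label order
  (reference first) — deterministic by construction.
* Threshold alerts use strict inequality (|mean dP| exactly at the
  cutoff does not alert) on the absolute value: negative over-reliance
  is as actionable as positive. Default cutoff 0.25, persistence k = 3
  consecutive batches for drift flags (k is a convention; it is echoed in
  every report).
* Unparseable receptor/status cells read as missing rather than erroring;
  genuinely absent mandatory columns are a schema error naming the
  column.
* Zero-observation subtype classes are dropped from the design with a
  warning; fewer than two observed classes is an error.
* One global seed fans out to per-stage seeds through a fixed
  SeedSequence splitting rule, so any stage can be re-run independently
  and reproduce downstream artifacts bit-identically.

## Problem sizes used by the test and acceptance runs

Concordance runs on an n = 2000 cohort with a 200-row background
(≈ 2000 × 2^5 × 200 model evaluations per feature, vectorized); the
null-feature analysis on n = 5000; property suites use n = 600–2000 and
10 seeds. These sizes make each statistic stable while keeping a full run
of the suite under a minute of compute for the heavy tests.

## Known limitations

* The attribution is first-order: interactions, nonlinearity and
  collinearity-induced instability are invisible to it by construction.
* Mean dP for a truly null feature is bounded away from zero only in
  expectation: fitted-coefficient noise of order se(beta) leaks into
  |mean dP| at roughly p(1−p)·se, i.e. ~0.01–0.03 at n = 5000 for a
  binary covariate — the null-feature acceptance quantity measures
  exactly this leakage and should be read as an estimator-noise floor,
  not as a method failure.
* Calibration (Brier) and discrimination (AUC) of the audited model are
  deliberately not computed; the audit concerns attribution, not
  predictive quality.
* The Shapley oracle applies the multinomial model per class; a per-class
  binary ("one-vs-rest") oracle would differ and is not implemented.
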