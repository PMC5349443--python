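# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Synthetic cohorts

The generator draws data with the exact statistical structure the analysis
assumes, so downstream estimates can be compared with known truth.

All structural paths are on the correlation scale (every latent and every
standardized variable has unit variance), because the effects the pipeline
reports are standardized coefficients. Per subject:

- `APOE ~ Bernoulli(p_e4)`, default `p_e4 = 0.39` (the carrier fraction of
  the cohort this design targets); the structural equations use the
  standardized carrier indicator.
- Each analyte latent `M_j = c_j·APOE_std + noise`, variance 1.
- `δ = a·APOE_std + Σ_j b_j·M_j + γ'Z + residual`, with the residual SD
  chosen in closed form so Var(δ) = 1 exactly (the generator refuses
  configurations whose systematic variance reaches 1).
- `g′ ~ N(0,1)` independent of everything above.
- Wave-2 indicators: `y_i = λδ_i·δ + λg_i·g′ + unique`, unit variance;
  Wave-1 indicators use a lag-correlated `δ_w1` (stability 0.8).

Defaults: `a = −0.25`; one mediator (`CRP`, c = −0.15, b = 0.15); ten
δ-only analytes (b = 0.15, c = 0) and 89 nulls, filling a ~100-analyte
panel; covariate effects on δ of −0.10 (age), +0.10 (education), −0.15
(GDS), −0.05 (HCY, HgbA1c); covariates independent except weak (0.1)
age–GDS and HCY–HgbA1c correlations. Covariate effects are applied to the
*observed* (discretized, clipped) covariate columns after in-sample
standardization, so an adjusted analysis of the written columns estimates
exactly the configured effects.

**Bifactor loading profiles.** The δ profile weights memory and function
(LMII .70, VRI .65, COWA .55, DST .50, IADL .75); the g′ profile weights
fluency/attention (.25, .30, .55, .60). The two cognitive profiles must not
be proportional: if they are, `λδλδ' + λgλg'` is numerically rank-1 on the
cognitive block and the bifactor decomposition admits a second, equally
well-fitting solution with the group factor collapsed. The chosen profiles
keep the model empirically identified and are also substantively sensible —
the dementia factor leans on memory/function, the residual intelligence
factor on speed/executive tasks.

**Severity.** Diagnosis is a three-class threshold on `δ + 0.5·noise` with
population cut points giving ≈ 41.8/20.8/37.4% NC/MCI/AD; CDR sum of boxes
is `clip(3 − 3δ + 0.5·noise, 0, 18)` rounded to half points. Any monotone
link suffices for the ROC/correlation validation stages; these are
stand-ins, not claims about how clinicians label.

**Assay artifacts** are overlaid separately (`inject_assay_artifacts`) on a
clean panel whose reads are `exp(M_j + batch shift)` — log-normal
concentrations with additive log-scale batch effects (4 batches, SD 0.3):
duplicate-read noise (CV 4%), LOW censoring below the analyte's LDD (the
population 5% quantile), gross outliers (0.5% of cells replaced ≥ 4
pre-injection SDs from the mean, both reads consistently so the pair
survives duplicate reconciliation), and 2% missing cells. Cohort-side item
missingness (indicators, GDS, HCY, HgbA1c) is MCAR by default with an MAR
option (probability increasing as δ falls) to stress FIML.

What the generator does **not** emulate: real marginal distributions of RBM
analytes, real covariate demographics, informative dropout between waves,
plate-position effects, or cross-assay drift. Passing tests demonstrate the
statistical machinery under the assumed structure; they say nothing about
model misspecification on real data.

## Panel QC

Fixed order: reconcile duplicates → resolve LOW → delete 3-SD outliers →
log/standardize → batch-residualize. Choices where the rules leave room:

- The 5% duplicate rule uses |r1 − r2| / mean(r1, r2) — symmetric and
  scale-free; surviving pairs are averaged (minimizes assay noise).
- The LOW fraction is computed over non-missing cells; strictly more than
  50% LOW drops the analyte, exactly 50% retains it.
- The outlier pass is single-shot (mean and SD from the full pre-deletion
  column) and runs on the **raw** concentration scale, before any log
  transform; the order is configurable in the per-stage functions. On
  log-normal analytes this deletes a small number of genuine upper-tail
  values — that is the rule's behavior, not a bug.
- "Highly skewed" means |sample skewness| > 1 (standard rule of thumb);
  zeros are shifted up by half the smallest positive value before logging,
  and the shift is recorded.
- Batch adjustment is OLS on reference-coded batch dummies with an
  intercept, then re-standardization; a singleton batch fits its point
  exactly (zero residual) and is warned about.

Every drop/deletion is counted per analyte in the QC report and the counts
are conserved (cells in = retained + missing + removed). QC touches only
the panel, never the cohort table.

## The SEM engine

Models are specified in RAM form (directed-path matrix A, symmetric
covariance matrix S, means M; implied moments `Σ = F(I−A)⁻¹S(I−A)⁻ᵀF'`,
`μ = F(I−A)⁻¹M`). Free entries carry labels; shared labels are equality
constraints, which is also how multi-group constrained fits are expressed.

- **Complete data:** minimize `F_ML = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p` with the
  1/N (maximum-likelihood) sample covariance, so FIML with no missing cells
  degenerates to ML exactly. The chi-square keeps the classic `(N−1)·F_ML`
  scale.
- **Missing data:** the casewise normal log-likelihood accumulated over
  missing-data patterns (pattern-level sufficient statistics, so cost scales
  with the number of patterns, not rows); the chi-square is the likelihood
  ratio against the saturated model, whose maximum is found by EM. Rows with
  no observed values are dropped with a warning.
- One analytic gradient serves both estimators, derived from
  `dΣ = dU·S·U' + U·dS·U' + U·S·dU'` with `U = F(I−A)⁻¹`; it is verified
  against finite differences in the tests.
- Variances are optimized on the log scale and bounded below at exp(−30) so
  boundary (Heywood) solutions stall at the edge instead of collapsing the
  likelihood; near-zero unique variances are reported as Heywood cases.
- Optimization is L-BFGS-B from fixed deterministic starts (loadings 0.7,
  uniquenesses 0.5, regressions 0), followed by a dense-BFGS polish that
  tightens the solution to the float64 floor of the chi-square-scale
  objective — needed for the exact-identity checks (FIML↔ML agreement,
  path-algebra conservation). Exogenous moments and means additionally start
  at sample values, and pure path models can opt into per-equation OLS
  starts (`start_from_data`), which the screening stage uses; all starts are
  deterministic functions of the data, so runs are reproducible.
- Standard errors: square roots of the diagonal of `2·H⁻¹`, where H is the
  numerically differentiated (central differences of the analytic gradient)
  Hessian of the chi-square-scale objective at the solution — the observed
  information. They are computed lazily, only when a caller asks.
- Fit indices: CMIN/DF, CFI against the independence baseline (closed form
  `−(N−1)ln|R|` for complete data; factorized univariate likelihoods under
  FIML), RMSEA. A saturated model (df = 0) returns an explicit undefined
  sentinel. The χ²-difference test returns the exact survival-function
  p-value and flags negative differences instead of clipping them.

## dEQ construction and scoring

Indicators are standardized before fitting — this is scaling only, not
covariate adjustment; no covariates enter the measurement model. dEQ loads
on all five indicators, g′ on the four cognitive ones, both identified by
fixed unit variances (keeping the two factors on comparable standardized
scales), orthogonal by a fixed zero covariance. Residual covariances default
to none; callers may list specific pairs (no automated search).

Composite scores use regression-method weights. Subjects with missing
indicators are scored with weights re-derived from the observed
sub-covariance — the exact conditional-expectation analogue of renormalizing
the weight vector — and the per-pattern counts are logged. Score orientation
is chosen so higher dEQ means better cognition/function (risk effects are
negative); flips are recorded.

Two properties of regression scores matter downstream:

1. **Attenuation.** The dEQ composite correlates ~0.86 with the true δ under
   the default design, so standardized paths onto the composite are shrunk
   by roughly that factor (a planted −0.25 is estimated near −0.22). The
   proportion mediated is immune: the attenuation factor multiplies both
   `b·c` and `a` and cancels.
2. **Cross-contamination.** Regression scores of orthogonal factors are not
   orthogonal; the g′ composite carries some δ variance, so a small
   APOE → g′-composite association appears even though APOE → g′ is truly
   zero. The dEQ-vs-g′ contrast (AUC difference, path-size ratio) remains
   clear-cut.

ROC validation (AD vs NC, MCI excluded) is restricted to complete cases,
uses the Mann–Whitney AUC with the Hanley–McNeil normal-approximation CI,
and reports AUC ≥ 0.5 by orientation convention (flips logged).

## Mediation screen

Covariate adjustment is simultaneous (covariate paths inside the model, the
exposure and covariates freely intercorrelated) rather than residualization
before fitting; with standardized variables the single-group model is
saturated, so per-analyte fit indices are reported only where df > 0
(constrained multi-group fits). Batch dummies are *not* re-entered in the
analyte equation: QC has already residualized analytes on batch, making the
dummy coefficients identically zero; re-adding them would only burn df and
runtime.

Path labels follow this report's convention — `a` = direct APOE → dEQ,
`b` = analyte → dEQ, `c` = APOE → analyte — which inverts the textbook a/b
mediation notation; the results schema documents the mapping. Tests are
two-sided throughout. The proportion mediated is `indirect/(indirect +
direct)` — MacKinnon's standard ratio — reported only when the indirect and
total effects agree in sign.

Classification uses a fixed dual gate (default p < 0.001 on both b and c,
a Bonferroni-style fixed threshold rather than α/m; the panel size m is
recorded for transparency). Analytes with both paths significant at 0.05
but not at the gate are flagged as trend mediators without changing their
class, so the three classes always partition the panel exactly.

Split-half replication: a seeded random permutation splits subjects 50/50
(odd subject to group 1); a, b, c are constrained equal across the halves
and the χ² worsening against the free two-group fit is tested on 3 df;
p > 0.05 counts as replication and the mediation effect is recomputed from
the constrained fit. A random split is homogeneous by construction — it
tests estimator stability, not subgroup structure. To test path homogeneity
across a *known* partition (site, ethnicity, a suspected subpopulation),
pass that partition via the `groups` argument; this is also how the
heterogeneity-power property is exercised in the tests, since planted
subpopulation differences are invisible to a random split.

## Problem sizes used in tests and the acceptance script

Chosen once as the package's study conditions: parameter recovery and
split-half calibration use 100 simulated cohorts of n = 3,000 with the
single planted mediator; the null false-positive rate uses one cohort of
n = 1,000 with 2,000 null analytes generated artifact-free, so the rate
isolates the inferential gate rather than QC attrition; the
Sobel-vs-bootstrap comparison uses a 12-analyte complete-data panel at
n ≈ 3,000 with 2,000 bootstrap draws per analyte; oracle comparisons use
n = 20,000 so sampling error is negligible against the 1e-3 agreement
bound; ground-truth covariance convergence is checked at n = 50,000.

## Known limitations

- No robust or weighted-least-squares estimators, no ordinal-indicator
  machinery, no modification indices, no bootstrap standard errors.
- The bifactor arrangement (dEQ on all five indicators, g′ cognitive-only,
  orthogonal) is one operationalization of "the cognitive correlates of
  functional status"; alternative homolog constructions (e.g. a residualized
  second-order factor) are not implemented.
- Composite-score mediation inherits the attenuation described above; a
  full latent-outcome mediation model would avoid it at the cost of
  per-analyte measurement-model fits.
- The QC order (outlier deletion before log transform) is a recorded choice;
  the per-stage functions can be recomposed in the other order.
- FIML assumes missing-at-random; the MAR generator option exists precisely
  to probe that assumption's failure modes, not to license it.
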