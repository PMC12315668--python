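# Methods

## Estimator

The cross-lagged panel network treats each of the five constructs
measured at wave *t+1* as a regression target and all five constructs at
wave *t*, plus covariates, as predictors. Estimation is node-wise
L1-penalized least squares,

  min over (b0, b) of (1/2n)·Σ (y − b0 − Xb)² + λ·Σ|b|,

solved by cyclic coordinate descent with soft-thresholding on the Gram
system (X'X/n, X'y/n), zero initialization, fixed cyclic order, and
convergence when the largest coordinate update falls below 1e-8.
Predictors are centered and scaled to unit population SD internally and
coefficients are reported back on the caller's (globally standardized)
scale, so edges are comparable across targets. The penalty grid has 100
log-spaced values from λ_max = maxⱼ |⟨xⱼ, y⟩|/n (the smallest penalty
with empty support) down to 10⁻³·λ_max. λ is selected per node by
10-fold cross-validation on a seeded participant partition shared across
the five node regressions; the default rule is the CV minimum, with ties
broken toward the larger (sparser) penalty, and the one-SE rule is
available as an option. Covariates (age at the earlier wave; optionally
gender, both standardized before entering the penalized design) are
predictors only and never targets. The gender sensitivity refit keeps
age and adds gender rather than replacing it.

Missing data are handled by listwise deletion per wave pair, matching
the complete-case inclusion rules below; no imputation or FIML.

## Preprocessing rules

1. **Outliers** — cells of the go/no-go summaries (mean correct-go RT,
   commission errors) with absolute z ≥ 4 are set missing. Moments are
   computed in a single pass per variable per wave, with no iterative
   re-standardization after removal; a zero-SD vector removes nothing.
2. **Inclusion** — participants must be complete on all six wave-1
   measures; each wave-pair analysis additionally requires completeness
   on that pair's node inputs (which for waves 2→3 subsumes the
   availability of wave-3 symptom scales).
3. **Harmonization** — wave-3 symptom sums come from the CBCL (age < 18)
   or the ABCL (age ≥ 18); each instrument subgroup is z-standardized
   separately before pooling.
4. **Working memory** — backward digit and corsi spans are each
   z-scored (sample SD) then averaged per participant; a participant
   missing either indicator gets a missing aggregate.
5. **Orientation** — RT and commission errors are negated so higher =
   better on every cognitive node. Negation precedes standardization
   (the two orders are equivalent after z-scoring).
6. **Standardization** — the five nodes are z-scored within wave on the
   wave-pair analysis sample.

Every step logs the moments it used into a report that can be replayed
on the raw input to reproduce the node table bit-for-bit.

## Synthetic cohort generator

Five latent constructs (internalizing, externalizing, working memory,
inhibition speed, inhibition accuracy; cognition oriented higher =
better) follow

  z⁽¹⁾ = ε + trend₁ + shift₁·HR,
  z⁽ᵗ⁺¹⁾ = Lᵗ' z⁽ᵗ⁾ + a·(age − age mean) + σ·ε + trendₜ₊₁ + shiftₜ₊₁·HR,

with one lag matrix L per wave pair (both spectral radius < 1, validated
at construction), innovation SD σ = 0.8, and small positive age effects
(0.05/year) on the cognitive nodes. The default truth is sparse with
cross-lagged magnitudes 0.15 and 0.3 and autoregression 0.4, arranged so
that inhibitory control is a risk factor for externalizing problems,
symptoms constrain working memory, the executive functions mutually
facilitate each other, and the middle-adolescence transition is denser
and more reciprocal than the early one.

Measurement: the two span indicators load √0.46 on latent working
memory with unit-variance residual completion, so their population
correlation is exactly 0.46 at wave 1 (the latent wave-1 variance is
exactly 1 because the high-risk shift on working memory is zero at
wave 1, consistent with a group deficit that emerges only at the last
wave). Commission errors are Binomial(25, p) with p = 0.18 at the
latent mean, decreasing by 0.5 logits per latent SD; RT is Gaussian
(mean 450 ms, SD 80 ms, loading 0.85) floored at 150 ms; symptom sums
are linear in the latent (loading 0.9) on instrument-specific raw
scales, with the ABCL assigned to wave-3 records at age ≥ 18. Spans and
symptom scores are kept continuous rather than integer-rounded — a
deliberate simplification that leaves correlations unattenuated.

High-risk membership is Bernoulli(0.6089); the high-risk group receives
latent mean shifts of +0.5 SD on both symptom domains at every wave and
−0.2 SD on cognition at later waves only. Wave mean ages are
10.20/13.48/18.20 with a shared per-participant offset (SD 0.6 years).
Gender is an independent Bernoulli(0.53) covariate with no true effects.

Attrition is a single monotone event per participant: dropout
probability logistic(α + c·z₁) with c = −0.3 on standardized wave-1
internalizing (more symptoms → *less* dropout) and α solved by root
finding so the marginal rate equals 0.3514; the dropout wave is 2 or 3
with equal probability, and all wave variables from that wave on are
missing. Everything is bit-reproducible from a single integer seed
consumed in a documented draw order.

**What the generator does not emulate:** site effects, item-level
responses, integer span/symptom scores, measurement non-invariance
between CBCL and ABCL beyond scale location/spread, non-monotone
("returning") dropouts, and group-specific dynamics (the high-risk
contrast is mean shifts only). Passing tests therefore demonstrate the
estimator's behavior under the assumed data-generating process, not
robustness to these real-data features.

## Numerical and design choices

* **Density convention** — nonzero entries of the 5×5 lagged matrix
  (autoregression included, covariate edges excluded) over 25; under
  this convention densities of 72% and 92% are the integer counts 18/25
  and 23/25. "Nonzero" is exact: the solver produces exact zeros and no
  epsilon threshold is applied.
* **Bootstrap** — whole participants are the resampling unit (both
  waves' records move together); λ is re-selected inside every
  replicate, treating penalty selection as part of the estimator;
  intervals are percentile (2.5/97.5). Replicates that fail to fit are
  skipped and counted; more than 10% failures aborts.
* **CV-min vs one-SE** — CV-min is the default because it yields the
  dense networks this estimator is known for on data of this kind. It
  overselects null predictors by design: in our recovery experiments at
  n = 1500 with effects of 0.15–0.3 the false-edge rate is ≈ 0.55 under
  CV-min and 0 under one-SE, while both rules detect all |β| = 0.3
  edges. Sparsity-focused analyses should pass `rule="one_se"`.
* **Pooled-sample caveat** — with the default risk-group mean shifts,
  group membership acts as an omitted common cause at consecutive
  waves, so edges that are zero in the latent dynamics have genuinely
  nonzero partial coefficients in the pooled sample. Null-soundness
  checks therefore use a configuration with shifts, trends, lag
  matrices, and age effects all zero.
* **Attrition calibration** — the logit intercept is solved by Brent's
  method on the empirical wave-1 internalizing distribution; a target of
  0 short-circuits to the identity.
* **Degenerate inputs** — non-stationary lag matrices, cohorts under 10
  participants, constant targets/predictors/subgroups, and fold counts
  exceeding n are all rejected with explicit errors; coordinate-descent
  non-convergence raises an error carrying the last iterate.
* **Problem sizes** — the shipped analyses use a cohort of n = 1,992
  with b = 1,000 bootstrap replicates; the automated validation suite
  uses cohorts of 400–10,000, 100-replicate recovery and null
  experiments, and b = 200 bootstraps, sizes at which every reported
  Monte-Carlo standard error is small relative to its acceptance band.

## Known limitations

CLPN estimates conflate within- and between-person variance; the
generator's latent process is itself a single-level model, so this
package neither separates those components nor implements the panel
graphical VAR family. Contemporaneous (within-wave) networks,
centrality indices, case-dropping stability, and formal network
difference tests are out of scope.
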