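# Methods

## Model family

All models in this package are random-intercept logistic GLMMs over the
observed (person, item) cells of a binary endorsement table:

    logit P(Y_ij = 1) = theta_j + x_ij' gamma,     theta_j ~ N(0, sigma^2).

The fixed-effect vector gamma always contains the 11 criterion indicators
(no global intercept), whose coefficients are item *easiness*; reports flip
the sign to the conventional *severity* scale, where severity is the latent
level at which the item characteristic curve crosses 0.5. On top of the
indicators a `ModelSpec` may add person covariate main effects (latent
regression), products of two person covariates, item x covariate
interactions (uniform DIF terms), or item-property (LLTM) columns that
replace the indicators. With person covariates present, theta_j is the
residual person effect net of the covariate terms, so the person variance
shrinks as explanatory terms enter; it is re-estimated in every model.

The logistic residual of the latent-response formulation (variance pi^2/3)
is not a free parameter: it is realised by Bernoulli sampling through the
logit link, both in the estimator and in the generator.

Identification: 11 easiness parameters + 1 variance give the 12-parameter
covariate-free model; each additional term adds one parameter. A full
item x covariate interaction set together with that covariate's main effect
is exactly collinear and is rejected with an identifiability error before
fitting.

## Estimation

Marginal maximum likelihood. The per-person likelihood integrates the
Bernoulli product over the normal random intercept; the integral is
evaluated by non-adaptive Gauss-Hermite quadrature with nodes fixed on the
standard-normal scale (theta = sigma * node), so one rule serves all
candidate sigma values. The optimiser is L-BFGS-B on (gamma, log sigma)
with an analytic gradient assembled from posterior node weights;
convergence is declared from optimiser success plus a projected-gradient
check. Standard errors are the inverse observed information, obtained by
central differences of the analytic gradient with step 1e-4 * max(1,
|param|); the SE of sigma follows by the delta method from log sigma.

Numerical choices that matter:

- **Quadrature size.** Default 41 nodes. Refining to 61 nodes moves fitted
  parameters by ~3e-5 on realistic data, so adaptivity is omitted for
  transparency. Away from a fitted optimum — random parameter vectors
  against extreme response patterns — the integrand's mass can sit many
  prior SDs off-centre and 41 nodes is only ~1e-2 accurate in
  log-likelihood; the correctness tests therefore arbitrate the quadrature
  path against a 20 001-point dense-trapezoid oracle using a 201-node rule,
  which agrees to better than 1e-6.
- **Score equations.** At the MML optimum the *posterior-averaged* expected
  endorsement rate per item equals the observed rate to ~1e-8 (this is the
  exact score-equation identity); the *prior marginal* rate implied by
  (easiness, sigma) matches only up to an O(1/sqrt(n)) gap, a few 1e-4 at
  n = 5000. `implied_prevalence(kind=...)` exposes both.
- **Starting values.** Easiness starts at the logit of the clipped observed
  item mean, covariate effects at 0, sigma at 1.
- **Degenerate inputs.** Items observed as all-0/all-1 have no finite
  easiness MLE and abort fitting with the item named; persons with no
  observed responses are EAP-scored at the prior (0, sigma); likelihood
  *evaluation* at fixed parameters is allowed on any non-empty table.

## Inference

Wald z = estimate/SE with normal reference p-values for individual terms
(no small-sample correction); star coding *** p<.001, ** p<.01, * p<.05,
with boundary values not starred. Likelihood-ratio tests compare nested
specs; each ladder model is tested against the most recent earlier model
nested in it, so the two 23-parameter extensions are both tested against
the 19-parameter model rather than against each other. AIC = deviance + 2k;
BIC = deviance + ln(N) k with N the number of observed response cells
(persons x items minus missing) — the convention under which deviance, df
and both criteria stay mutually consistent for this model family.

The DIF scan tests one item x covariate interaction at a time, all other
items anchoring the scale, with the covariate's main effect always in the
model so the interaction measures a *differential* severity shift rather
than a group mean difference. Sign convention: a positive interaction
estimate means easier endorsement for the indicator-1 group (or per SD of a
continuous score). Whether a joint interaction model or backward selection
would be preferable is genuinely open; the one-at-a-time design was chosen
because it cannot collide with the main effect and each test has a clean
1-df null. Benjamini-Hochberg correction within covariate is available
behind a flag; the default is per-test alpha = .05. Only uniform DIF is in
scope — the Rasch family fixes discrimination equal across groups, so
nonuniform DIF is undetectable by construction here.

Two-step comparison: scoring persons by EAP under the covariate-free fit
and regressing the scores on a covariate gives slopes attenuated toward
zero, because EAPs are shrunk toward the population mean in proportion to
measurement error. The package exposes both routes and a test confirms the
joint estimate dominates in absolute value in >= 18/20 replicates.

## Synthetic data generator

`GenerationConfig` defaults emulate the reference clinical sample the
package was designed around: 573 persons, 30% female, 29% non-drinkers,
standardised personality scores with identity correlation (no inter-factor
correlations are reported for such samples; any SPD matrix can be
supplied), item severities between -2.58 and -0.99 logits,
latent-regression effects including a gender x alcohol interaction of 0.92,
and a uniform DIF map on six criteria. The residual person SD defaults to
1.50 (the residual spread once those covariate effects are modelled); the
covariate-free helper `null_config()` uses 1.60, the corresponding total
spread. The reported variance/SD pair for the covariate-adjusted reference
fit is internally inconsistent at the printed precision (2.34 vs 1.50^2 =
2.25); the generator takes the printed SD as the truth.

Covariate missingness is person-wise: with the configured probability a
person gets exactly one uniformly chosen covariate field blanked, which
matches how complete-case counts are usually reported (persons removed,
not cells). Theta and responses are always drawn from the complete
underlying covariates; the mask is applied afterwards (MCAR).

What the generator does *not* emulate: item-level Likert responses behind
the personality scores (factor scores enter directly), response
missingness, multi-drug category structure, non-normal latent
distributions, and nonuniform DIF. Passing recovery/calibration tests on
these synthetic conditions therefore shows the estimator is correct under
its own assumptions — not that real clinical data meet them.

## Descriptives

Item descriptives use the n-1 denominator SD. Unidimensionality checks use
the phi (Pearson) correlation matrix of the binary items — tetrachoric
correlations are a defensible alternative; phi was chosen as deterministic
and dependency-free, and the choice is flagged as a reproduction risk for
eigenvalue magnitudes. Both raw correlation-matrix eigenvalues and
communality-reduced eigenvalues (iterated principal-axis factoring, SMC
start, tol 1e-6, max 100 iterations, Heywood loadings clipped with a
warning) are reported, since published "EFA eigenvalues" with near-zero
trailing values are typically the reduced kind. Coefficient omega is
computed from the single-factor loadings as (sum lambda)^2 / ((sum
lambda)^2 + sum(1 - lambda^2)).

## Problem sizes used by the test suites

Correctness oracles run on 2-12 person instances; recovery checks use
n = 5000 (3 seeds) for the full explanatory model and n = 2000-3000
(20 seeds) for attenuation and DIF recovery; null-calibration uses 200
replicates at n = 500. These sizes give each check useful statistical
power while keeping the default suite in the minutes range on one core.

## Known limitations

- Non-adaptive quadrature: likelihood evaluations far from any optimum
  need a finer rule (see above).
- Wald inference and chi-square LR reference distributions are asymptotic;
  no profile likelihood or small-sample corrections.
- The one-at-a-time DIF design tests each interaction in isolation; with
  many truly DIF items the anchor set is contaminated and estimates can be
  redistributed.
- No polytomous items, no 2PL discrimination, no crossed (item) random
  effects, no nonuniform DIF.
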