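# explirt

Explanatory item response modelling (EIRM) for dichotomous diagnostic
criteria, built for the psychometrics of substance-use-disorder (SUD)
assessment: Rasch measurement of 11 DSM-5 SUD criteria, latent regression of
the disorder level on person covariates (gender, alcohol use, and four
personality risk scores), nested model comparison, and uniform differential
item functioning (DIF) scans — plus a synthetic-data generator that emulates
a clinical sample of illicit drug users, since raw clinical response data of
this kind are rarely shareable.

## The model

A person *j* endorses criterion *i* with probability

```
P(Y_ij = 1) = exp(θ_j − β_i) / (1 + exp(θ_j − β_i))
```

where θ_j is the person's latent disorder level and β_i the criterion
severity (the latent level at which endorsement probability is 0.5). As a
generalized linear mixed model with a logit link, the linear predictor is
η_ij = θ_j + x_ij′γ with θ_j ~ N(0, σ²): item indicators carry easiness
(−β_i), and the *explanatory* part enters as person covariates Z_pj with
effects J_p (latent regression), person×person interaction products, and
item×covariate interactions δ_h whose significance signals uniform DIF.
With covariates in the model, θ_j is the residual person effect after the
covariate terms.

Estimation is marginal maximum likelihood: the random intercept is
integrated out by Gauss–Hermite quadrature (41 nodes by default) and all
fixed effects plus log σ are maximised jointly by L-BFGS with an analytic
gradient. Standard errors come from the observed information; nested models
are compared by likelihood-ratio tests and AIC/BIC; persons are scored by
expected a posteriori (EAP) means. Fitting the model jointly avoids the
attenuation of the classical two-step route (EAP scoring followed by OLS),
whose slopes are shrunk toward zero by measurement error.

## Worked example

```python
import explirt as ex

cfg = ex.GenerationConfig(seed=42)           # 573 persons, reference conditions
ds = ex.simulate_dataset(cfg)
responses, covariates, n_removed = ex.filter_complete_cases(ds.responses, ds.covariates)

fit = ex.RaschModel(responses).fit()
print(f"person variance (SD): {fit.person_var:.2f} ({fit.person_sd:.2f})")
print(fit.severity.round(2).head(4).to_string())

ladder = ex.run_ladder(responses, covariates, [ex.NULL, ex.M1, ex.M2, ex.M3])
for c in ladder.comparisons:
    print(f"{c.smaller} -> {c.larger}: LR = {c.lr_stat:.2f}, ddf = {c.delta_df}, p = {c.p:.3g}")
```

prints

```
person variance (SD): 2.35 (1.53)
Larger       -0.97
Cut down     -1.91
Time spent   -1.50
Craving      -0.42
null -> m1: LR = 10.53, ddf = 2, p = 0.00517
m1 -> m2: LR = 10.08, ddf = 1, p = 0.0015
m2 -> m3: LR = 65.83, ddf = 4, p = 1.72e-13
```

The Rasch fit recovers the generator's negative severities (every criterion
is easy to endorse for this clinical population — the latent distribution
sits far above the item locations) and a person SD near the generating
1.50. Each likelihood-ratio step is the evidence that the newly added
covariate block (gender+alcohol, their interaction, the four personality
scores) explains real variation in the latent disorder level; here all
three steps reject, and in the `m3` fit sensation seeking is the dominant
personality effect. `ex.dif_scan(responses, covariates)` then tests each
criterion for a severity shift by each covariate at matched latent level.

The same pipeline is scriptable from a shell:

```sh
explirt simulate --n-persons 573 --seed 42 --out run/
explirt report --responses run/responses.csv --covariates run/covariates.csv --out run/
```

which writes `table3.csv` (descriptives + severities), `table4.csv/.json`
(model ladder), `table5.csv` (DIF), `fig1_eap.csv`, `fig2_icc_*.csv`,
`unidim.csv` (eigenvalues, loadings, coefficient omega) and an echoed run
configuration sufficient to regenerate every artifact.

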