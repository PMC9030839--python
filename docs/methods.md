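# Methods

## The measure

A household is financially distressed when its financial margin
`FM = I − DP − BLC` is negative and its liquid assets fall short of its
medical expenditure, `LA < ME`.  All monetary quantities are per capita in
CNY per year.  Income `I` and medical expenditure `ME` are random; debt
payments `DP`, liquid assets `LA`, and the basic living cost `BLC` are
treated as fixed over the short horizon of one survey wave.  Vulnerability
is the conditional probability

Δ(x, y) = P( ln I < ln(DP + BLC),  ln ME > ln LA | x, y ),

an ex ante score in [0, 1] rather than an ex post distress dummy.

`BLC` defaults to the USD 2/day/person international poverty line converted
at a configurable exchange rate (6.5 CNY/USD → 4,745 CNY/year).  The rate
is a run parameter, one value for all households, overridable per stratum.

## Margins

Both outcomes are log-normal with covariate-linear mean and variance:

ln I | x ~ N(α'x, θ'x),  ln ME | y ~ N(β'y, ω'y)

with x the income covariates (age, gender, education, married, size, labor,
area, disable, health_s) and y those plus health, diseases, and the three
insurance indicators (insur_em, insur_cm, insur_om).  Estimation is the
three-step feasible GLS standard in vulnerability-to-poverty work:

1. OLS of the log outcome on the covariates; residuals ê.
2. OLS of ê² on the same covariates; both sides are divided by the fitted
   values of that regression and the variance equation is re-estimated
   (WLS with weights 1/f², f the provisional fit), giving θ̂ (resp. ω̂).
   Non-positive provisional fits would produce sign-flipping or unbounded
   weights, so f is floored at `variance_floor` before weighting.
3. The mean equation is re-estimated with each row scaled by 1/√(θ̂'x),
   giving α̂ (resp. β̂).

Fitted variances below `variance_floor` (default 1e-4 on the log scale) are
floored and counted in the model diagnostics rather than dropped, so every
household remains scoreable.  Margins are fit per (stratum, wave) cell by
default — the published group summaries vary by stratum and year — with
pooled fits available; the model itself is time-invariant, so pooling is
also correctly specified.  Coefficient standard errors are the conventional
WLS ones from steps 2 and 3.

## Dependence

With margins G and H fixed at their FGLS estimates
(inference-functions-for-margins), the pseudo-observations
u_i = G(ln I_i | x_i), v_i = H(ln ME_i | y_i) are clipped to
[1e-10, 1 − 1e-10] (clipping engages only beyond |z| ≈ 6.36) and the copula
parameter solves γ̂ = argmax Σ log c(u_i, v_i; γ) by bounded scalar
optimisation.  Families: Gaussian (γ ∈ (−1,1)), Clayton (γ > 0), Gumbel
(γ ≥ 1), Frank (γ ≠ 0), independence.  Family CDF/density/sampling come
from statsmodels; Frank sampling at γ < 0 uses the reflection
(U, 1−V) ~ Frank(−γ), which statsmodels' sampler does not cover.

Family choice uses the standard empirical-copula Cramér–von Mises test:
pairs are rank-transformed to r_i = rank/(n+1), the parameter re-estimated,
S_n = Σ (C_n(r_i) − C(r_i; γ̂))² computed, and the null distribution built
by parametric bootstrap (simulate n pairs from the fitted copula, re-rank,
refit, recompute; p = share of bootstrap statistics ≥ observed; default 200
bootstraps).  Rank transformation is deliberate: computing S_n on the raw
parametric-margin uniforms inflates the null variance of the empirical
copula and costs most of the test's power against tail-asymmetric
alternatives.  Among families not rejected at 0.05 the highest
log-likelihood wins; if all are rejected the largest p-value is returned
with a warning and the decision trace is attached to the model.

## Evaluating Δ

With u* = G(ln(DP+BLC) | x) and v* = H(ln LA | y), the defining double
integral of c·g·h over (−∞, a] × [b, ∞) is evaluated exactly by the
rectangle identity

Δ = P(U ≤ u*, V > v*) = u* − C(u*, v*; γ).

`LA = 0` maps to b = −∞, v* = 0, Δ = u*: the asset condition then holds
with probability one, the only reading consistent with the definition.
Because the copula CDF is increasing in γ for these positively ordered
families, Δ is *decreasing* in γ everywhere on the open unit square —
stronger positive dependence between income and medical spending makes the
combination "low income and high spending" rarer.

Two independent evaluators exist purely as oracles: adaptive 2-D quadrature
of c(G(u), H(v)) g(u) h(v) on the log scale (absolute tolerance 1e-8,
integration box truncated at mean ± 10 sd) and a Monte Carlo sampler that
draws copula pairs, maps them through the marginal quantiles, and counts
distress events.  For the Gaussian family the closed form also equals
Φ(ã) − Φ₂(ã, b̃; γ) with standardized thresholds, which the tests check to
1e-10 against scipy's bivariate normal CDF.

Group summaries average Δ by the six health levels, labor-share bins
(<0.25, 0.25–0.5, 0.5–0.75, ≥0.75), or education bins (<6, 6–9, 9–12,
12–15, ≥15 years), half-open [lo, hi) with the last bin closed above,
within each (stratum, wave) cell.

## Determinant panel and decomposition

Δ_it is regressed untransformed on the fourteen determinants by pooled
OLS, the within (fixed-effects) estimator, and Swamy–Arora random effects;
standard errors are conventional.  Covariates with no within-entity
variation are dropped from the FE fit with a named warning rather than
reported — the within transform removes them, and reporting coefficients
for them would be incoherent.  Specification tests: individual-effect F
(pooled vs. within residual sums of squares, df (N−1, NT−N−K)), Hausman on
the common slopes with a pseudo-inverse fallback when V_FE − V_RE is not
positive definite, and the classical Chow F across two wave windows.
Significance markers: ** p<0.01, * p<0.05, + p<0.10.

The change in mean Δ between waves t and t+1 is decomposed as: elasticity
of determinant k = b_FE,k · x̄_k/Δ̄ (base-wave means; which wave's means
enter is configurable), absolute contribution = elasticity × percent change
in x̄_k, relative contribution = 100 × absolute/total, and a computed (never
estimated) residual closes total = Σ contributions + residual.  Binary
determinants enter through their group shares, which the change-in-means
convention covers automatically.  Published per-determinant elasticities,
changes, and contributions for the CHARLS urban/rural application are
frozen in `finvuln.reference` as worked-example inputs; reproducing their
printed contributions carries a 0.06 absolute / 0.01 relative tolerance
because the printed inputs are rounded to three decimals.

## Synthetic panels

The generator draws covariates from simple parametric families matched to
the published CHARLS urban and rural descriptive statistics (truncated
normal age; clipped rounded normal education; 1 + Poisson household size;
Beta labor share moment-matched to mean/SD; Bernoulli binaries at the
published shares; a six-level health distribution matched to the published
mean and SD), then generates (ln I, ln ME) from the measure's own model:
copula pairs mapped through the conditional-normal margins.  DP and LA are
zero-inflated log-normal, moment-matched to the published means.  Default
dependence is Gaussian with γ = 0.144 (urban) and 0.214 (rural).  Mean
coefficient defaults reproduce the published income/expenditure levels
(e.g. urban log-income mean ≈ 8.59 with variance ≈ 1 implied by the
published mean and SD of income); variance loadings put extra dispersion on
disability, health shock, and labor share.

Wave-to-wave dynamics are the package's own invention (nothing about them
is published): heads age two years; size takes ±1 steps w.p. 0.08 each;
labor share takes small Gaussian steps; health a ±1 random walk; chronic
disease, disability, and insurance take-up are absorbing switches with
small on-probabilities; the health-shock indicator is redrawn each wave;
gender, area, and education are fixed.  Specs whose linear variance model
goes non-positive anywhere on the generated support are rejected outright
rather than floored, keeping ground truth clean.  Every panel ships a
sidecar with the generative coefficients and each row's true Δ.

What the generator does *not* emulate: survey sampling design, attrition,
measurement error, item non-response, within-household correlation beyond
the modelled covariates, or any misspecification of the variance link.
Passing tests therefore demonstrate correctness of the estimators and
evaluators under the model's own assumptions, not robustness of the measure
on real survey data.

## Numerical choices and problem sizes

* Copula MLE bounds: Gaussian ±0.999, Clayton (1e-3, 30), Gumbel
  (1+1e-9, 30), Frank ±35 with the |γ| < 1e-4 neighbourhood treated as the
  independence limit; boundary solutions are recorded as warnings.
* Pseudo-observation clip ε = 1e-10; ties after clipping are broken by the
  stable ordinal ranking inside the GOF test.
* Quadrature non-convergence (estimated error above tolerance) raises with
  diagnostics instead of returning a value.
* Test-suite problem sizes are chosen to estimate each property precisely
  while keeping the default run short: FGLS recovery uses 200 replicates at
  n = 10,000 (3-SE coverage per coefficient ≥ 95%); oracle equivalence uses
  15 random parameter draws per family against quadrature (1e-6) and 8 per
  family against 2×10⁵-draw Monte Carlo (3 binomial SE); the Gaussian
  orthant check uses 1,000 draws at 1e-10; size control of Hausman/F/Chow
  uses 400 replicates each and the copula GOF 200 replicates with 100
  bootstraps at n = 150, all asserted at 0.05 ± 0.02.

## Known limitations

* The variance equations are linear in levels; a log-link variance model is
  out of scope, and negative fitted variances are floored (counted in
  diagnostics) rather than modelled away.
* The copula parameter is constant within stratum (no time-varying or
  covariate-dependent dependence) and estimation is two-stage, not full
  simultaneous MLE; two-stage standard errors for γ are not propagated.
* Fixed-effects coefficients for time-invariant covariates are undefined
  under the within transform; the package drops them rather than emulating
  published tables that print them.
* Conventional (non-clustered) standard errors throughout, matching the
  reporting convention of the application this measure comes from.
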