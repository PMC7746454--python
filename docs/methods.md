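# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `merlcross`, including the ones where the
procedure it implements was genuinely open.

## Data model

A 2×2 crossover trial: subjects in sequence AB receive treatment A in
period 1 and B in period 2; sequence BA the reverse.  Each subject
contributes four strictly positive times — baselines b₁, b₂ measured
before treatment in each period and post-treatment event times y₁, y₂ —
plus event indicators δ₁, δ₂.  Censoring is administrative: a subject
still event-free at the follow-up cap τ is censored at τ, so a censored
time always equals τ.  Baselines are assumed uncensored.  All analysis
is on the log scale, so zero times are rejected at validation.  When τ
is not supplied it is inferred as the common censored value; censored
times above a supplied τ are a validation error (censored times below
it are tolerated, to allow datasets with staggered follow-up).

## Median residual life regression

m(t₀ | x) = median(T − t₀ | T > t₀, x) = exp(x'β(t₀)), with an
intercept always included.

**Parametric route (default).**  An accelerated-failure-time model fit
by maximum likelihood with right censoring; linear predictor
μ = x'β on the log-time scale.

* Weibull: S(t|x) = exp(−(t/e^μ)^s).  Then
  m(t₀|x) = e^μ ((t₀/e^μ)^s + ln 2)^{1/s} − t₀ in closed form.
* Exponential: the Weibull with s ≡ 1; m = e^μ ln 2, constant in t₀
  (memorylessness).
* Log-normal: log T | x ~ N(μ, σ²); m is obtained by inverting the
  normal survivor analytically.

Optimisation is BFGS on (β, log s) resp. (β, log σ) with analytic
gradients for the Weibull/exponential cases, started at the OLS
solution of log t on x.  Convergence is accepted when the optimizer
reports success **or** the gradient max-norm falls below
1e-5·(1+|loglik|) — BFGS routinely reports "precision loss" with the
gradient already at machine zero.  A non-convergent Weibull fit falls
back to the exponential family with a warning.  Tolerance 1e-8 and a
2000-iteration cap are configurable.

The parametric route is the default because under administrative
censoring every censored subject sits exactly at τ and no events are
observed beyond it: the conditional survivor must be extrapolated past
τ, which only a parametric model can do.  This is also the only way
imputed times can exceed τ, as they must.

**Semiparametric route.**  At a fixed t₀, minimise the
inverse-probability-of-censoring-weighted median check loss
Σ wᵢ |log(Tᵢ − t₀) − xᵢ'β| over at-risk uncensored subjects (Tᵢ > t₀,
δᵢ = 1), with wᵢ = 1/Ĝ(Tᵢ⁻) and Ĝ the Kaplan–Meier survivor of the
censoring time (indicators flipped; computed via lifelines).  The
optimiser is Nelder–Mead started at the IPCW-weighted least-squares
solution.  With an intercept-only design the minimiser is computed
exactly as the weighted median of the residual lifetimes; an
even-weight split resolves to the midpoint of the two central order
statistics, matching the usual summary-median convention.  Fewer than
`min_events` (default 5) events beyond t₀ raises a degenerate-risk-set
error pointing to the parametric route.

## Sequential imputation

Period 1 is completed first: one model pooled over both sequences, with
default covariates `treatment` (1 = treatment A in that period), `age`
(dropped automatically when absent) and the period baseline.  Each
censored y₁ becomes t₀ + m(t₀ | x) with t₀ its own censoring time.
Period 2 then additionally conditions on the **completed** period-1
outcome; an `include_b1` flag also adds the period-1 baseline, whose
membership in the period-2 model is ambiguous in the source analysis.
The audit table records subject, period, t₀, predicted median residual
and the final imputed time.

Covariate lists are fully configurable
(`ImputationConfig.period{1,2}_covariates`); a `log_` prefix enters a
time-valued covariate on the log scale.  Two specification issues
matter in practice:

* **Covariate scale.**  With a time-valued covariate entering the
  exponent linearly, predictions grow exponentially in the covariate;
  for unbounded baselines (as in the simulation marginals) a handful of
  large draws produce absurd median residuals (we observed 10⁴-scale
  values) and can overflow the period-2 fit.  The log scale — natural
  for an AFT predictor — caps this at polynomial growth.  Defaults:
  linear (faithful to the source specification, harmless for bounded
  trial data like the treadmill test); the simulation harness uses log.
* **Arm-specific imputation noise and test size.**  A deterministic
  single imputation whose model contains an estimated arm coefficient
  copies that coefficient's sampling noise into *every* completed value
  of one arm.  This noise does not cancel in the sequence contrast
  γ̂₂, and the completed-data OLS cannot see it, so the type-I error of
  the downstream test inflates (we measure 8–17% at a nominal 5% over
  the simulation grid; the SD of log θ̂ exceeds its average reported SE
  by a factor ≈1.2).  Pooling the arms (dropping `treatment` from the
  imputation covariates) keeps the noise symmetric, and we measure
  3.8–5.2% rejection under the null across families, sample sizes and
  censoring levels.  The replication harness therefore defaults to the
  pooled model (`simulation_imputation_config()`).  The cost is
  attenuation under strong alternatives: censored treated subjects are
  imputed from a mixture model, which biases log θ̂ toward zero —
  roughly −13% relative at 30% censoring and up to −30% at 50% in our
  measurements.  No deterministic single-imputation variant we examined
  achieves calibrated size and unattenuated estimation simultaneously;
  users who prioritise point estimation under a large effect can switch
  the harness to the arm-specific covariates and accept the
  anticonservative test.

## Crossover ANCOVA

OLS (via statsmodels) of Δ on (1, D, Q) with classical standard errors.
Q is coded {0, 1} with AB = 1: since E[Δ|AB] − E[Δ|BA] = 2 log θ, this
coding makes log θ̂ = γ̂₂/2 (a ±1 coding would give γ̂₂ = log θ).
Inference uses the t distribution on n − 3 df (the normal-reference
p-value is also reported).  Two 95% intervals: the exponentiated
log-scale interval (used for coverage in simulations) and the symmetric
θ-scale interval θ̂ ± z·SE(θ̂) with the delta-method
SE(θ̂) = θ̂·SE(log θ̂) (the form matching the published CI arithmetic
for this design).  Rank-deficient designs (e.g. constant D) and
single-sequence data are errors, as is any remaining censored value —
imputation must run first.

## Simulator

Latent 4-vectors Z ~ N(0, R) with AR(1) R_{ij} = ρ^{|i−j|} (Cholesky
factor applied to iid normals), mapped through Φ and the inverse CDF of
the marginal — a Gaussian copula.  Marginals, chosen to mimic a
10-minute treadmill outcome (times mostly 0–10, mean ≈ 5 per period):
exponential rate 0.3; Weibull in the shape/decay parameterisation
f(x) = s·d·x^{s−1}e^{−d·x^s} with s = 0.95, d = 0.29 (scipy scale
d^{−1/s}); gamma shape 3.2, rate 0.7.  The study grid uses latent
ρ ∈ {0.7, 0.83} (labelled mean pairwise correlations 0.5 and 0.7; the
labels are approximate and the latent values are authoritative),
N ∈ {12, 24, 48} per sequence and censoring fractions 30% / 50% of
post-treatment values.

The treatment effect multiplies the treated component's time scale
(y₁ in AB, y₂ in BA) by θ, which makes the ratio of geometric means
exactly θ by construction — the estimand the ANCOVA targets.  The cap τ
solves ½S₀(τ) + ½S₀(τ/θ) = c (Brent's method; closed form reduces to
the marginal quantile at θ = 1), because post-treatment values are an
equal mixture of the control and θ-scaled margins.  Baselines are never
censored.  No adjustment forces the product-moment correlation of the
transformed margins to match the latent ρ.

Reproducibility: a scenario seed plus replication index feed
`numpy.random.default_rng([seed, rep])`, so any single replication is
bit-reproducible in isolation.

## Replication harness

Each replication: simulate → impute (pooled model, no age — the
simulated design has none) → ANCOVA at α = 0.05.  Aggregates over
(default) 1000 replications: rejection rate (type-I error at θ = 1,
power otherwise), bias of log θ̂ — absolute under the null (where
log θ = 0 makes a relative measure undefined; null biases are at
Monte-Carlo zero, order 10⁻³), relative percent under alternatives —
and coverage of the nominal 95% log-scale CI.  Replications that fail
(non-convergent fits, rank-deficient ANCOVA, non-finite estimates) are
dropped from aggregates and counted; silent NaN propagation would
corrupt the rates.  Monte-Carlo standard errors accompany every rate.
The acceptance script runs the full 72-cell grid at 500 replications
per cell and the two reference power cells at 1000 — sizes chosen so
the whole recomputation stays around ten minutes on one core while
keeping MC standard errors near one percentage point.

## What the synthetic data do and do not show

The generator reproduces the features the method is sensitive to:
small per-sequence samples, strong within-subject correlation,
administrative censoring at a common cap, and skewed positive event
times.  It does not emulate covariate-dependent or random dropout
censoring, period or carryover effects, measurement ties from coarse
timing grids (real treadmill times cluster on half-minutes), or an age
covariate.  Passing operating-characteristic checks on this generator
therefore speaks to calibration and power under clean administrative
censoring, not to robustness against informative censoring or carryover
— both explicitly out of scope.

## Known limitations

* Single deterministic imputation cannot propagate imputation
  uncertainty; the size/attenuation trade-off described above is
  intrinsic, and only the pooled variant yields a calibrated 5% test.
* The semiparametric route is unavailable under purely administrative
  censoring (empty risk set beyond τ) — by construction, not by
  implementation.
* Parametric imputations extrapolate beyond τ under an assumed family;
  with families misspecified for the tail, imputed values inherit that
  misspecification (visible as a few percent residual bias in the gamma
  scenarios).
* Very small trials (≲ 6 per sequence) frequently fail to fit; failures
  are surfaced, not patched.
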