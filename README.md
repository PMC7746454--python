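# merlcross

Median-residual-life imputation and ANCOVA for **2×2 crossover trials
with right-censored time-to-event outcomes**.

## The problem

In a two-treatment, two-period crossover trial each subject receives
both treatments (sequence AB or BA, with a wash-out between periods),
and a baseline measurement `b` is taken before treatment in each period
alongside the post-treatment event time `y`.  When the outcome is a
time to event — e.g. minutes until a cardiopulmonary event on a capped
treadmill test — subjects still event-free at the follow-up cap τ are
administratively right-censored.  Crossover samples are small by
design, so discarding censored subjects is not an option, and standard
censored-data regression does not mesh with the baseline-adjusted
crossover ANCOVA analysts want to run.

`merlcross` takes the imputation route: complete each censored time,
then analyse the completed trial with ordinary ANCOVA.

## The method

**1. Median residual life (MERL) regression.**  The median residual
life at time t₀ is m(t₀) = median(T − t₀ | T > t₀), the median
remaining lifetime among survivors beyond t₀.  With covariates x it is
modelled log-linearly,

```
median(T − t₀ | T > t₀, x) = exp(x'β(t₀)).
```

Fitting routes: a parametric maximum-likelihood AFT fit (Weibull,
exponential or log-normal) from which m(t₀|x) = S_x⁻¹(S_x(t₀)/2) − t₀,
and a semiparametric IPCW-weighted median-check-loss fit at a fixed t₀.
Under administrative censoring no events are observed beyond τ, so the
parametric route (which extrapolates the conditional survivor) is the
default.

**2. Sequential imputation.**  Period 1 first: one model pooled over
both sequences with the treatment indicator, age (if recorded) and the
period-1 baseline as covariates; each censored y₁ becomes
t₀ + m(t₀ | x) with t₀ its own censoring time.  Then period 2, with
the completed period-1 outcome as an extra covariate.  Every imputed
time therefore exceeds the cap, and an audit table records each one.

**3. Crossover ANCOVA.**  On the completed data, the per-subject log
period-difference Δ = log y₁ − log y₂ is regressed on the baseline
difference D = log b₁ − log b₂ and the sequence indicator Q (1 for AB):

```
Δ = γ₀ + γ₁ D + γ₂ Q + ε,    ε ~ N(0, η²).
```

Because E[Δ|AB] − E[Δ|BA] = 2·log θ, the ratio of geometric means of
event times under treatment A vs B is estimated by log θ̂ = γ̂₂/2, with
SE(γ̂₂)/2 as its standard error and a t test of H₀: θ = 1 on n − 3 df.

**4. Simulation machinery.**  A Gaussian copula with latent AR(1)
correlation (ρ^|i−j|) generates correlated (b₁, y₁, b₂, y₂) vectors
with exponential, Weibull or gamma marginals; θ multiplies the treated
margin's time scale; administrative censoring at a τ calibrated to a
target censoring fraction.  A replication harness computes type-I
error, power, bias of log θ̂ and CI coverage over the scenario grid.

## Worked example

The packaged fixture is a 40-subject, 10-minute treadmill crossover
trial (drug vs placebo, 20 subjects per sequence, six times censored at
the cap):

```sh
merlcross analyze treadmill
```

```
Imputed values:
subject_id  period   t0  median_residual  imputed_time
         4       1 10.0         5.929395     15.929395
        18       1 10.0         5.714794     15.714794
         3       2 10.0         1.390491     11.390491
        11       2 10.0         7.424593     17.424593
        13       2 10.0         2.721748     12.721748
        16       2 10.0         1.378209     11.378209
ANCOVA  Delta ~ gamma0 + gamma1*D + gamma2*Q:
  gamma0 = -0.4835  (SE 0.2337)
  gamma1 =  0.8848  (SE 0.2030)
  gamma2 =  1.0282  (SE 0.3309)
theta_hat = 1.6721   SE(theta) = 0.2766   SE(log theta) = 0.1654
95% CI (theta scale, symmetric): (1.130, 2.214)
95% CI (log scale, exponentiated): (1.196, 2.338)
p-value (t, H0: theta=1) = 0.003617
```

Reading: the six censored subjects are completed to 11.4–17.4 minutes
(cap plus predicted median residual life, adjusting for age, baseline
and arm).  The drug multiplies the geometric mean time to event by an
estimated θ̂ = 1.67 — a two-thirds longer typical walking time — and
the effect is clearly significant (p = 0.004).  Both a symmetric
θ-scale interval (delta method) and the exponentiated log-scale
interval are reported.

The same pipeline is available programmatically:

```python
from merlcross import (CrossoverAncova, ImputationConfig,
                       impute_dataset, treadmill_fixture)

trial = treadmill_fixture()
completed = impute_dataset(trial, ImputationConfig(use_age=True))
fit = CrossoverAncova().fit(completed)
print(fit.theta_, fit.ci_theta_symmetric_, fit.p_value_)
```

## Simulating operating characteristics

```sh
merlcross simulate --family gamma --theta 1.4 --rho 0.7 --n 24 \
    --censoring 0.3 --seed 1 -o trial.csv
merlcross reproduce --reps 1000 --seed 7 -o grid.csv
```

`reproduce` emits one CSV row per grid cell (family × latent ρ ∈
{0.7, 0.83} × censoring {30%, 50%} × N ∈ {12, 24, 48} × H₀/H₁) with
rejection percentage, bias, coverage and their Monte-Carlo standard
errors.  In the harness the imputation model pools the two arms; see
`docs/methods.md` for why an arm-specific imputation term breaks the
size of the downstream test.

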