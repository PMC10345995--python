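# margcrisk

Marginal proportional cause-specific hazards regression for **clustered
competing risks data** in which the cause of failure is **missing at random
(MAR)** for part of the sample and the **cluster size is informative** (ICS):
larger clusters may systematically differ in their members' outcomes, as in
multicenter cohorts where bigger clinics deliver different care.

The package is aimed at biostatisticians analyzing multicenter survival data
— e.g., multicenter HIV cohorts where deaths are under-reported and the
true event type (death vs. disengagement from care) is ascertained only for
a double-sampled subset — and at methodologists who need a reference
implementation of the estimator with full variance/band machinery and a
matching synthetic-data generator.

## The model and the estimator

For subject *j* in cluster *i*, with follow-up time `X = T ∧ U`, any-cause
failure indicator `Δ`, cause `C ∈ {1,…,k}`, cause-observation indicator `R`
(`ε = ΔRC`, 0 = censored or missing) and covariates `Z`, the marginal
cause-specific hazards follow the proportional-hazards form

```
λ_l(t; z) = λ_{0,l}(t) · exp(β_l' z),    l = 1, …, k ,
```

with the within-cluster dependence left completely unspecified.  Estimation
is a **two-step maximum partial pseudolikelihood**:

1. **Cause-probability model.**  `π_l(W, γ) = P(C = l | Δ = 1, W)`,
   `W = (X, Z, A)` with optional auxiliary covariates `A`, is a binary
   (k = 2) or baseline-category multinomial (k > 2) logit fitted on the
   complete-case failures by estimating equations weighted by the inverse
   cluster size `1/M_i`, under working independence.  MAR makes the
   complete-case fit valid.
2. **Partial pseudoscore.**  Unobserved cause-specific counting increments
   are replaced by their conditional expectation
   `dÑ_ijl = {RΔ_l + (1−R) π_l(W, γ̂)} dN_ij`, and `β̂_l` solves the
   `1/M_i`-weighted partial pseudoscore equation
   `Σ_i (1/M_i) Σ_j ∫ {Z_ij − E_n(t, β_l)} dÑ_ijl(t) = 0`, where `E_n` is
   the weighted at-risk covariate average.  A Breslow-type step estimator
   gives the baseline cumulative hazard `Λ̂_l`, and covariate-specific
   cumulative incidence functions follow by plugging into
   `F_l(t; z₀) = ∫₀ᵗ exp{−Σ_m Λ̂_m(u−; z₀)} dΛ̂_l(u; z₀)`.

The `1/M_i` weights target the *typical cluster member* (TCM) population;
passing `mode="acm"` drops them for *all-cluster-members* inference.

Standard errors come from cluster-level empirical influence functions of the
two-stage estimator, valid under arbitrary within-cluster dependence and
ICS.  Simultaneous 95% confidence bands for `Λ_l` and `F_l` use a standard
normal **multiplier bootstrap** of the influence curves, with equal-precision
or Hall–Wellner weightings and log / complementary-log-log transforms.  A
simulation-based sup test of the cumulative residual process checks the
parametric `π_l` model.

## Worked example

```python
import numpy as np
from margcrisk import (ScenarioConfig, generate, PiModelSpec, fit_mpple,
                       InfluenceSet, cif, cumhaz_band, gof_test)

cfg = ScenarioConfig(scenario=1, n_clusters=100, seed=7)   # positive stable frailty study
data, truth = generate(cfg)
fit = fit_mpple(data, pi_spec=PiModelSpec(features=("time", "z1", "z2")))
infl = InfluenceSet(fit)

for l in (1, 2):
    b, se = fit.beta[l - 1], infl.beta_se(l)
    print(f"cause {l}: beta = {np.round(b, 3)}, se = {np.round(se, 3)}")
print(f"Lambda_1(1.0) = {fit.Lambda[0](1.0):.3f}")
print(f"F_1(1.0; z=0) = {cif(fit, np.zeros(2))[0](1.0):.3f}")

band = cumhaz_band(fit, 1, infl=infl, weight="ep", n_draws=1000, rng=1)
i = np.searchsorted(band.times, 0.5)
print(f"95% EP band for Lambda_1 at t=0.5: ({band.band_lower[i]:.3f}, {band.band_upper[i]:.3f})")

g = gof_test(data, fit.gamma_fit, l=1, n_draws=1000, rng=2)
print(f"GOF: sup = {g.sup_stat:.3f}, p = {g.p_value:.3f}")
```

Output:

```
cause 1: beta = [-0.239  0.033], se = [0.023 0.054]
cause 2: beta = [-0.023 -0.27 ], se = [0.018 0.073]
Lambda_1(1.0) = 0.946
F_1(1.0; z=0) = 0.468
95% EP band for Lambda_1 at t=0.5: (0.513, 0.898)
GOF: sup = 0.123, p = 0.111
```

The generator's conditional coefficients are −0.5 with a positive stable
frailty of index α = 0.5, so the *marginal* truths are αβ = −0.25 for the
own-cause covariate (cause 1 / `z1`, cause 2 / `z2`), 0 for the other
covariate, and `Λ'_1(t) = √t`; the estimates above sit within two standard
errors of those values, the band at t = 0.5 covers √0.5 ≈ 0.707, and the
goodness-of-fit test does not reject the (approximately correct)
linear-time cause-probability model.

The same workflow is scriptable from the shell:

```bash
margcrisk simulate --scenario 1 --n-clusters 100 --seed 7 --out study.csv
margcrisk fit study.csv --z0 0,0 --bands --out-dir study_fit/
margcrisk gof study.csv
margcrisk table1 --n-clusters 50 --n-reps 500     # replicated coverage study
```

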