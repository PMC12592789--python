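# sunjoint

Semi-parametric joint models for longitudinal outcomes observed at
**irregular, outcome-dependent visit times**.

In many longitudinal studies (tumor-recurrence counts, symptom scores,
lab values) subjects are not measured on a fixed schedule: each subject
has their own visit times, and sicker subjects may visit more (or less)
often. When a latent subject-level factor drives both the outcome level
and the visit frequency, naive regression on the pooled visit records is
biased. `sunjoint` fits the multiplicative joint model

```
E(Y_i(t) | X_i, nu_i)    = nu_i * mu0(t) * exp(X_i' beta)      (outcome)
lambda(t | X_i, nu_i)    = nu_i * lambda0(t) * exp(X_i' gamma) (visit intensity)
```

where `nu_i` is a positive frailty with `E(nu | X) = 1` shared by both
processes, `mu0(t)` is the intercept trajectory (mean outcome of a
reference subject), and `beta` are the covariate effects of interest on
the log scale.

The package provides:

* the **original Sun estimator** of `beta` (intercept differenced out —
  relative effects only), via the weighted estimating equation
  `U(beta) = (1/n) sum_i int (X_i - xbar(t; beta, gamma)) Y_i(t) dN_i(t) = 0`
  with `xbar` the risk-set average of `X` weighted by the moment
  estimates of `nu^2`;
* the **extended Sun estimator**: the intercept is parameterized as
  `mu0(t) = exp(B(t)' alpha)` with a B-spline basis `B`, and
  `eta = (beta, alpha)` solves the estimating equation
  `L(eta) = sum_i int [ Z_i(t) Y_i(t) exp(-Z_i(t)'eta) - S(t) ] dN_i(t) = 0`,
  `Z_i(t) = (X_i, B(t))`, where the risk-set term `S(t)` is free of
  `eta` and built from the visit-model fit. This recovers **absolute**
  mean trajectories, not only relative effects, with smaller bias and
  standard error than the original estimator;
* the first-stage machinery: Andersen–Gill partial-likelihood fit of the
  visit intensity (optionally with a shared gamma frailty), the Breslow
  cumulative baseline, and method-of-moments frailty estimates
  `omega_i` (for `nu_i`) and `Omega_i` (for `nu_i^2`);
* a log-link **independence GEE** comparator, a **residual diagnostic**
  `Res(t)` for the intercept's functional form, subject-level
  **bootstrap** inference, and the full **simulation study** generator.

## Worked example

```python
import numpy as np
from sunjoint import ScenarioSpec, generate_dataset, fit_pipeline, predict_trajectory

spec = ScenarioSpec(n=200, beta0=1.0, mu0_form="loglinear", tau=5.0)
ds = generate_dataset(spec, np.random.default_rng(2025))
for est in ("sun", "extended", "gee"):
    pf = fit_pipeline(ds, estimator=est)
    print(est, pf.beta[0])
```

prints (one simulated replicate, true effect `beta0 = 1`):

```
sun       beta-hat = +1.153   (truth 1.0)
extended  beta-hat = +0.998   (truth 1.0)
gee       beta-hat = +0.974   (truth 1.0)
```

The extended fit also yields the intercept trajectory: with the same
fit, `predict_trajectory(pf.fit, [0.5, 1.5, 3.0])` returns estimated
mean outcomes `32.1, 383.0, 12409.6` for a covariate-zero subject
against true values `30.1, 371.0, 11923.8` — information the original
Sun estimator cannot provide by construction.

More narrative scripts live in `examples/` (one per capability): a
small simulation comparison, the residual diagnostic, bootstrap CIs,
and the bladder-tumor case study, where thiotepa reduces the mean
number of recurrent tumors by about half (extended-model ratio 0.45,
95% bootstrap CI 0.26–0.83).

## Command line

A thin CLI wraps the library for file-based workflows:

```sh
sunjoint fit --visits visits.csv --subjects subjects.csv --estimator extended --out out/
sunjoint simulate --n 200 --reps 505 --seed 1 --out sim/
sunjoint diagnose --visits visits.csv --subjects subjects.csv --out diag/
```

Input is long-format CSV: one row per visit (`id,time,y`) plus a
subject table (`id,C,<covariates>`) with the end-of-follow-up time `C`.

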