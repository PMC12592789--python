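# Methods

## Model

For subjects `i = 1..n` followed on `[0, tau)`, let `Y_i(t)` be the
longitudinal outcome, `X_i` time-invariant covariates, `C_i` the
end-of-follow-up (censoring) time, `Delta_i(t) = I(C_i >= t)` the
at-risk indicator, and `N_i(t)` the counting process of visit times.
The joint model links the outcome and visit processes through a shared
positive frailty `nu_i` with `E(nu_i | X_i) = 1`:

```
E(Y_i(t) | X_i, nu_i) = nu_i * mu0(t)     * exp(X_i' beta)
lambda(t | X_i, nu_i) = nu_i * lambda0(t) * exp(X_i' gamma)
```

Outcome and visits are assumed conditionally independent given
`(X_i, nu_i)`; covariates are time-invariant (a time-varying extension
would require the covariate path between visits, which is out of
scope). Because high-`nu` subjects both visit more often and have
higher outcomes, pooled visit records over-represent high outcomes:
the visit-weighted mean outcome at `t` given `X` is
`E(nu^2|X) * mu0(t) * exp(X'beta)`, which is what a naive marginal
regression estimates.

## Two-stage estimation

**Stage 1 — visit model.** `gamma` is estimated by the Andersen–Gill
recurrent-event partial likelihood (Newton–Raphson from `gamma = 0`,
Breslow tie handling, convergence at relative score max-norm `1e-8`,
max 50 iterations, step-halving safeguard). The cumulative baseline
`Lambda0` is the Breslow step estimator,
`sum_{u <= t} (#visits at u) / sum_j Delta_j(u) exp(X_j' gamma)`,
jumping only at observed visit times and evaluated right-continuously.
Because the visit process is conditionally Poisson,

```
E(m_i | nu_i, X_i, C_i)   = nu_i   Lambda0(C_i)   exp(X_i'gamma)
E(m_i^2 | nu_i, X_i, C_i) = nu_i^2 Lambda0(C_i)^2 exp(2X_i'gamma) + E(m_i | ...)
```

giving the method-of-moments frailty estimates

```
omega_i = m_i / (Lambda0(C_i) exp(X_i'gamma))                    # for nu_i
Omega_i = m_i (m_i - 1) / (Lambda0(C_i)^2 exp(2 X_i'gamma))      # for nu_i^2
```

`Omega_i = 0` whenever `m_i <= 1` and `omega_i = 0` when `m_i = 0`;
such subjects still shape the risk sets. The `Lambda0` used to form the
moments is the **unit-frailty-weight** Breslow estimator even when
`gamma` comes from a frailty fit (two-pass convention: the moment
estimators are defined in terms of `Lambda0` and `gamma` alone; the
frailty-weighted denominators enter only later through the
`omega`-weighted term of the extended equation). A sensitivity check on
the bladder data showed the alternative (frailty-weighted `Lambda0`)
moves the treatment effect by < 0.02.

For the case-study recipe a shared **gamma frailty** visit model is
available: an EM algorithm (E-step
`nu_i = (m_i + 1/theta) / (mu_i + 1/theta)`; M-step a frailty-weighted
partial-likelihood Newton step and weighted Breslow update) nested in a
1-D profile search over the frailty variance `theta`, which maximizes
the gamma-mixture marginal likelihood with the baseline jumps profiled
out. Everywhere else the default is the plain (no-frailty) fit.

**Stage 2a — original Sun estimator.** `beta` solves

```
U(beta) = (1/n) sum_i sum_{visits (t,y) of i} (X_i - xbar(t; beta, gamma)) y = 0
xbar(t) = sum_j Delta_j(t) Omega_j exp{X_j'(beta+gamma)} X_j
          / sum_j Delta_j(t) Omega_j exp{X_j'(beta+gamma)}
```

The weight process multiplying the integrand is taken as identity (its
general form is not pinned down in the source derivation, and the
identity weight is what the zero-mean-process derivation produces).
Solved by damped Newton with a central-difference Jacobian (step
`1e-5 * (1+|beta|)`), init `0`, tolerance `1e-8` on `||U||_inf`, max 100
iterations, step-halving on the residual norm. Constant covariate
columns are rejected: the intercept is not identified by this equation
(it differences out), which is the estimator's defining limitation.

**Stage 2b — extended Sun estimator.** With `mu0(t) = exp(B(t)'alpha)`,
`Z_i(t) = (X_i, B(t))` and `eta = (beta, alpha)`:

```
L(eta) = sum_i sum_{visits (t,y) of i} [ Z_i(t) y exp(-Z_i(t)'eta) - S(t) ] = 0
S(t)   = sum_j Delta_j(t) Omega_j exp(X_j'gamma) Z_j(t)
         / sum_j Delta_j(t) omega_j exp(X_j'gamma)
```

`S(t)` does not involve `eta`, so it is precomputed once per visit
time (risk-set sums are suffix cumsums over subjects sorted by `C`,
making each `L` evaluation `O(V + n log n)` for `V` visits). The
Jacobian is `-sum Z Z' y exp(-Z'eta)`: symmetric negative semidefinite
since `y >= 0`, so Newton iteration with the analytic Jacobian and
step-halving converges reliably from `eta = 0`; tolerance `1e-8` on
`||L||_inf`, max 100 iterations. For conditioning, the non-intercept
spline columns are centered over visits before solving and the
intercept un-shifted afterwards (an exact reparameterization — verified
against the uncentered equation in the tests).

**Spline basis.** Cubic B-splines (scipy), boundary `[0, tau]`,
interior knots at the `j/(k+1)` quantiles of the pooled visit times
(`k = 4` quintile knots in the simulations; `k = 3` quartile knots in
the case-study recipe, whose placement the source leaves unstated —
quartiles are the natural analogue of the simulation rule). Raw
B-splines sum to one, so alongside an explicit intercept the first raw
column is dropped; any drop-one choice spans the same space. The basis
dimension is `K = k + degree + 1`.

**Comparator GEE.** A log-link marginal regression of the pooled visit
outcomes on `(intercept + spline columns, X)` under working
independence — the quasi-score root coincides with a Poisson GLM point
estimate and is computed by statsmodels IRLS. The working-correlation
structure of the original comparison is unstated; independence is the
minimal choice (an exchangeable structure was also tried: it diverges
under the strong-trend scenarios and is numerically identical to
independence in the short-follow-up scenario, so nothing hinges on it).
Standard errors for everything come from the pipeline bootstrap, never
from model-based formulas.

**Missing outcomes.** A visit whose outcome was not recorded (`y =
NaN`) still counts as an event for Stage 1 (it carries information
about the visit intensity and `m_i`), but is excluded from all
outcome-stage sums (`U`, `L`, GEE rows, residuals). This matters for
the bladder data, where 2 of 132 recurrence visits lack a tumor count.

## Residual diagnostic

```
R_i(t)  = sum_{visits (u,y) of i, u <= t} exp(-Z_i(u)'eta - X_i'gamma) y
          - Omega_i * Lambda0(min(C_i, t))
Res(t)  = (1/n) sum_i R_i(t)
```

Under a correctly specified intercept basis `Res(t)` converges in
probability to zero; it is plotted on a default grid of 100 equispaced
points on `[0, tau]` (the curve is piecewise constant between event
times, so the grid is cosmetic). The population `nu_i^2` in the
compensator is replaced by its estimate `Omega_i`, the only observable
choice. This is a diagnostic, not a test: no reference bands or
p-values are produced.

## Bootstrap

Nonparametric, resampling **subjects** with replacement (visits are
dependent within subject). Each resample refits the entire pipeline,
including the spline knot locations recomputed from the resample's own
pooled visit times, so the intervals reflect basis variability. SEs are
sample sds of the resampled coefficients; CIs are 2.5/97.5 percentile
intervals; mean-ratio intervals exponentiate the endpoints. Resample
streams are spawned from one master seed (`numpy.random.SeedSequence`),
so results are bit-reproducible. Failed resamples are dropped; more
than 10% failures aborts. Case-study default `B = 600`.

## Synthetic-data generator

Each replicate draws, per subject and in a fixed order (covariate,
frailty, censoring, visit gaps, outcome errors — making replicates
bit-reproducible given a seed):

* `X ~ Bernoulli(1/2)` or `N(0, 0.25)`;
* frailty `nu = exp(-log(2.75) * g(X)) * nu*` with `nu* ~ U(0.5, 1.5)`
  in the reference group and `U(1.5, 4)` in the elevated group
  (`g(X) = X` for binary, `I(X >= 0)` for normal covariates); both
  regimes give `E(nu | X) = 1` and mildly different frailty variances
  (1/12 vs ~0.069), which is the confounding engine of the design;
* censoring `C ~ U(1, 1.1 tau)` truncated at `tau` (administrative
  censoring);
* visit times: homogeneous Poisson with rate `nu * exp(0.5 X)` on
  `(0, C]`, via exponential gaps;
* outcomes at each visit `t`:
  `log Y = log nu + m0(t) + X beta0 + eps`, `eps ~ N(-0.0625, 0.1225)`
  iid across visits. The stated error mean is kept verbatim although
  exact mean-one multiplicative noise would need `-0.06125`; the
  difference (`E exp(eps) = 0.99875`) is negligible.

The log-scale intercepts are `m0(t) = log(1+t) + 2(t+1)`,
`sin(t) + 2(t+1)`, or `sin(4t)`. The first two carry a strong linear
trend: outcomes span roughly `e^2` to `e^13` over `tau = 5`, the regime
in which intercept-free estimators lose most of their efficiency while
the spline-based ones absorb the trend (the registry in
`sunjoint.simulate.MU0_FORMS` is plain-function-valued and can be
swapped for other shapes). The generator emulates the study design
faithfully but is idealized in the usual ways — visit intensities are
time-constant given the frailty, errors are homoscedastic lognormal,
censoring is independent — so passing tests demonstrate correctness of
the estimators under these conditions, not robustness on arbitrary
real data.

Scenario runs default to 505 replicates; the basis *rule* is fixed
while knot locations are recomputed per replicate from its own visit
times. Replicates where an estimator fails are excluded from that
estimator's summary (failure rates are reported; >5% triggers a
warning).

## Replication status and known discrepancies

With the defaults above (505 replicates, n=200, binary covariate), the
extended estimator's published behavior reproduces closely: ESE ~0.072
vs published 0.078 at n=200, ~0.046 vs 0.049 at n=500, ~0.086-0.090 vs
0.086 under the sinusoidal intercept, with |bias| under 0.01
everywhere. Three published numbers do **not** reproduce and are left
as computed rather than tuned:

* the original-Sun ESE in the base scenario (~0.27-0.30 here vs 0.36)
  and the GEE ESE (~0.13 vs 0.17), both ~20% lower than published;
* the published short-follow-up (tau=1.5) biases (+0.063 extended,
  -0.10 GEE) do not appear: both are near zero here, and the GEE bias
  matches its closed-form visit-weighting value
  `log(E(nu^2|X=1)/E(nu^2|X=0)) = -0.0134` exactly, which is a strong
  internal consistency check on generator and estimator alike.

Several alternative readings (fraction-form intercepts, exchangeable
working correlation, knots frozen across scenarios) were implemented
and tested; none moves the comparators toward the published dispersion
without breaking the quantities that already match.

## Numerical notes and limitations

* Ties in visit times are handled by the Breslow convention throughout;
  times are otherwise treated as continuous.
* Degenerate inputs fail loudly: constant covariates
  (unidentifiable), rank-deficient visit designs, empty risk sets,
  `Lambda0(C_i) = 0` with `m_i >= 1`, evaluation outside the basis
  boundary.
* The closed-form asymptotic variance of the extended estimator is not
  implemented (it is known to be unstable at realistic sample sizes);
  the bootstrap is the supported inference route.
* Formal lack-of-fit tests, time-varying covariates, and
  covariate-wise residual diagnostics are out of scope.
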