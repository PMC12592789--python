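"""Fit all three estimators on one simulated study.

Generates a single dataset from the base simulation design (n=200
subjects, binary covariate with true log-effect beta0=1, frailty-driven
informative visits, log-linear intercept) and fits the original Sun
estimating equation, the extended (spline-intercept) estimator, and the
naive independence GEE.  The covariate coefficient estimates show how
close each method gets to the truth on one replicate; only the extended
fit also recovers the intercept trajectory.
"""

import numpy as np

from sunjoint import ScenarioSpec, fit_pipeline, generate_dataset, predict_trajectory

spec = ScenarioSpec(n=200, beta0=1.0, mu0_form="loglinear", tau=5.0)
ds = generate_dataset(spec, np.random.default_rng(2025))
print(f"dataset: {ds.n} subjects, {ds.arrays().n_visits} visits, tau={ds.tau}")

for est in ("sun", "extended", "gee"):
    pf = fit_pipeline(ds, estimator=est)
    print(f"{est:9s} beta-hat = {pf.beta[0]:+.3f}   (truth {spec.beta0})")

pf = fit_pipeline(ds, estimator="extended")
times = np.array([0.5, 1.5, 3.0, 4.5])
traj = predict_trajectory(pf.fit, times)
from sunjoint.simulate import MU0_FORMS

truth = np.exp(MU0_FORMS["loglinear"](times))
print("\nintercept trajectory mu0(t) (reference subject, X=0):")
for t, est_v, tr in zip(times, traj, truth):
    print(f"  t={t:3.1f}  estimate {est_v:10.2f}   truth {tr:10.2f}")
print("estimates track the true mean outcome of a covariate-zero subject;")
print("the sun estimator cannot produce this curve at all.")
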