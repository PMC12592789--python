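import numpy as np
import pytest

from sunjoint import LongitudinalDataset, ScenarioSpec, Subject, generate_dataset


def make_dataset(subjects_spec, tau=None, covariate_names=None):
    """Build a dataset from (id, X, C, times, y) tuples."""
    subs = [Subject(id=i, X=np.atleast_1d(x), C=C,
                    times=np.asarray(t, float), y=np.asarray(y, float))
            for i, x, C, t, y in subjects_spec]
    p = len(np.atleast_1d(subjects_spec[0][1]))
    names = covariate_names or [f"x{j}" for j in range(p)]
    return LongitudinalDataset(subs, tau=tau, covariate_names=names)


def poisson_process_dataset(n, rate_fn, C_fn, y_fn, rng, tau=None, X_fn=None):
    """Homogeneous-Poisson visit times per subject; used where the truth
    (rates, baselines) must be known independently of the package's own
    scenario generator."""
    subs = []
    for i in range(n):
        x = np.atleast_1d(X_fn(rng) if X_fn else 0.0)
        C = C_fn(rng)
        rate = rate_fn(x)
        times = []
        t = rng.exponential(1.0 / rate)
        while t <= C:
            times.append(t)
            t += rng.exponential(1.0 / rate)
        times = np.asarray(times)
        y = y_fn(times, x, rng) if len(times) else np.empty(0)
        subs.append(Subject(id=f"s{i}", X=x, C=C, times=times, y=np.asarray(y, float)))
    p = len(subs[0].X)
    return LongitudinalDataset(subs, tau=tau, covariate_names=[f"x{j}" for j in range(p)])


@pytest.fixture(scope="session")
def scenario1_dataset():
    """One scenario-1 replicate (n=200, Bernoulli X, log-linear intercept)."""
    rng = np.random.default_rng(2024)
    return generate_dataset(ScenarioSpec(n=200), rng)


@pytest.fixture(scope="session")
def small_fitted(scenario1_dataset):
    from sunjoint import fit_pipeline

    pf = fit_pipeline(scenario1_dataset, estimator="extended")
    return scenario1_dataset, pf
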