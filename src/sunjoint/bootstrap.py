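"""Nonparametric subject-level bootstrap for the two-stage pipeline.

Subjects are resampled with replacement (each keeping all of their
visits, since visits are dependent within subject) and the entire
pipeline -- intensity fit, Breslow baseline, frailty moments, spline
knots, outcome estimator -- is refit on every resample.  Standard
errors are the sample sd of the resampled coefficients; confidence
intervals are 2.5/97.5 percentile intervals, and mean-ratio intervals
are obtained by exponentiating the coefficient-scale endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset
from .extended import predict_trajectory
from .pipeline import fit_pipeline

__all__ = ["BootstrapResult", "bootstrap"]


@dataclass
class BootstrapResult:
    B: int
    seed: int
    estimator: str
    table: pd.DataFrame
    samples: np.ndarray          # (B_ok, q) resampled coefficient draws
    n_failed: int
    trajectory_times: np.ndarray | None = None
    trajectory_point: np.ndarray | None = None
    trajectory_band: np.ndarray | None = None   # (2, len(times)) lower/upper

    def save_table(self, path) -> None:
        self.table.to_csv(path, index=False)


def bootstrap(
    ds: LongitudinalDataset,
    estimator: str = "extended",
    B: int = 600,
    seed: int = 0,
    basis_spec: dict | None = None,
    frailty: str = "none",
    trajectory_times=None,
    trajectory_X=None,
    max_failure_frac: float = 0.10,
) -> BootstrapResult:
    """Bootstrap SEs, percentile CIs and (optionally) trajectory bands.

    Reproducible: one master seed spawns an independent substream per
    resample, so the same ``(ds, estimator, B, seed)`` gives identical
    results.  Resamples where the estimator fails are dropped; more
    than ``max_failure_frac`` failures is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    point = fit_pipeline(ds, estimator=estimator, basis_spec=basis_spec, frailty=frailty)
    q = len(point.coefficients)
    want_traj = trajectory_times is not None and estimator == "extended"
    if want_traj:
        trajectory_times = np.asarray(trajectory_times, dtype=float)
        traj_point = predict_trajectory(point.fit, trajectory_times, X=trajectory_X)
    master = np.random.SeedSequence(seed)
    children = master.spawn(B)
    draws, traj_draws = [], []
    n_failed = 0
    n = ds.n
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        try:
            res = ds.subset(idx)
            pf = fit_pipeline(res, estimator=estimator, basis_spec=basis_spec,
                              frailty=frailty)
            draws.append(pf.coefficients)
            if want_traj:
                traj_draws.append(predict_trajectory(pf.fit, trajectory_times,
                                                     X=trajectory_X))
        except Exception:
            n_failed += 1
    if n_failed > max_failure_frac * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap resamples failed (> {max_failure_frac:.0%})"
        )
    samples = np.asarray(draws)
    se = samples.std(axis=0, ddof=1)
    lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
    table = pd.DataFrame({
        "parameter": point.parameter_names,
        "estimate": point.coefficients,
        "se": se,
        "ci_low": lo,
        "ci_high": hi,
        "ratio": np.exp(point.coefficients),
        "ratio_low": np.exp(lo),
        "ratio_high": np.exp(hi),
    })
    band = None
    if want_traj:
        band = np.percentile(np.asarray(traj_draws), [2.5, 97.5], axis=0)
    return BootstrapResult(
        B=B, seed=seed, estimator=estimator, table=table, samples=samples,
        n_failed=n_failed,
        trajectory_times=trajectory_times if want_traj else None,
        trajectory_point=traj_point if want_traj else None,
        trajectory_band=band,
    )
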