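"""Original Sun estimator of relative covariate effects.

Solves the weighted estimating equation

    U(beta; gamma) = (1/n) sum_i sum_{visits (t,y) of i}
                     (X_i - xbar(t; beta, gamma)) y  =  0

where xbar is the risk-set average of X weighted by
``Omega_j exp{X_j'(beta + gamma)}`` and Omega_j is the moment estimate
of nu_j^2.  The intercept function is differenced out, so only relative
effects are identified; any constant covariate column is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LongitudinalDataset
from .visits import (
    ConvergenceError,
    FrailtyMoments,
    IdentifiabilityError,
    IntensityFit,
    _RiskSet,
    _check_covariates,
)

__all__ = ["SunFit", "xbar", "solve_sun", "estimating_function_U"]


@dataclass
class SunFit:
    beta: np.ndarray
    converged: bool
    equation_norm: float
    iterations: int


def xbar(t, beta, ds: LongitudinalDataset, moments: FrailtyMoments, gamma) -> np.ndarray:
    """Weighted average of X over subjects at risk at time t, with
    weights Omega_i exp{X_i'(beta + gamma)}."""
    arr = ds.arrays()
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    at_risk = arr.C >= t
    w = moments.Omega * np.exp(arr.X @ (beta + gamma))
    w = np.where(at_risk, w, 0.0)
    den = w.sum()
    if den <= 0:
        raise ValueError(f"all at-risk subjects have zero weight at t={t}")
    return (w @ arr.X) / den


def estimating_function_U(beta, ds, moments, gamma) -> np.ndarray:
    """U(beta; gamma), vectorized over all visits."""
    arr = ds.arrays()
    obs = arr.y_observed
    t, y, si = arr.t[obs], arr.y[obs], arr.subject_index[obs]
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    w = moments.Omega * np.exp(arr.X @ (beta + gamma))
    rs = _RiskSet(arr.C)
    s0 = rs.suffix_sum(w, t)
    if np.any(s0 <= 0):
        bad = t[np.argmax(s0 <= 0)]
        raise ValueError(f"all at-risk subjects have zero weight at t={bad}")
    s1 = rs.suffix_sum(w[:, None] * arr.X, t)
    xb = s1 / s0[:, None]
    return ((arr.X[si] - xb) * y[:, None]).sum(axis=0) / arr.n


def solve_sun(
    ds: LongitudinalDataset,
    fit: IntensityFit,
    moments: FrailtyMoments,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SunFit:
    """Root of U(beta) by damped Newton with a central-difference Jacobian."""
    arr = ds.arrays()
    _check_covariates(arr, ds.covariate_names)
    if not np.any(arr.y[arr.y_observed] > 0):
        raise ValueError("no visit with positive outcome; U is identically zero")
    gamma = np.atleast_1d(fit.gamma)
    p = arr.p

    def U(b):
        return estimating_function_U(b, ds, moments, gamma)

    beta = np.zeros(p)
    val = U(beta)
    norm = np.max(np.abs(val))
    it = 0
    while norm >= tol and it < max_iter:
        it += 1
        J = np.empty((p, p))
        for j in range(p):
            h = 1e-5 * (1.0 + abs(beta[j]))
            e = np.zeros(p)
            e[j] = h
            J[:, j] = (U(beta + e) - U(beta - e)) / (2 * h)
        try:
            step = np.linalg.solve(J, -val)
        except np.linalg.LinAlgError as exc:
            raise IdentifiabilityError(
                "singular Jacobian of U; covariates may be collinear"
            ) from exc
        frac = 1.0
        for _ in range(40):
            cand = beta + frac * step
            val_new = U(cand)
            if np.all(np.isfinite(val_new)) and np.max(np.abs(val_new)) < norm:
                break
            frac /= 2.0
        else:
            raise ConvergenceError(
                f"Sun estimating equation stalled with ||U||={norm:.3e}"
            )
        beta, val = cand, val_new
        norm = np.max(np.abs(val))
    if norm >= tol:
        raise ConvergenceError(
            f"Sun estimating equation did not converge: ||U||={norm:.3e}"
        )
    return SunFit(beta=beta, converged=True, equation_norm=float(norm), iterations=it)
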