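"""Visit-intensity model: Andersen-Gill fit, Breslow baseline, frailty moments.

The visit process is modelled with a proportional intensity
``lambda(t | X, nu) = nu * lambda0(t) * exp(X' gamma)`` where ``nu`` is a
positive subject-level frailty with ``E(nu | X) = 1``.  The regression
part is estimated by the Andersen-Gill recurrent-event partial
likelihood; the cumulative baseline ``Lambda0`` by the Breslow step
estimator; and the frailty moments per subject by method of moments:
because the visit process is conditionally Poisson,

    E(m_i | nu, X, C)  = nu  * Lambda0(C) * exp(X'gamma)
    E(m_i^2 | ...)     = nu^2 * Lambda0(C)^2 * exp(2 X'gamma) + E(m_i | ...)

which gives the unbiased plug-in estimators

    omega_i = m_i / (Lambda0(C_i) exp(X_i'gamma))            for nu_i
    Omega_i = m_i (m_i - 1) / (Lambda0(C_i)^2 exp(2X_i'gamma)) for nu_i^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .dataset import DatasetArrays, LongitudinalDataset

__all__ = [
    "StepFunction",
    "IntensityFit",
    "FrailtyMoments",
    "fit_andersen_gill",
    "breslow_baseline",
    "frailty_moments",
]


class ConvergenceError(RuntimeError):
    pass


class IdentifiabilityError(ValueError):
    pass


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous nondecreasing step function with value 0 before
    the first jump (a cumulative baseline intensity)."""

    jump_times: np.ndarray
    values: np.ndarray  # cumulative value at and after each jump

    def __post_init__(self):
        object.__setattr__(self, "jump_times", np.asarray(self.jump_times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("cumulative values must be nondecreasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        vals = np.concatenate([[0.0], self.values])
        out = vals[idx]
        return out if out.ndim else float(out)


@dataclass
class IntensityFit:
    """Fitted visit-intensity model: gamma plus the Breslow Lambda0."""

    gamma: np.ndarray
    Lambda0: StepFunction
    converged: bool
    iterations: int
    frailty: str = "none"
    frailty_variance: float | None = None
    score_norm: float = np.nan

    def to_json(self, path) -> None:
        payload = {
            "gamma": list(map(float, np.atleast_1d(self.gamma))),
            "jump_times": list(map(float, self.Lambda0.jump_times)),
            "values": list(map(float, self.Lambda0.values)),
            "frailty": self.frailty,
            "frailty_variance": self.frailty_variance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "IntensityFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gamma=np.asarray(d["gamma"], dtype=float),
            Lambda0=StepFunction(np.asarray(d["jump_times"]), np.asarray(d["values"])),
            converged=True,
            iterations=0,
            frailty=d.get("frailty", "none"),
            frailty_variance=d.get("frailty_variance"),
        )


@dataclass
class FrailtyMoments:
    """Per-subject moment estimates: omega for nu_i, Omega for nu_i^2."""

    omega: np.ndarray
    Omega: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        if np.any(self.omega < 0) or np.any(self.Omega < 0):
            raise ValueError("moment estimates must be nonnegative")


# ---------------------------------------------------------------------------
# risk-set machinery: sums over {j : C_j >= t} via suffix cumsums

class _RiskSet:
    def __init__(self, C: np.ndarray):
        self.order = np.argsort(C, kind="stable")
        self.C_sorted = C[self.order]

    def suffix_sum(self, weights: np.ndarray, query_t: np.ndarray) -> np.ndarray:
        """sum_j I(C_j >= t) * weights_j for each t; weights (n,) or (n, q)."""
        w = weights[self.order]
        rev = np.cumsum(w[::-1], axis=0)[::-1]
        pad = np.zeros((1,) + w.shape[1:])
        ssum = np.concatenate([rev, pad], axis=0)
        idx = np.searchsorted(self.C_sorted, query_t, side="left")
        return ssum[idx]


def _check_covariates(arr: DatasetArrays, names) -> None:
    for j in range(arr.p):
        if np.ptp(arr.X[:, j]) == 0:
            nm = names[j] if names and j < len(names) else f"column {j}"
            raise IdentifiabilityError(
                f"covariate {nm!r} is constant across subjects and cannot be identified"
            )


def _ag_score_info(gamma, arr: DatasetArrays, rs: _RiskSet, nu=None):
    """Score and information of the AG log partial likelihood (Breslow ties).

    ``nu`` optionally weights subjects in the risk sets (gamma-frailty EM).
    """
    X, t, si = arr.X, arr.t, arr.subject_index
    w = np.exp(X @ gamma)
    if nu is not None:
        w = w * nu
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    s0 = rs.suffix_sum(w, t)                        # (V,)
    s1 = rs.suffix_sum(wx, t)                       # (V, p)
    s2 = rs.suffix_sum(wxx.reshape(arr.n, -1), t)   # (V, p*p)
    xbar = s1 / s0[:, None]
    score = (X[si] - xbar).sum(axis=0)
    info = (s2 / s0[:, None]).sum(axis=0).reshape(arr.p, arr.p) - xbar.T @ xbar
    return score, info, s0


def fit_andersen_gill(
    ds: LongitudinalDataset,
    frailty: str = "none",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> IntensityFit:
    """Estimate gamma and Lambda0 for the visit process.

    ``frailty="none"`` (default): Newton-Raphson on the Andersen-Gill
    log partial likelihood with Breslow tie handling; the reported
    Lambda0 is the Breslow estimator at gamma-hat with unit frailty
    weight in the denominator (the convention under which the moment
    estimators omega/Omega are defined).

    ``frailty="gamma"``: shared gamma-frailty fit by EM with the
    frailty variance chosen to maximize the marginal likelihood; used
    by the bladder case-study recipe.  The reported Lambda0 is still
    the unit-weight Breslow estimator at the resulting gamma-hat.
    """
    arr = ds.arrays()
    if arr.n_visits == 0:
        raise ValueError("cannot fit the visit model: dataset has no visits")
    _check_covariates(arr, ds.covariate_names)
    rs = _RiskSet(arr.C)

    if frailty == "none":
        gamma, it, snorm = _newton_ag(arr, rs, tol, max_iter)
        theta = None
    elif frailty == "gamma":
        gamma, theta, it = _gamma_frailty_em(arr, rs)
        snorm = 0.0
    else:
        raise ValueError(f"unknown frailty option {frailty!r}")

    Lam = breslow_baseline(ds, gamma)
    return IntensityFit(gamma=gamma, Lambda0=Lam, converged=True, iterations=it,
                        frailty=frailty, frailty_variance=theta, score_norm=snorm)


def _ag_loglik(gamma, arr, rs, nu=None):
    w = np.exp(arr.X @ gamma)
    if nu is not None:
        w = w * nu
    s0 = rs.suffix_sum(w, arr.t)
    lw = arr.X[arr.subject_index] @ gamma
    if nu is not None:
        lw = lw + np.log(nu[arr.subject_index])
    return np.sum(lw - np.log(s0))


def _newton_ag(arr, rs, tol, max_iter, nu=None, gamma0=None):
    gamma = np.zeros(arr.p) if gamma0 is None else np.asarray(gamma0, float).copy()
    if arr.p == 0:  # covariate-free model: only Lambda0 is estimated
        return gamma, 0, 0.0
    nev = arr.n_visits
    ll = _ag_loglik(gamma, arr, rs, nu=nu)
    for it in range(1, max_iter + 1):
        score, info, _ = _ag_score_info(gamma, arr, rs, nu=nu)
        snorm = np.max(np.abs(score)) / nev
        if snorm < tol:
            return gamma, it, snorm
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise IdentifiabilityError("singular information matrix in AG fit") from exc
        # step-halving: the partial likelihood is concave, but guard overshoot
        frac = 1.0
        for _ in range(30):
            cand = gamma + frac * step
            ll_new = _ag_loglik(cand, arr, rs, nu=nu)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            frac /= 2.0
        gamma, ll = gamma + frac * step, ll_new
    score, _, _ = _ag_score_info(gamma, arr, rs, nu=nu)
    snorm = np.max(np.abs(score)) / nev
    if snorm >= tol:
        raise ConvergenceError(
            f"Andersen-Gill fit did not converge in {max_iter} iterations "
            f"(relative score norm {snorm:.3e})"
        )
    return gamma, max_iter, snorm


def breslow_baseline(ds: LongitudinalDataset, gamma) -> StepFunction:
    """Breslow estimator of the cumulative baseline visit intensity.

    Jumps only at observed visit times u, by
    (number of visits at u) / sum_j I(C_j >= u) exp(X_j' gamma).
    """
    arr = ds.arrays()
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if arr.n_visits == 0:
        return StepFunction(np.array([ds.tau]), np.array([0.0]))
    rs = _RiskSet(arr.C)
    w = np.exp(arr.X @ gamma)
    ut, counts = np.unique(arr.t, return_counts=True)
    denom = rs.suffix_sum(w, ut)
    if np.any(denom <= 0):
        bad = ut[np.argmax(denom <= 0)]
        raise ValueError(f"empty risk set at visit time {bad}")
    return StepFunction(ut, np.cumsum(counts / denom))


def _weighted_breslow(arr, rs, gamma, nu):
    w = np.exp(arr.X @ gamma) * nu
    ut, counts = np.unique(arr.t, return_counts=True)
    denom = rs.suffix_sum(w, ut)
    return StepFunction(ut, np.cumsum(counts / denom))


def _gamma_frailty_em(arr, rs, tol: float = 1e-6, max_outer: int = 40):
    """Shared gamma-frailty AG fit; theta maximizes the marginal likelihood."""
    warm = {"nu": np.ones(arr.n), "gamma": np.zeros(arr.p)}

    def inner(theta):
        nu = warm["nu"].copy()
        gamma = warm["gamma"].copy()
        for _ in range(200):
            gamma_new, _, _ = _newton_ag(arr, rs, 1e-9, 50, nu=nu, gamma0=gamma)
            Lam = _weighted_breslow(arr, rs, gamma_new, nu)
            mu = Lam(arr.C) * np.exp(arr.X @ gamma_new)
            nu_new = (arr.m + 1.0 / theta) / (mu + 1.0 / theta)
            delta = max(np.max(np.abs(gamma_new - gamma)), np.max(np.abs(nu_new - nu)))
            gamma, nu = gamma_new, nu_new
            if delta < tol:
                break
        warm["nu"], warm["gamma"] = nu.copy(), gamma.copy()
        # marginal log-likelihood with the jump sizes profiled in
        Lam = _weighted_breslow(arr, rs, gamma, nu)
        dL = np.diff(np.concatenate([[0.0], Lam.values]))
        jump_of_visit = np.searchsorted(Lam.jump_times, arr.t)
        mu = Lam(arr.C) * np.exp(arr.X @ gamma)
        invt = 1.0 / theta
        ll = (
            np.sum(np.log(dL[jump_of_visit]))
            + np.sum((arr.X @ gamma) * arr.m)
            + np.sum(gammaln(arr.m + invt) - gammaln(invt))
            - arr.n * invt * np.log(theta)
            - np.sum((arr.m + invt) * np.log(mu + invt))
        )
        return gamma, ll

    res = minimize_scalar(
        lambda lt: -inner(np.exp(lt))[1], bounds=(-7.0, 3.0), method="bounded",
        options={"xatol": 1e-2},
    )
    theta = float(np.exp(res.x))
    gamma, _ = inner(theta)
    return gamma, theta, int(res.nfev)


def frailty_moments(ds: LongitudinalDataset, fit: IntensityFit) -> FrailtyMoments:
    """Method-of-moments frailty estimates omega_i (for nu) and Omega_i
    (for nu^2); both are 0 for subjects with no visits, and Omega_i is 0
    whenever m_i <= 1."""
    arr = ds.arrays()
    Lam_C = np.asarray(fit.Lambda0(arr.C), dtype=float)
    if np.any((Lam_C <= 0) & (arr.m >= 1)):
        bad = np.argmax((Lam_C <= 0) & (arr.m >= 1))
        raise ValueError(
            f"Lambda0(C)=0 for subject index {bad} with {arr.m[bad]} visits; "
            "fit and data are inconsistent"
        )
    ex = np.exp(arr.X @ np.atleast_1d(fit.gamma))
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(arr.m >= 1, arr.m / (Lam_C * ex), 0.0)
        Omega = np.where(arr.m >= 2, arr.m * (arr.m - 1) / (Lam_C**2 * ex**2), 0.0)
    return FrailtyMoments(omega=omega, Omega=Omega, m=arr.m.copy())
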