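"""Extended Sun estimator: joint estimation of relative effects and the
intercept trajectory.

The marginal outcome model is ``E(Y(t) | X, nu) = nu * mu0(t) * exp(X'beta)``
with the intercept parameterized on the log scale through a spline basis,
``mu0(t) = exp(B(t)' alpha)``.  Writing ``Z_i(t) = (X_i, B(t))`` and
``eta = (beta, alpha)``, the estimator solves the estimating equation

    L(eta) = sum_i sum_{visits (t, y) of i} [ Z_i(t) y exp(-Z_i(t)'eta) - S(t) ] = 0

where the stabilizing term

    S(t) = sum_j D_j(t) Omega_j exp(X_j'gamma) Z_j(t)
           / sum_j D_j(t) omega_j exp(X_j'gamma)

involves only the visit-model fit (gamma, Breslow Lambda0) and the
frailty moments, not eta itself, so it is precomputed once per visit
time.  The Jacobian of L is ``-sum Z Z' y exp(-Z'eta)``, symmetric
negative semidefinite, so Newton's method with the analytic Jacobian
converges reliably from eta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .dataset import LongitudinalDataset
from .visits import FrailtyMoments, IntensityFit, _RiskSet, ConvergenceError

__all__ = [
    "SplineBasis",
    "ExtendedFit",
    "build_basis",
    "estimating_function_L",
    "solve_extended",
    "predict_trajectory",
]


@dataclass(frozen=True)
class SplineBasis:
    """B-spline basis for the log intercept, with an explicit intercept
    column and the first raw B-spline column dropped (raw B-splines sum
    to one, so keeping all of them alongside an intercept would be
    collinear)."""

    degree: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]
    include_intercept: bool = True

    def __post_init__(self):
        object.__setattr__(self, "interior_knots",
                           np.asarray(self.interior_knots, dtype=float))
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError("boundary must satisfy low < high")
        if len(self.interior_knots):
            if np.any(np.diff(self.interior_knots) <= 0):
                raise ValueError("interior knots must be strictly increasing")
            if self.interior_knots[0] <= lo or self.interior_knots[-1] >= hi:
                raise ValueError("interior knots must lie strictly inside the boundary")

    @property
    def n_raw(self) -> int:
        """Number of raw B-spline columns: interior knots + degree + 1."""
        return len(self.interior_knots) + self.degree + 1

    @property
    def dimension(self) -> int:
        """K: columns of the design actually used in the model."""
        return self.n_raw if self.include_intercept else self.n_raw

    @property
    def column_names(self) -> list[str]:
        if self.include_intercept:
            return ["intercept"] + [f"spline{j}" for j in range(1, self.n_raw)]
        return [f"spline{j}" for j in range(self.n_raw)]

    def _knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate([
            np.full(self.degree + 1, lo), self.interior_knots, np.full(self.degree + 1, hi)
        ])

    def raw_design(self, times) -> np.ndarray:
        """Raw B-spline design matrix; rows sum to one (partition of unity)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.boundary
        if np.any(t < lo) or np.any(t > hi):
            bad = t[(t < lo) | (t > hi)][0]
            raise ValueError(f"time {bad} outside basis boundary [{lo}, {hi}]")
        dm = BSpline.design_matrix(t, self._knot_vector(), self.degree,
                                   extrapolate=False).toarray()
        return dm

    def design(self, times) -> np.ndarray:
        raw = self.raw_design(times)
        if not self.include_intercept:
            return raw
        return np.column_stack([np.ones(raw.shape[0]), raw[:, 1:]])


def build_basis(
    times,
    degree: int = 3,
    n_interior_knots: int = 4,
    boundary: tuple[float, float] | None = None,
) -> SplineBasis:
    """Basis with interior knots at the j/(k+1)-quantiles of ``times``.

    With the default four interior knots the knots sit at the quintiles
    (20/40/60/80th percentiles) of the pooled visit times; quantiles use
    linear interpolation of order statistics.
    """
    t = np.asarray(times, dtype=float)
    if boundary is None:
        boundary = (0.0, float(t.max()))
    distinct = np.unique(t)
    if len(distinct) <= n_interior_knots:
        raise ValueError(
            f"need more than {n_interior_knots} distinct times to place "
            f"{n_interior_knots} interior knots; got {len(distinct)}"
        )
    if n_interior_knots > 0:
        qs = np.arange(1, n_interior_knots + 1) / (n_interior_knots + 1)
        knots = np.quantile(t, qs)
        if np.any(np.diff(knots) <= 0):
            raise ValueError("duplicate interior knots; too few distinct visit times")
    else:
        knots = np.empty(0)
    return SplineBasis(degree=degree, interior_knots=knots, boundary=boundary)


@dataclass
class ExtendedFit:
    """Solution eta = (beta, alpha) of L(eta) = 0 with its basis."""

    eta: np.ndarray
    basis: SplineBasis
    n_covariates: int
    covariate_names: list[str]
    converged: bool
    equation_norm: float
    iterations: int

    @property
    def beta(self) -> np.ndarray:
        return self.eta[: self.n_covariates]

    @property
    def alpha(self) -> np.ndarray:
        return self.eta[self.n_covariates:]

    @property
    def parameter_names(self) -> list[str]:
        return list(self.covariate_names) + self.basis.column_names

    def export(self, path) -> None:
        """Flat text export: basis spec block plus named coefficients,
        sufficient to re-evaluate trajectories exactly."""
        with open(path, "w") as fh:
            fh.write(f"# degree {self.basis.degree}\n")
            fh.write("# interior_knots " + " ".join(f"{k:.17g}" for k in self.basis.interior_knots) + "\n")
            fh.write(f"# boundary {self.basis.boundary[0]:.17g} {self.basis.boundary[1]:.17g}\n")
            for name, val in zip(self.parameter_names, self.eta):
                fh.write(f"{name}\t{val:.17g}\n")


def _context(ds, fit, moments, basis):
    """Precompute the visit design Z, outcomes y, and the eta-free total
    sum of S(t) over visits.

    Sums run over visits with a recorded outcome; visits with missing
    outcomes enter the pipeline only through the intensity stage (they
    still shape Lambda0 and the frailty moments).
    """
    arr = ds.arrays()
    obs = arr.y_observed
    t, y, si = arr.t[obs], arr.y[obs], arr.subject_index[obs]
    B = basis.design(t)                           # (V, K)
    Z = np.column_stack([arr.X[si], B])
    ex = np.exp(arr.X @ np.atleast_1d(fit.gamma))
    a = moments.Omega * ex
    b = moments.omega * ex
    rs = _RiskSet(arr.C)
    den = rs.suffix_sum(b, t)                     # (V,)
    if np.any(den <= 0):
        bad = t[np.argmax(den <= 0)]
        raise ValueError(f"S(t) denominator vanishes at visit time {bad}")
    numX = rs.suffix_sum(a[:, None] * arr.X, t)   # (V, p)
    numA = rs.suffix_sum(a, t)                    # (V,) shared spline factor
    S_total = np.concatenate([
        (numX / den[:, None]).sum(axis=0),
        ((numA / den)[:, None] * B).sum(axis=0),
    ])
    return Z, y, S_total


def estimating_function_L(
    eta,
    ds: LongitudinalDataset,
    fit: IntensityFit,
    moments: FrailtyMoments,
    basis: SplineBasis,
) -> np.ndarray:
    """Value of the extended estimating function L at ``eta``."""
    eta = np.asarray(eta, dtype=float)
    arr = ds.arrays()
    if arr.n_visits == 0:
        return np.zeros(arr.p + basis.dimension)
    Z, y, S_total = _context(ds, fit, moments, basis)
    w = y * np.exp(-(Z @ eta))
    return Z.T @ w - S_total


def _rank_check(Z, y):
    mask = y > 0
    Zp = Z[mask]
    if Zp.shape[0] < Zp.shape[1]:
        raise ValueError("fewer positive-outcome visits than parameters")
    sv = np.linalg.svd(Zp, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        _, r = np.linalg.qr(Zp)
        dep = [j for j in range(r.shape[1]) if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(
            f"design over visits is rank deficient; dependent columns: {dep}"
        )


def solve_extended(
    ds: LongitudinalDataset,
    fit: IntensityFit,
    moments: FrailtyMoments,
    basis: SplineBasis,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ExtendedFit:
    """Solve L(eta) = 0 by Newton iteration with the analytic Jacobian.

    The spline columns are centered over visits (folded into the
    intercept) for conditioning and un-centered on exit; step-halving is
    applied whenever a full Newton step does not reduce ``||L||``.
    """
    arr = ds.arrays()
    Z, y, S_total = _context(ds, fit, moments, basis)
    _rank_check(Z, y)
    p = arr.p
    K = basis.dimension
    # center spline columns (all basis columns except the explicit intercept)
    icol = p  # intercept position in Z
    spl = np.arange(p + 1, p + K) if basis.include_intercept else np.arange(p, p + K)
    mu_c = Z[:, spl].mean(axis=0)
    Zc = Z.copy()
    Zc[:, spl] -= mu_c
    # S_total is a sum of Z-rows, so it transforms like a Z-row:
    # each centered spline entry loses mu_j times the intercept entry
    Sc = S_total.copy()
    if basis.include_intercept:
        Sc[spl] -= mu_c * S_total[icol]

    eta_c = np.zeros(p + K)

    def L_of(ec):
        w = y * np.exp(-(Zc @ ec))
        return Zc.T @ w - Sc, w

    L, w = L_of(eta_c)
    norm = np.max(np.abs(L))
    it = 0
    while norm >= tol and it < max_iter:
        it += 1
        # J = -sum Z Z' y exp(-Z'eta); w already equals y*exp(-Z'eta)
        J = -(Zc * w[:, None]).T @ Zc
        try:
            step = np.linalg.solve(J, -L)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular Jacobian; check design collinearity") from exc
        frac = 1.0
        for _ in range(40):
            cand = eta_c + frac * step
            L_new, w_new = L_of(cand)
            if np.all(np.isfinite(L_new)) and np.max(np.abs(L_new)) < norm:
                break
            frac /= 2.0
        else:
            raise ConvergenceError(
                f"extended estimating equation stalled at ||L||={norm:.3e}"
            )
        eta_c, L, w = cand, L_new, w_new
        norm = np.max(np.abs(L))
    if norm >= tol:
        raise ConvergenceError(
            f"extended estimating equation did not converge: ||L||={norm:.3e} "
            f"after {max_iter} iterations"
        )
    # un-center: Z'eta = Zc'eta_c with eta_j = eta_c_j off-intercept and
    # eta_icol = eta_c_icol - mu_c . eta_c[spl]
    eta = eta_c.copy()
    if basis.include_intercept:
        eta[icol] = eta_c[icol] - mu_c @ eta_c[spl]
    return ExtendedFit(eta=eta, basis=basis, n_covariates=p,
                       covariate_names=list(ds.covariate_names),
                       converged=True, equation_norm=float(norm), iterations=it)


def predict_trajectory(fit: ExtendedFit, times, X=None) -> np.ndarray:
    """Estimated mean outcome exp(B(t)'alpha + X'beta) at each time.

    With X = 0 this is the intercept trajectory mu0-hat(t), the mean
    outcome for a reference (all-covariates-zero) subject with unit
    frailty.
    """
    B = fit.basis.design(times)
    lin = B @ fit.alpha
    if X is not None:
        X = np.atleast_1d(np.asarray(X, dtype=float))
        lin = lin + float(X @ fit.beta)
    return np.exp(lin)
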