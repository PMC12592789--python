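"""Comparator: log-link marginal regression with the same spline basis,
ignoring the dependence between the visit and outcome processes.

With working independence the quasi-score is

    sum_i sum_{visits (t, y) of i} Z_i(t) (y - exp(Z_i(t)' theta)) = 0,

whose root coincides with the point estimate of a Poisson GLM on the
pooled visit rows; statsmodels' IRLS provides the fit.  Standard errors
come from the pipeline bootstrap, never from the GLM itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .dataset import LongitudinalDataset
from .extended import SplineBasis

__all__ = ["GeeFit", "fit_gee_log"]


@dataclass
class GeeFit:
    """Coefficients ordered as (intercept + spline columns, covariates)."""

    coefficients: np.ndarray
    parameter_names: list[str]
    n_covariates: int
    converged: bool
    quasi_score_norm: float

    @property
    def beta(self) -> np.ndarray:
        """Covariate effects (the last ``n_covariates`` coefficients)."""
        return self.coefficients[-self.n_covariates:]

    @property
    def alpha(self) -> np.ndarray:
        return self.coefficients[: -self.n_covariates] if self.n_covariates else self.coefficients


def fit_gee_log(ds: LongitudinalDataset, basis: SplineBasis) -> GeeFit:
    """Independence-working log-link fit on pooled visit records."""
    arr = ds.arrays()
    if arr.n_visits == 0:
        raise ValueError("cannot fit: dataset has no visits")
    obs = arr.y_observed
    t, y, si = arr.t[obs], arr.y[obs], arr.subject_index[obs]
    design = np.column_stack([basis.design(t), arr.X[si]])
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("pooled visit-level design is rank deficient")
    with warnings.catch_warnings():
        # outcomes are continuous; the Poisson family is used only as a
        # quasi-likelihood for its log-link point estimates
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design, family=sm.families.Poisson())
        res = model.fit(maxiter=200, tol=1e-12)
    theta = np.asarray(res.params)
    score = design.T @ (y - np.exp(design @ theta))
    names = basis.column_names + list(ds.covariate_names)
    return GeeFit(
        coefficients=theta,
        parameter_names=names,
        n_covariates=arr.p,
        converged=bool(res.converged),
        quasi_score_norm=float(np.max(np.abs(score))),
    )
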