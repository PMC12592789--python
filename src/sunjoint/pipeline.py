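"""End-to-end fitting recipes shared by the bootstrap, CLI and examples.

The two-stage procedure is always: (1) fit the visit-intensity model
(gamma-hat, Breslow Lambda0) and the per-subject frailty moments; then
(2) fit the requested outcome estimator on top of that stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LongitudinalDataset
from .extended import ExtendedFit, build_basis, solve_extended
from .gee import fit_gee_log
from .sun import solve_sun
from .visits import FrailtyMoments, IntensityFit, fit_andersen_gill, frailty_moments

__all__ = ["PipelineFit", "fit_pipeline", "DEFAULT_BASIS", "CASE_STUDY_BASIS"]

#: simulation-study default: cubic basis, interior knots at the quintiles
DEFAULT_BASIS = {"degree": 3, "n_interior_knots": 4}
#: case-study recipe: cubic basis with 3 interior knots (quartiles)
CASE_STUDY_BASIS = {"degree": 3, "n_interior_knots": 3}


@dataclass
class PipelineFit:
    estimator: str
    coefficients: np.ndarray
    parameter_names: list[str]
    intensity: IntensityFit
    moments: FrailtyMoments
    fit: object  # ExtendedFit | SunFit | GeeFit

    @property
    def beta(self) -> np.ndarray:
        """Covariate (relative-effect) coefficients."""
        return np.atleast_1d(self.fit.beta)


def fit_pipeline(
    ds: LongitudinalDataset,
    estimator: str = "extended",
    basis_spec: dict | None = None,
    frailty: str = "none",
) -> PipelineFit:
    """Fit the full two-stage pipeline with one of the three estimators.

    ``basis_spec`` is a dict with keys ``degree`` and ``n_interior_knots``
    (ignored by the original Sun estimator, which has no intercept); the
    knots are placed on this dataset's pooled visit times.
    """
    intensity = fit_andersen_gill(ds, frailty=frailty)
    moments = frailty_moments(ds, intensity)
    if estimator == "sun":
        f = solve_sun(ds, intensity, moments)
        return PipelineFit("sun", np.atleast_1d(f.beta), list(ds.covariate_names),
                           intensity, moments, f)
    spec = dict(DEFAULT_BASIS if basis_spec is None else basis_spec)
    arr = ds.arrays()
    basis = build_basis(arr.t, degree=spec["degree"],
                        n_interior_knots=spec["n_interior_knots"],
                        boundary=spec.get("boundary", (0.0, ds.tau)))
    if estimator == "extended":
        f = solve_extended(ds, intensity, moments, basis)
        return PipelineFit("extended", f.eta, f.parameter_names, intensity, moments, f)
    if estimator == "gee":
        f = fit_gee_log(ds, basis)
        return PipelineFit("gee", f.coefficients, f.parameter_names, intensity, moments, f)
    raise ValueError(f"unknown estimator {estimator!r}; choose sun, extended or gee")
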