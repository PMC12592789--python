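"""Residual diagnostic for the functional form of the intercept.

For subject i the residual process compares observed (standardized)
outcomes against their compensator under the fitted model:

    R_i(t) = sum_{visits (u, y) of i, u <= t} exp(-Z_i(u)'eta - X_i'gamma) y
             - Omega_i * Lambda0(min(C_i, t))

Under a correctly specified intercept the average Res(t) = mean_i R_i(t)
converges in probability to zero, so plotting Res(t) against t flags a
misspecified basis; this is a diagnostic, not a formal test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset
from .extended import ExtendedFit
from .visits import FrailtyMoments, IntensityFit

__all__ = ["ResidualCurve", "residual_process", "residual_curve"]


@dataclass
class ResidualCurve:
    grid: np.ndarray
    values: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.grid, "Res": self.values})

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.grid, self.values)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("t")
        ax.set_ylabel("Res(t)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _per_subject_terms(ds, fit, intensity, moments):
    """Standardized outcome contribution per visit (observed outcomes only)."""
    arr = ds.arrays()
    obs = arr.y_observed
    t, y, si = arr.t[obs], arr.y[obs], arr.subject_index[obs]
    Z = np.column_stack([arr.X[si], fit.basis.design(t)])
    xg = arr.X @ np.atleast_1d(intensity.gamma)
    r = np.exp(-(Z @ fit.eta) - xg[si]) * y
    return arr, t, si, r


def residual_process(
    ds: LongitudinalDataset,
    subject_id: str,
    fit: ExtendedFit,
    intensity: IntensityFit,
    moments: FrailtyMoments,
    t: float,
) -> float:
    """R_i(t) for one subject (identified by id)."""
    if not 0 <= t <= ds.tau:
        raise ValueError(f"t={t} outside [0, tau={ds.tau}]")
    idx = next((k for k, s in enumerate(ds.subjects) if s.id == subject_id), None)
    if idx is None:
        raise KeyError(f"no subject with id {subject_id!r}")
    arr, vt, si, r = _per_subject_terms(ds, fit, intensity, moments)
    observed = r[(si == idx) & (vt <= t)].sum()
    comp = moments.Omega[idx] * intensity.Lambda0(min(arr.C[idx], t))
    return float(observed - comp)


def residual_curve(
    ds: LongitudinalDataset,
    fit: ExtendedFit,
    intensity: IntensityFit,
    moments: FrailtyMoments,
    grid=None,
) -> ResidualCurve:
    """Res(t) = mean_i R_i(t) on a grid (default: 100 equispaced points
    on [0, tau])."""
    if grid is None:
        grid = np.linspace(0.0, ds.tau, 100)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid.min() < 0 or grid.max() > ds.tau:
        raise ValueError(f"grid must lie within [0, {ds.tau}]")
    arr, vt, si, r = _per_subject_terms(ds, fit, intensity, moments)
    order = np.argsort(vt, kind="stable")
    t_sorted = vt[order]
    csum = np.concatenate([[0.0], np.cumsum(r[order])])
    obs = csum[np.searchsorted(t_sorted, grid, side="right")]
    # compensator: sum_i Omega_i Lambda0(min(C_i, g)) per grid point
    Cmin = np.minimum(arr.C[:, None], grid[None, :])
    comp = (moments.Omega[:, None] * np.asarray(intensity.Lambda0(Cmin))).sum(axis=0)
    return ResidualCurve(grid=grid, values=(obs - comp) / arr.n, n=arr.n)
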