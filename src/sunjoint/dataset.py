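"""Data model for irregularly observed longitudinal outcomes.

A study consists of subjects followed on :math:`[0, \\tau)`, each with
time-invariant covariates :math:`X_i`, an end-of-follow-up (censoring)
time :math:`C_i`, and an outcome :math:`Y_i(t)` recorded only at the
subject's own visit times.  The visit times form a counting process
:math:`N_i(t)` whose intensity may depend on the outcome through a
shared latent frailty, which is what makes the visit scheme
informative.  Subjects with no visits are retained: they still
contribute to risk sets through :math:`\\Delta_i(t) = I(C_i \\ge t)`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Subject",
    "LongitudinalDataset",
    "load_long_format",
    "write_long_format",
    "summarize_visits",
]


class DataValidationError(ValueError):
    """Raised when input data violate the study-design constraints."""


@dataclass
class Subject:
    """One subject: covariates, censoring time, and timed outcome visits.

    ``times`` and ``y`` are aligned arrays (one entry per visit, times
    strictly increasing, all ``<= C``).  A visit at exactly ``t == C``
    is legal since the at-risk indicator is inclusive.
    """

    id: str
    X: np.ndarray
    C: float
    times: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_1d(np.asarray(self.X, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.C = float(self.C)

    @property
    def m(self) -> int:
        """Number of visits :math:`m_i`."""
        return len(self.times)

    def validate(self, tau: float, n_covariates: int) -> None:
        sid = self.id
        if self.X.shape != (n_covariates,):
            raise DataValidationError(
                f"subject {sid!r}: expected {n_covariates} covariates, got {self.X.shape}"
            )
        if not np.all(np.isfinite(self.X)):
            raise DataValidationError(f"subject {sid!r}: non-finite covariate value")
        if not (self.C > 0 and np.isfinite(self.C)):
            raise DataValidationError(f"subject {sid!r}: censoring time must be positive, got {self.C}")
        if len(self.times) != len(self.y):
            raise DataValidationError(f"subject {sid!r}: times and outcomes differ in length")
        if self.m:
            if np.any(np.diff(self.times) <= 0):
                raise DataValidationError(f"subject {sid!r}: visit times must be strictly increasing")
            if self.times[0] < 0:
                raise DataValidationError(f"subject {sid!r}: negative visit time")
            if self.times[-1] > self.C:
                raise DataValidationError(
                    f"subject {sid!r}: visit time {self.times[-1]} exceeds censoring time {self.C}"
                )
            if self.times[-1] > tau:
                raise DataValidationError(
                    f"subject {sid!r}: visit time {self.times[-1]} exceeds tau={tau}"
                )
            obs = ~np.isnan(self.y)
            if np.any(np.isinf(self.y)) or np.any(self.y[obs] < 0):
                raise DataValidationError(
                    f"subject {sid!r}: outcomes must be >= 0 (NaN marks a visit "
                    "whose outcome was not recorded)"
                )


@dataclass
class DatasetArrays:
    """Flat array view of a dataset used by the fitting routines.

    Subject-level arrays are indexed ``0..n-1`` in the order of
    ``dataset.subjects``; visit-level arrays carry the owning subject's
    index in ``subject_index``. Visits are sorted by time within subject
    but ``t`` is not globally sorted.
    """

    C: np.ndarray          # (n,)
    X: np.ndarray          # (n, p)
    m: np.ndarray          # (n,) visit counts
    subject_index: np.ndarray  # (V,)
    t: np.ndarray          # (V,)
    y: np.ndarray          # (V,) NaN where the outcome was not recorded

    @property
    def y_observed(self) -> np.ndarray:
        """Mask of visits with a recorded outcome; visits with missing
        outcomes still count as events for the visit-intensity stage."""
        return ~np.isnan(self.y)

    @property
    def n(self) -> int:
        return len(self.C)

    @property
    def n_visits(self) -> int:
        return len(self.t)

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class LongitudinalDataset:
    subjects: list[Subject]
    tau: float
    covariate_names: list[str]
    _arrays: DatasetArrays | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise DataValidationError("dataset must contain at least one subject")
        if self.tau is None:
            self.tau = max(s.C for s in self.subjects)
        self.tau = float(self.tau)
        seen: set[str] = set()
        for s in self.subjects:
            if s.id in seen:
                raise DataValidationError(f"duplicate subject id {s.id!r}")
            seen.add(s.id)
            s.validate(self.tau, len(self.covariate_names))

    @property
    def n(self) -> int:
        return len(self.subjects)

    def arrays(self) -> DatasetArrays:
        if self._arrays is None:
            n = self.n
            p = len(self.covariate_names)
            C = np.array([s.C for s in self.subjects])
            X = np.array([s.X for s in self.subjects]).reshape(n, p)
            m = np.array([s.m for s in self.subjects])
            if m.sum():
                subject_index = np.concatenate(
                    [np.full(s.m, i) for i, s in enumerate(self.subjects)]
                ).astype(np.intp)
                t = np.concatenate([s.times for s in self.subjects])
                y = np.concatenate([s.y for s in self.subjects])
            else:
                subject_index = np.empty(0, dtype=np.intp)
                t = np.empty(0)
                y = np.empty(0)
            self._arrays = DatasetArrays(C=C, X=X, m=m, subject_index=subject_index, t=t, y=y)
        return self._arrays

    def subset(self, indices: Sequence[int], ids: Iterable[str] | None = None) -> "LongitudinalDataset":
        """New dataset from subject positions (with replacement allowed)."""
        if ids is None:
            ids = [f"r{k}" for k in range(len(indices))]
        subs = [
            Subject(id=sid, X=self.subjects[i].X, C=self.subjects[i].C,
                    times=self.subjects[i].times, y=self.subjects[i].y)
            for sid, i in zip(ids, indices)
        ]
        return LongitudinalDataset(subs, tau=self.tau, covariate_names=list(self.covariate_names))

    def visits_frame(self) -> pd.DataFrame:
        arr = self.arrays()
        ids = [self.subjects[i].id for i in arr.subject_index]
        return pd.DataFrame({"id": ids, "time": arr.t, "y": arr.y})

    def subjects_frame(self) -> pd.DataFrame:
        rows = {"id": [s.id for s in self.subjects], "C": [s.C for s in self.subjects]}
        for j, name in enumerate(self.covariate_names):
            rows[name] = [s.X[j] for s in self.subjects]
        return pd.DataFrame(rows)


def load_long_format(
    visits_path,
    subjects_path=None,
    tau: float | None = None,
) -> LongitudinalDataset:
    """Read a dataset from two CSV files (or one denormalized file).

    ``visits_path`` needs columns ``id, time, y`` (one row per visit);
    ``subjects_path`` needs ``id, C`` plus one column per covariate.
    Every visit id must appear in the subjects file; subjects without
    visit rows are kept with zero visits.  ``tau`` defaults to the
    maximum censoring time.

    With ``subjects_path=None`` a single denormalized file is accepted:
    the visit file then also carries ``C`` and the covariate columns,
    repeated on each of a subject's rows (they must be consistent
    within subject; subjects therefore need at least one row).
    """
    visits = pd.read_csv(visits_path)
    if subjects_path is None:
        subj_cols = [c for c in visits.columns if c not in ("time", "y")]
        if "C" not in subj_cols:
            raise DataValidationError("single-file input requires a C column")
        subjects = visits[subj_cols].drop_duplicates()
        if subjects["id"].duplicated().any():
            bad = subjects.loc[subjects["id"].duplicated(), "id"].iloc[0]
            raise DataValidationError(
                f"subject-level columns are inconsistent across rows of id {bad!r}"
            )
        visits = visits[["id", "time", "y"]]
    else:
        subjects = pd.read_csv(subjects_path)
    for col in ("id", "time", "y"):
        if col not in visits.columns:
            raise DataValidationError(f"visits file missing column {col!r}")
    for col in ("id", "C"):
        if col not in subjects.columns:
            raise DataValidationError(f"subjects file missing column {col!r}")
    covariate_names = [c for c in subjects.columns if c not in ("id", "C")]
    for col in ("time", "y"):
        if not np.issubdtype(visits[col].dtype, np.number):
            raise DataValidationError(f"non-numeric values in visits column {col!r}")
    for col in ["C"] + covariate_names:
        if not np.issubdtype(subjects[col].dtype, np.number):
            raise DataValidationError(f"non-numeric values in subjects column {col!r}")

    subj_ids = subjects["id"].astype(str)
    if subj_ids.duplicated().any():
        dup = subj_ids[subj_ids.duplicated()].iloc[0]
        raise DataValidationError(f"duplicate subject id {dup!r} in subjects file")
    known = set(subj_ids)
    visit_ids = visits["id"].astype(str)
    missing = set(visit_ids) - known
    if missing:
        raise DataValidationError(f"visit rows reference unknown subject id(s): {sorted(missing)!r}")

    grouped = {
        sid: grp.sort_values("time") for sid, grp in visits.assign(id=visit_ids).groupby("id")
    }
    subs = []
    for _, row in subjects.iterrows():
        sid = str(row["id"])
        grp = grouped.get(sid)
        times = grp["time"].to_numpy(float) if grp is not None else np.empty(0)
        ys = grp["y"].to_numpy(float) if grp is not None else np.empty(0)
        subs.append(Subject(id=sid, X=row[covariate_names].to_numpy(float),
                            C=float(row["C"]), times=times, y=ys))
    return LongitudinalDataset(subs, tau=tau, covariate_names=covariate_names)


def write_long_format(ds: LongitudinalDataset, visits_path, subjects_path) -> None:
    ds.visits_frame().to_csv(visits_path, index=False)
    ds.subjects_frame().to_csv(subjects_path, index=False)


def summarize_visits(ds: LongitudinalDataset, group_by: str | None = None) -> pd.DataFrame:
    """Per-group count of subjects and mean/sd of the visit counts m_i.

    ``group_by`` must name a covariate with finitely many values; with
    ``None`` a single overall row is returned.  The sd is the sample
    standard deviation (ddof=1); it is 0 for a single-subject group.
    """
    m = np.array([s.m for s in ds.subjects], dtype=float)
    if group_by is None:
        groups = {"all": np.ones(ds.n, dtype=bool)}
    else:
        if group_by not in ds.covariate_names:
            raise KeyError(
                f"unknown covariate {group_by!r}; available: {ds.covariate_names}"
            )
        j = ds.covariate_names.index(group_by)
        vals = np.array([s.X[j] for s in ds.subjects])
        groups = {v: vals == v for v in np.unique(vals)}
    rows = []
    for g, mask in groups.items():
        mg = m[mask]
        sd = float(np.std(mg, ddof=1)) if len(mg) > 1 else 0.0
        rows.append({"group": g, "n_subjects": int(mask.sum()),
                     "mean_m": float(mg.mean()), "sd_m": sd})
    return pd.DataFrame(rows)
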