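"""Loader for the VACURG bladder-tumor recurrence study.

The study followed bladder cancer patients randomized to placebo,
thiotepa or pyridoxine; at each cystoscopy visit new tumors were counted
and removed.  The analysis here uses the placebo and thiotepa arms, with
the recurrence times as visit times and the number of recurrent tumors
as the outcome.  Covariates: thiotepa indicator (placebo reference) and
the initial tumor count centered at its mean.

The data ship with the R ``survival`` package (dataset ``bladder1``);
:func:`load_bladder_study` exports it via ``Rscript`` at call time, so
an R installation with ``survival`` is required.  Preparation rules:

* pyridoxine arm excluded;
* the one placebo subject with zero follow-up time is excluded
  (leaving 47 placebo and 38 thiotepa subjects);
* recurrence rows with a missing recurrent-tumor count (2 of 132) are
  kept as visits -- they count for the visit-intensity stage -- with the
  outcome marked missing (NaN), so outcome-stage sums skip them.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset, Subject

__all__ = ["load_bladder_study", "bladder_frames"]

_R_EXPORT = """
suppressMessages(library(survival))
d <- bladder1
write.csv(d[, c("id", "treatment", "number", "size", "start", "stop",
                "status", "rtumor")], file = commandArgs(TRUE)[1],
          row.names = FALSE)
"""


def bladder_frames() -> pd.DataFrame:
    """Raw bladder1 rows exported from R's survival package."""
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "bladder1.csv"
        script = Path(tmp) / "export.R"
        script.write_text(_R_EXPORT)
        subprocess.run(["Rscript", str(script), str(out)], check=True,
                       capture_output=True)
        return pd.read_csv(out)


def load_bladder_study(center_number: bool = True) -> LongitudinalDataset:
    """Placebo + thiotepa arms as a LongitudinalDataset.

    Covariates: ``thiotepa`` (1 for the treated arm) and ``number``
    (initial tumor count, centered at the sample mean when
    ``center_number``).  The censoring time is each subject's final
    follow-up time; tau defaults to the maximum censoring time.
    """
    d = bladder_frames()
    d = d[d["treatment"].isin(["placebo", "thiotepa"])]
    fup = d.groupby("id")["stop"].max()
    keep = fup[fup > 0].index
    d = d[d["id"].isin(keep)]
    first = d.drop_duplicates("id").set_index("id")
    number = first["number"].astype(float)
    center = number.mean() if center_number else 0.0
    events = d[d["status"] == 1].copy()
    events["rtumor"] = pd.to_numeric(events["rtumor"], errors="coerce")
    subjects = []
    for sid in first.index:
        ev = events[events["id"] == sid].sort_values("stop")
        subjects.append(Subject(
            id=str(sid),
            X=np.array([1.0 if first.loc[sid, "treatment"] == "thiotepa" else 0.0,
                        number[sid] - center]),
            C=float(fup[sid]),
            times=ev["stop"].to_numpy(float),
            y=ev["rtumor"].to_numpy(float),
        ))
    return LongitudinalDataset(subjects, tau=None,
                               covariate_names=["thiotepa", "number"])
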