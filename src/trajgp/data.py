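"""Containers and I/O for bounded longitudinal clinical trajectories.

A trajectory is a subject's time-ordered sequence of (time-from-onset,
score) visits on a bounded instrument such as the ALSFRS-R total (0-48),
an ALSFRS-R domain subscore (0-12) or percent-predicted forced vital
capacity (0-100).  Times are expressed in years from symptom onset
throughout; readers of tables in months or days convert via the
``time_unit`` entry of the column map.

The module also implements the cohort-level quality-control filters used
before model fitting and the onset anchor: an imputed maximum-score
observation at t = 0 that pins every trajectory's start at the healthy
end of the scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreScale",
    "ALSFRSR",
    "SUBSCORE",
    "FVC",
    "Visit",
    "PatientTrajectory",
    "QCReport",
    "read_long_format",
    "write_long_format",
    "apply_qc_filters",
    "add_onset_anchor",
]

_TIME_UNIT_TO_YEARS = {"years": 1.0, "months": 1.0 / 12.0, "days": 1.0 / 365.25}


@dataclass(frozen=True)
class ScoreScale:
    """A bounded clinical score scale."""

    name: str
    y_max: float
    y_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.y_max > self.y_min:
            raise ValueError(f"y_max ({self.y_max}) must exceed y_min ({self.y_min})")

    @property
    def span(self) -> float:
        return self.y_max - self.y_min


ALSFRSR = ScoreScale("ALSFRS-R", 48.0)
SUBSCORE = ScoreScale("ALSFRS-R subscore", 12.0)
FVC = ScoreScale("FVC %", 100.0)


@dataclass(frozen=True)
class Visit:
    """One scored visit at time ``t`` (years from symptom onset)."""

    t: float
    y: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError(f"visit time must be finite and non-negative, got {self.t}")
        if not np.isfinite(self.y):
            raise ValueError("visit score must be finite")


class TrajectoryError(ValueError):
    """Invalid trajectory construction or operation."""


@dataclass(frozen=True)
class PatientTrajectory:
    """A subject's time-ordered visits on one scale.

    ``anchored`` marks the presence of the imputed onset anchor
    (0, y_max) as the first visit.  ``metadata`` may carry onset site,
    survival time and event flags, or any other per-subject sidecar
    fields.
    """

    subject_id: str
    visits: tuple[Visit, ...]
    scale: ScoreScale
    anchored: bool = False
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [v.t for v in self.visits]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrajectoryError(
                f"visits of {self.subject_id!r} must be strictly increasing in time"
            )
        for v in self.visits:
            if not (self.scale.y_min <= v.y <= self.scale.y_max):
                raise TrajectoryError(
                    f"score {v.y} of {self.subject_id!r} outside "
                    f"[{self.scale.y_min}, {self.scale.y_max}]"
                )
        if self.anchored:
            if not self.visits or self.visits[0].t != 0.0 or self.visits[0].y != self.scale.y_max:
                raise TrajectoryError("anchored trajectory must start with (0, y_max)")

    @classmethod
    def from_arrays(
        cls,
        subject_id: str,
        t: Sequence[float],
        y: Sequence[float],
        scale: ScoreScale,
        anchored: bool = False,
        metadata: Mapping[str, object] | None = None,
        duplicate_policy: str = "average",
    ) -> "PatientTrajectory":
        """Build a trajectory from parallel arrays, sorting by time.

        Duplicate timestamps are averaged (with a warning) or rejected
        depending on ``duplicate_policy`` ("average" | "error").
        """
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise TrajectoryError("t and y must have equal length")
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        if t.size and np.any(np.diff(t) == 0.0):
            if duplicate_policy == "error":
                raise TrajectoryError(f"duplicate visit times for {subject_id!r}")
            warnings.warn(
                f"duplicate visit times for {subject_id!r}; averaging scores",
                stacklevel=2,
            )
            uniq, inv = np.unique(t, return_inverse=True)
            y = np.bincount(inv, weights=y) / np.bincount(inv)
            t = uniq
        visits = tuple(Visit(float(ti), float(yi)) for ti, yi in zip(t, y))
        return cls(subject_id, visits, scale, anchored, dict(metadata or {}))

    # -- array views -------------------------------------------------

    @property
    def t(self) -> np.ndarray:
        return np.array([v.t for v in self.visits])

    @property
    def y(self) -> np.ndarray:
        return np.array([v.y for v in self.visits])

    def measured(self) -> "PatientTrajectory":
        """The trajectory without its onset anchor (a no-op if unanchored)."""
        if not self.anchored:
            return self
        return replace(self, visits=self.visits[1:], anchored=False)

    @property
    def n_measured(self) -> int:
        return len(self.visits) - (1 if self.anchored else 0)

    def first_measured(self) -> Visit:
        if self.n_measured == 0:
            raise TrajectoryError(f"{self.subject_id!r} has no measured visits")
        return self.visits[1] if self.anchored else self.visits[0]


@dataclass
class QCReport:
    """Bookkeeping for cohort quality-control filtering."""

    n_input: int
    n_retained: int
    exclusions: list[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["subject_id", "reason"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_input": self.n_input,
                    "n_retained": self.n_retained,
                    "exclusions": [list(e) for e in self.exclusions],
                },
                indent=2,
            )
        )


class FormatError(ValueError):
    """Input table does not conform to the expected long format."""


def read_long_format(
    path: str | Path,
    scale: ScoreScale,
    column_map: Mapping[str, str] | None = None,
    metadata_path: str | Path | None = None,
    sep: str = ",",
) -> list[PatientTrajectory]:
    """Read a delimited long-format visits table into trajectories.

    ``column_map`` maps logical names {"subject", "time", "score"} to the
    file's column names and may carry a "time_unit" entry
    ("years" | "months" | "days", default years).  Rows with missing or
    unparseable time/score are dropped and counted; the read fails only
    if a required column is absent or no row survives.
    """
    cmap = {"subject": "subject_id", "time": "time_years", "score": "score"}
    cmap.update(column_map or {})
    unit = str(cmap.pop("time_unit", "years"))
    if unit not in _TIME_UNIT_TO_YEARS:
        raise FormatError(f"unknown time unit {unit!r}")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (cmap["subject"], cmap["time"], cmap["score"]) if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")

    df = df.rename(
        columns={cmap["subject"]: "subject", cmap["time"]: "time", cmap["score"]: "score"}
    )
    df["time"] = pd.to_numeric(df["time"], errors="coerce") * _TIME_UNIT_TO_YEARS[unit]
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    n_bad = int(df[["time", "score"]].isna().any(axis=1).sum())
    df = df.dropna(subset=["time", "score"])
    if df.empty:
        raise FormatError(f"no parseable rows in {path} ({n_bad} dropped)")
    if n_bad:
        warnings.warn(f"dropped {n_bad} rows with missing/unparseable time or score")

    meta: dict[str, dict] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path)
        key = mdf.columns[0]
        meta = {str(r[key]): r.drop(key).to_dict() for _, r in mdf.iterrows()}

    out = []
    for sid, grp in df.groupby("subject", sort=True):
        out.append(
            PatientTrajectory.from_arrays(
                str(sid),
                grp["time"].to_numpy(),
                grp["score"].to_numpy(),
                scale,
                metadata=meta.get(str(sid), {}),
            )
        )
    return out


def write_long_format(trajs: Iterable[PatientTrajectory], path: str | Path) -> None:
    """Write trajectories as the canonical (subject_id, time_years, score) CSV."""
    rows = [
        (tr.subject_id, v.t, v.y)
        for tr in trajs
        for v in tr.visits
    ]
    pd.DataFrame(rows, columns=["subject_id", "time_years", "score"]).to_csv(path, index=False)


def apply_qc_filters(
    trajs: Sequence[PatientTrajectory],
    min_visits: int = 3,
    max_first_visit_yr: float = 7.0,
    max_jump: float = 6.0,
) -> tuple[list[PatientTrajectory], QCReport]:
    """Apply the standard cohort quality-control rules.

    A subject is excluded if it has fewer than ``min_visits`` complete
    visits, its first visit falls more than ``max_first_visit_yr`` years
    after symptom onset, or the score increases by more than ``max_jump``
    points between consecutive visits (declines of any size pass; a jump
    that large is most plausibly a data-entry error).  The first rule to
    fire, in that order, is the recorded exclusion reason.
    """
    retained: list[PatientTrajectory] = []
    exclusions: list[tuple[str, str]] = []
    for tr in trajs:
        if tr.anchored:
            raise TrajectoryError("QC filters apply to unanchored (measured) trajectories")
        if len(tr.visits) < min_visits:
            exclusions.append((tr.subject_id, "too_few_visits"))
            continue
        if tr.visits[0].t > max_first_visit_yr:
            exclusions.append((tr.subject_id, "late_first_visit"))
            continue
        if np.any(np.diff(tr.y) > max_jump):
            exclusions.append((tr.subject_id, "score_jump"))
            continue
        retained.append(tr)
    return retained, QCReport(len(trajs), len(retained), exclusions)


def add_onset_anchor(traj: PatientTrajectory) -> PatientTrajectory:
    """Prepend the onset anchor (0, y_max) to a trajectory.

    Raises if the trajectory is already anchored (the operation is not
    idempotent by design) or if a measured visit sits at exactly t = 0,
    which would put two conflicting observations at one timepoint; the
    caller must shift or drop such a visit first.
    """
    if traj.anchored:
        raise TrajectoryError(f"{traj.subject_id!r} is already anchored")
    if traj.visits and traj.visits[0].t == 0.0:
        raise TrajectoryError(
            f"{traj.subject_id!r} has a measured visit at t=0; shift or drop it before anchoring"
        )
    anchor = Visit(0.0, traj.scale.y_max)
    return replace(traj, visits=(anchor,) + traj.visits, anchored=True)
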