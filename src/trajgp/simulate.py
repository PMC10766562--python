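"""Synthetic cohorts of sparse, monotonically declining trajectories.

The generator provides ground truth for tests and experiments: each
cluster has a template decline curve (linear, sigmoid, convex, concave
or stable), subjects draw irregular visit times from a renewal process
with exponential inter-visit gaps (mimicking irregular clinic
schedules), scores are the template plus independent Gaussian noise,
clipped to the instrument's bounds, and survival time is a decreasing
function of the template's first-year decline with log-normal noise —
faster decline, shorter survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ALSFRSR, PatientTrajectory, ScoreScale

__all__ = [
    "ClusterSpec",
    "CohortSpec",
    "template_curve",
    "generate_cohort",
    "write_cohort",
    "default_cohort_spec",
    "two_group_linear_spec",
    "sigmoid_cohort_spec",
    "linear_cohort_spec",
]

SHAPES = ("linear", "sigmoid", "convex", "concave", "stable")


@dataclass(frozen=True)
class ClusterSpec:
    """One generative cluster: a named shape with its parameters.

    Shape parameters:
      linear  : slope (points/year, < 0)
      sigmoid : d50 (years at half-max), dx (decline-duration, years)
      convex  : duration (years to floor), gamma > 1 (early-slow)
      concave : duration, gamma < 1 (early-fast)
      stable  : slope (small decline, points/year)
    """

    shape: str
    params: Mapping[str, float]
    size: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort recipe; fully deterministic given ``seed``.

    visit_rate is the expected visits per year; follow-up is drawn
    uniformly from ``followup_range``; ``first_visit_range`` sets the
    onset-to-baseline delay; ``dropout_per_visit`` is the attrition
    probability applied after every visit; survival parameters (a, b,
    sd) define log T = a − b·(first-year template decline) + sd·ε.
    """

    clusters: tuple[ClusterSpec, ...]
    scale: ScoreScale = ALSFRSR
    noise_sd: float = 1.5
    visit_rate: float = 3.0
    followup_range: tuple[float, float] = (1.8, 2.2)
    first_visit_range: tuple[float, float] = (0.2, 0.8)
    dropout_per_visit: float = 0.02
    min_visits: int = 4
    survival_a: float = 1.6
    survival_b: float = 0.08
    survival_sd: float = 0.3
    survival_horizon: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not self.clusters:
            problems.append("at least one cluster required")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if self.visit_rate <= 0:
            problems.append("visit_rate must be positive")
        if self.min_visits < 1:
            problems.append("min_visits must be >= 1")
        if not 0 <= self.dropout_per_visit < 1:
            problems.append("dropout_per_visit must be in [0, 1)")
        if problems:
            raise ValueError("invalid cohort spec: " + "; ".join(problems))

    @property
    def n_subjects(self) -> int:
        return sum(c.size for c in self.clusters)


def template_curve(shape: str, params: Mapping[str, float], t, scale: ScoreScale = ALSFRSR):
    """Evaluate a cluster's template decline curve, clipped at the floor.

    All shapes start at (or asymptotically near) y_max at t = 0 and are
    monotone non-increasing.
    """
    t = np.asarray(t, float)
    y_max, y_min = scale.y_max, scale.y_min
    if shape == "linear" or shape == "stable":
        s = params["slope"]
        if s > 0:
            raise ValueError("linear/stable slope must be <= 0")
        y = y_max + s * t
    elif shape == "sigmoid":
        d50, dx = params["d50"], params["dx"]
        if d50 <= 0 or dx <= 0:
            raise ValueError("sigmoid d50 and dx must be positive")
        y = y_max / (1.0 + np.exp(np.clip((t - d50) / dx, -500, 500)))
    elif shape in ("convex", "concave"):
        T, g = params["duration"], params["gamma"]
        if T <= 0 or g <= 0:
            raise ValueError("power-law duration and gamma must be positive")
        if shape == "convex" and g <= 1:
            raise ValueError("convex shape requires gamma > 1")
        if shape == "concave" and g >= 1:
            raise ValueError("concave shape requires gamma < 1")
        y = y_max * (1.0 - np.minimum(t / T, 1.0) ** g)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return np.clip(y, y_min, y_max)


def _visit_times(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Irregular schedule: baseline delay + exponential gaps, with
    per-visit attrition; resampled until ``min_visits`` visits exist."""
    for _ in range(1000):
        followup = rng.uniform(*spec.followup_range)
        t0 = rng.uniform(*spec.first_visit_range)
        times = [t0]
        while True:
            gap = rng.exponential(1.0 / spec.visit_rate)
            nxt = times[-1] + gap
            if nxt - t0 > followup:
                break
            times.append(nxt)
            if rng.random() < spec.dropout_per_visit:
                break
        if len(times) >= spec.min_visits:
            return np.round(np.asarray(times), 6)
    raise RuntimeError("could not draw a schedule with the requested minimum visits")


def _truncated_noise(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    """Independent clinician-scoring noise, truncated at 2.5 sd.

    Rater error on a bounded instrument is itself bounded: a scorer does
    not mis-total by 6+ points.  Truncation shrinks the marginal sd by
    ~3.5% relative to ``sd``; draws are by rejection, deterministic
    given the generator state.
    """
    if sd == 0.0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > 2.5 * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > 2.5 * sd
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[PatientTrajectory], pd.DataFrame]:
    """Draw a full synthetic cohort.

    Returns unanchored trajectories and a truth table with one row per
    subject: cluster label, shape, template parameters, survival time
    (years from onset) and event indicator.
    """
    rng = np.random.default_rng(spec.seed)
    trajs: list[PatientTrajectory] = []
    rows = []
    sid = 0
    for ci, cl in enumerate(spec.clusters):
        for _ in range(cl.size):
            subject = f"S{sid:04d}"
            sid += 1
            t = _visit_times(rng, spec)
            template = template_curve(cl.shape, cl.params, t, spec.scale)
            y = template + _truncated_noise(rng, spec.noise_sd, t.size)
            y = np.clip(y, spec.scale.y_min, spec.scale.y_max)
            trajs.append(
                PatientTrajectory.from_arrays(subject, t, y, spec.scale,
                                              metadata={"true_cluster": ci})
            )
            decline_1yr = float(
                spec.scale.y_max - template_curve(cl.shape, cl.params, [1.0], spec.scale)[0]
            )
            log_t = spec.survival_a - spec.survival_b * decline_1yr + rng.normal(0.0, spec.survival_sd)
            t_death = float(np.exp(log_t))
            if t_death <= spec.survival_horizon:
                surv_time, event = t_death, 1
            else:
                surv_time, event = float(t[-1]), 0
            rows.append(
                {
                    "subject_id": subject,
                    "cluster": ci,
                    "cluster_name": cl.name or f"C{ci}",
                    "shape": cl.shape,
                    "params": ";".join(f"{k}={v:g}" for k, v in sorted(cl.params.items())),
                    "decline_1yr": decline_1yr,
                    "survival_time": surv_time,
                    "event": event,
                }
            )
    return trajs, pd.DataFrame(rows)


def write_cohort(trajs, truth: pd.DataFrame, out_dir: str | Path) -> None:
    from .data import write_long_format

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_long_format(trajs, out / "cohort.csv")
    truth.to_csv(out / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# Canonical study conditions used by the test battery and experiments.


def default_cohort_spec(seed: int = 0, size: int = 30, noise_sd: float = 1.5) -> CohortSpec:
    """Four-cluster ALSFRS-R cohort: fast linear, slow linear, sigmoidal
    functional cliff, concave early-fast decline; ~6 visits over 2 yr."""
    return CohortSpec(
        clusters=(
            ClusterSpec("linear", {"slope": -16.0}, size, "linear-fast"),
            ClusterSpec("linear", {"slope": -4.0}, size, "linear-slow"),
            ClusterSpec("sigmoid", {"d50": 1.0, "dx": 0.2}, size, "sigmoid-cliff"),
            ClusterSpec("concave", {"duration": 5.0, "gamma": 0.45}, size, "concave-fast-early"),
        ),
        noise_sd=noise_sd,
        seed=seed,
    )


def two_group_linear_spec(seed: int = 0, size: int = 25, noise_sd: float = 1.0) -> CohortSpec:
    """Two well-separated linear groups (slopes −12 and −2 points/yr)."""
    return CohortSpec(
        clusters=(
            ClusterSpec("linear", {"slope": -12.0}, size, "fast"),
            ClusterSpec("linear", {"slope": -2.0}, size, "slow"),
        ),
        noise_sd=noise_sd,
        seed=seed,
    )


def sigmoid_cohort_spec(seed: int = 0, size: int = 50, noise_sd: float = 1.5) -> CohortSpec:
    """Sigmoidal cohort with staggered onset-to-baseline delays and long
    follow-up, for interpolation/forecasting experiments: the late cliff
    is invisible within a short window after baseline for early
    presenters but visible through later presenters."""
    return CohortSpec(
        clusters=(
            ClusterSpec("sigmoid", {"d50": 1.5, "dx": 0.3}, size // 2, "cliff-early"),
            ClusterSpec("sigmoid", {"d50": 2.5, "dx": 0.4}, size - size // 2, "cliff-late"),
        ),
        noise_sd=noise_sd,
        visit_rate=4.0,
        followup_range=(2.5, 3.5),
        first_visit_range=(0.2, 1.5),
        dropout_per_visit=0.0,
        min_visits=6,
        seed=seed,
    )


def linear_cohort_spec(seed: int = 0, size: int = 50, noise_sd: float = 1.0) -> CohortSpec:
    """Exactly-linear heterogeneous cohort for the linear-regime control."""
    rng = np.random.default_rng(seed + 90001)
    slopes = rng.uniform(-14.0, -2.0, size=4)
    quarter = size // 4
    sizes = [quarter, quarter, quarter, size - 3 * quarter]
    return CohortSpec(
        clusters=tuple(
            ClusterSpec("linear", {"slope": float(s)}, sz, f"lin{i}")
            for i, (s, sz) in enumerate(zip(slopes, sizes))
        ),
        noise_sd=noise_sd,
        visit_rate=4.0,
        followup_range=(2.5, 3.5),
        first_visit_range=(0.2, 1.5),
        dropout_per_visit=0.0,
        min_visits=6,
        seed=seed,
    )
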