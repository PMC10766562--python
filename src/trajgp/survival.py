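"""Survival correspondence of trajectory clusters.

Kaplan–Meier product-limit curves per cluster, pairwise logrank tests
with Benjamini–Hochberg FDR correction across all cluster pairs, and
the summary fraction of pairs showing differential survival.  Survival
time runs from symptom onset; subjects without a recorded death are
censored at their last recorded visit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .data import PatientTrajectory
from .model import MoGPResults

__all__ = [
    "SurvivalRecord",
    "records_from_trajectories",
    "KMCurve",
    "km_curve",
    "pairwise_logrank",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-subject time-to-event (years from symptom onset)."""

    subject_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(f"survival time must be positive, got {self.time}")


def records_from_trajectories(
    trajs: Iterable[PatientTrajectory],
    survival_key: str = "survival_time",
    event_key: str = "event",
) -> list[SurvivalRecord]:
    """Derive survival records from trajectory metadata; subjects without
    a recorded death are censored at the last recorded visit."""
    out = []
    for tr in trajs:
        meta = tr.metadata
        if event_key in meta and bool(meta[event_key]):
            out.append(SurvivalRecord(tr.subject_id, float(meta[survival_key]), True))
        else:
            out.append(SurvivalRecord(tr.subject_id, float(tr.measured().t[-1]), False))
    return out


@dataclass
class KMCurve:
    """A fitted Kaplan–Meier curve with its risk table."""

    times: np.ndarray  # event/censoring times in the risk table
    survival: np.ndarray  # S(t) immediately after each time
    table: pd.DataFrame  # at_risk / censored / deaths per time

    def at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_csv(self, path: str | Path) -> None:
        df = self.table.copy()
        df["survival"] = self.survival
        df.to_csv(path, index_label="time")


def km_curve(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate with at-risk/censored/death counts."""
    if not records:
        raise ValueError("no survival records")
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records], bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ev = kmf.event_table[kmf.event_table.index > 0]
    table = pd.DataFrame(
        {
            "at_risk": ev["at_risk"].astype(int),
            "censored": ev["censored"].astype(int),
            "deaths": ev["observed"].astype(int),
        }
    )
    # product-limit from the integer risk table (exact rational factors)
    surv = np.cumprod(1.0 - table["deaths"].to_numpy() / table["at_risk"].to_numpy())
    return KMCurve(ev.index.to_numpy(float), surv, table)


def pairwise_logrank(
    results: MoGPResults,
    records: Sequence[SurvivalRecord],
    alpha_level: float = 0.05,
    min_cluster_records: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Pairwise logrank tests between cluster survival curves.

    Returns the matrix of BH-adjusted p-values (unit diagonal,
    symmetric) and the fraction of evaluable unordered pairs with
    adjusted p < ``alpha_level``.  Clusters with fewer than
    ``min_cluster_records`` records are excluded; pairs with fewer than
    two events in total are non-evaluable (NaN) and excluded from the
    fraction's denominator.
    """
    by_subject = {r.subject_id: r for r in records}
    groups: dict[int, list[SurvivalRecord]] = {}
    for cl in results.clusters:
        recs = [by_subject[s] for s in cl.member_ids if s in by_subject]
        if len(recs) < min_cluster_records:
            logger.info("survival: cluster %d excluded (%d records)", cl.cluster_id, len(recs))
            continue
        groups[cl.cluster_id] = recs
    cids = sorted(groups)
    if len(cids) < 2:
        raise ValueError("need at least two clusters with survival records")

    pairs = list(combinations(cids, 2))
    raw = []
    evaluable = []
    for a, b in pairs:
        ra, rb = groups[a], groups[b]
        n_events = sum(r.event for r in ra) + sum(r.event for r in rb)
        if n_events < 2:
            raw.append(np.nan)
            evaluable.append(False)
            continue
        res = logrank_test(
            [r.time for r in ra], [r.time for r in rb],
            event_observed_A=[r.event for r in ra],
            event_observed_B=[r.event for r in rb],
        )
        raw.append(float(res.p_value))
        evaluable.append(True)

    adj = np.full(len(pairs), np.nan)
    mask = np.array(evaluable)
    if mask.any():
        adj[mask] = multipletests(np.asarray(raw)[mask], method="fdr_bh")[1]

    mat = pd.DataFrame(np.eye(len(cids)), index=cids, columns=cids)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p
    n_eval = int(mask.sum())
    fraction = float(np.sum(adj[mask] < alpha_level) / n_eval) if n_eval else np.nan
    return mat, fraction
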