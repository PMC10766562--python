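"""Model scoring and evaluation experiments.

Per-patient accuracy is the RMSE between measured scores and the
model's predicted trajectory — for mixture models the mean function of
the subject's (assigned or predicted) cluster, for patient-specific
benchmarks the fitted curve.  The experiment harnesses reproduce three
designs: interpolation of randomly withheld visits, forecasting beyond
a right-censoring horizon, and transfer of a reference model to
external cohorts against study-specific models and a shuffled-label
control.  Statistical comparisons use the two-sample Kolmogorov–Smirnov
test, the one-sided Wilcoxon signed-rank test, and per-cluster
hypergeometric enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .benchmarks import fit_anchored_slope, fit_sigmoid
from .data import PatientTrajectory, add_onset_anchor
from .model import Cluster, MixtureOfGPs, MoGPConfig, MoGPResults

__all__ = [
    "PatientError",
    "rmse",
    "rmse_to_cluster_mean",
    "first_year_slope",
    "interpolation_experiment",
    "censoring_experiment",
    "transfer_experiment",
    "meta_cluster",
    "compare_error_distributions",
    "cluster_enrichment",
    "MIXTURE_MODELS",
    "PATIENT_MODELS",
]

logger = logging.getLogger(__name__)

MIXTURE_MODELS = {"MoGP": "se", "LKM": "linear"}
PATIENT_MODELS = ("SM", "SG")


@dataclass(frozen=True)
class PatientError:
    subject_id: str
    model: str
    rmse: float
    n_eval_points: int


def rmse(predicted, observed) -> float:
    predicted = np.asarray(predicted, float).ravel()
    observed = np.asarray(observed, float).ravel()
    if observed.size == 0:
        raise ValueError("empty evaluation set")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def rmse_to_cluster_mean(
    results: MoGPResults,
    traj: PatientTrajectory,
    eval_visits: PatientTrajectory | None = None,
    model_label: str = "MoGP",
) -> PatientError:
    """RMSE between a subject's measured visits and their cluster mean.

    Evaluation always uses measured (never anchor) visits.  If the
    subject is in the model, its training assignment is used; otherwise
    membership is predicted from ``traj``.
    """
    ev = (eval_visits or traj).measured()
    if ev.n_measured == 0:
        raise ValueError("empty evaluation set")
    if traj.subject_id in results.assignments:
        cid = results.assignments[traj.subject_id]
    else:
        cid = results.predict(traj).cluster_id
    pred, _ = results.cluster_mean_function(cid, ev.t)
    return PatientError(traj.subject_id, model_label, rmse(pred, ev.y), ev.n_measured)


def first_year_slope(cluster: Cluster, y_max: float) -> float:
    """Decline magnitude of the cluster mean over the first year:
    (y_max − mean(1 yr)) / 1 yr, in points/year; positive = decline."""
    mean1 = float(cluster.mean_function([1.0])[0][0])
    return (y_max - mean1) / 1.0


# ---------------------------------------------------------------------------
# experiment harnesses


def _fit_mixtures(train_trajs, models, config, seed):
    fits = {}
    for label in models:
        if label in MIXTURE_MODELS:
            fits[label] = MixtureOfGPs(
                train_trajs, kernel=MIXTURE_MODELS[label], config=config
            ).fit(seed=seed)
    return fits


def _score_subject(label, mixture_fits, train_traj, eval_t, eval_y):
    """Predicted scores at eval times for one subject under one model."""
    if label in MIXTURE_MODELS:
        res = mixture_fits[label]
        cid = res.assignments[train_traj.subject_id]
        return res.cluster_mean_function(cid, eval_t)[0]
    if label == "SM":
        return fit_anchored_slope(train_traj).predict(eval_t)
    if label == "SG":
        return fit_sigmoid(train_traj).predict(eval_t)
    raise ValueError(f"unknown model label {label!r}")


def interpolation_experiment(
    trajs: Sequence[PatientTrajectory],
    fractions: Sequence[float] = (0.25, 0.50, 0.75),
    models: Sequence[str] = ("MoGP", "LKM", "SM"),
    seed: int = 0,
    config: MoGPConfig | None = None,
    min_visits: int = 10,
) -> pd.DataFrame:
    """Withhold visits at random and score reconstruction error.

    Each fraction names the share of a subject's visits *provided* as
    training data (rounded half-up, floor of 2); the withheld complement
    is the evaluation set.  Only subjects with at least ``min_visits``
    measured visits enter.  Mixture models are refit per fraction on the
    retained cohort.
    """
    config = config or MoGPConfig(n_sweeps=30)
    trajs = [tr.measured() for tr in trajs if tr.n_measured >= min_visits]
    if not trajs:
        raise ValueError(f"no subjects with >= {min_visits} visits")
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(len(fractions) * 2)
    for fi, frac in enumerate(fractions):
        rng = np.random.default_rng(seeds[2 * fi])
        splits = {}
        for tr in trajs:
            n = tr.n_measured
            n_train = max(2, int(math.floor(frac * n + 0.5)))
            if n - n_train < 1:
                logger.info("interpolation: %s skipped at fraction %g", tr.subject_id, frac)
                continue
            keep = np.sort(rng.choice(n, size=n_train, replace=False))
            mask = np.zeros(n, bool)
            mask[keep] = True
            train = PatientTrajectory.from_arrays(
                tr.subject_id, tr.t[mask], tr.y[mask], tr.scale
            )
            splits[tr.subject_id] = (add_onset_anchor(train), tr.t[~mask], tr.y[~mask])
        mix = _fit_mixtures(
            [s[0] for s in splits.values()], models, config, int(seeds[2 * fi + 1] % 2**31)
        )
        for sid, (train, et, ey) in splits.items():
            for label in models:
                pred = _score_subject(label, mix, train, et, ey)
                rows.append((frac, sid, label, rmse(pred, ey), et.size))
    return pd.DataFrame(
        rows, columns=["condition", "subject_id", "model", "rmse", "n_eval_points"]
    )


def censoring_experiment(
    trajs: Sequence[PatientTrajectory],
    horizons: Sequence[float] = (0.25, 0.5, 1.0, 1.5, 2.0),
    models: Sequence[str] = ("MoGP", "LKM", "SM"),
    seed: int = 0,
    config: MoGPConfig | None = None,
    min_visits: int = 4,
) -> pd.DataFrame:
    """Train on visits within a horizon after baseline, forecast the rest.

    Horizons are measured from each subject's first measured visit (the
    baseline), not from symptom onset.  Subjects with no post-horizon
    visits, or fewer than two training visits, are skipped.
    """
    config = config or MoGPConfig(n_sweeps=30)
    trajs = [tr.measured() for tr in trajs if tr.n_measured >= min_visits]
    if not trajs:
        raise ValueError(f"no subjects with >= {min_visits} visits")
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(len(horizons))
    for hi, horizon in enumerate(horizons):
        splits = {}
        for tr in trajs:
            t, y = tr.t, tr.y
            mask = t <= t[0] + horizon
            if mask.sum() < 2 or mask.all():
                logger.info("censoring: %s skipped at horizon %g", tr.subject_id, horizon)
                continue
            train = PatientTrajectory.from_arrays(tr.subject_id, t[mask], y[mask], tr.scale)
            splits[tr.subject_id] = (add_onset_anchor(train), t[~mask], y[~mask])
        if not splits:
            continue
        mix = _fit_mixtures(
            [s[0] for s in splits.values()], models, config, int(seeds[hi] % 2**31)
        )
        for sid, (train, et, ey) in splits.items():
            for label in models:
                pred = _score_subject(label, mix, train, et, ey)
                rows.append((horizon, sid, label, rmse(pred, ey), et.size))
    return pd.DataFrame(
        rows, columns=["condition", "subject_id", "model", "rmse", "n_eval_points"]
    )


def transfer_experiment(
    reference_cohort: Sequence[PatientTrajectory],
    target_cohorts: Mapping[str, Sequence[PatientTrajectory]],
    split: float = 0.6,
    n_splits: int = 5,
    seed: int = 0,
    config: MoGPConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-vs-study-specific transfer of trajectory clusters.

    For each of ``n_splits`` random 60/40 train–test splits: fit the
    reference model on the reference training split and a study-specific
    model on each target's training split; score every target test
    subject under both, plus a shuffled-cluster-label control on the
    reference predictions, and score the reference model on its own
    held-out test split ("baseline").

    Returns (per-subject tidy table, per-dataset summary with mean RMSE,
    0.95 normal CIs across subjects, and a paired one-sided Wilcoxon
    p-value over split means for reference < study-specific).
    """
    config = config or MoGPConfig(n_sweeps=30)
    for name, cohort in target_cohorts.items():
        if len(cohort) < 5:
            raise ValueError(f"target cohort {name!r} has fewer than 5 subjects")
    rows = []
    root = np.random.SeedSequence(seed)
    for si, child in enumerate(root.spawn(n_splits)):
        rng = np.random.default_rng(child)
        fit_seed = int(child.generate_state(1)[0] % 2**31)

        def split_cohort(cohort):
            idx = rng.permutation(len(cohort))
            n_train = int(round(split * len(cohort)))
            return [cohort[i] for i in idx[:n_train]], [cohort[i] for i in idx[n_train:]]

        ref_train, ref_test = split_cohort(list(reference_cohort))
        ref_model = MixtureOfGPs(ref_train, config=config).fit(seed=fit_seed)

        def score(model_results, test_trajs, dataset, label, shuffle_rng=None):
            preds = [model_results.predict(tr) for tr in test_trajs]
            cids = [p.cluster_id for p in preds]
            if shuffle_rng is not None:
                cids = [cids[i] for i in shuffle_rng.permutation(len(cids))]
            for tr, cid in zip(test_trajs, cids):
                ev = tr.measured()
                pred, _ = model_results.cluster_mean_function(cid, ev.t)
                rows.append((si, dataset, label, tr.subject_id, rmse(pred, ev.y), ev.n_measured))

        score(ref_model, ref_test, "reference_set", "baseline")
        for name, cohort in target_cohorts.items():
            tgt_train, tgt_test = split_cohort(list(cohort))
            study_model = MixtureOfGPs(tgt_train, config=config).fit(seed=fit_seed + 1)
            score(ref_model, tgt_test, name, "reference")
            score(study_model, tgt_test, name, "study_specific")
            score(ref_model, tgt_test, name, "shuffled", shuffle_rng=rng)
    table = pd.DataFrame(
        rows, columns=["split", "dataset", "model", "subject_id", "rmse", "n_eval_points"]
    )

    summaries = []
    for (dataset, model), grp in table.groupby(["dataset", "model"]):
        errs = grp["rmse"].to_numpy()
        half = 1.96 * errs.std(ddof=1) / math.sqrt(errs.size) if errs.size > 1 else np.nan
        summaries.append(
            {
                "dataset": dataset,
                "model": model,
                "mean_rmse": errs.mean(),
                "ci_low": errs.mean() - half,
                "ci_high": errs.mean() + half,
                "n": errs.size,
            }
        )
    summary = pd.DataFrame(summaries)
    pvals = {}
    for dataset in target_cohorts:
        sub = table[table["dataset"] == dataset]
        ref_means = sub[sub["model"] == "reference"].groupby("split")["rmse"].mean()
        stu_means = sub[sub["model"] == "study_specific"].groupby("split")["rmse"].mean()
        _, p = compare_error_distributions(
            ref_means.to_numpy(), stu_means.to_numpy(), test="wilcoxon_one_sided"
        )
        pvals[dataset] = p
    summary["wilcoxon_p_ref_lt_study"] = summary["dataset"].map(pvals)
    return table, summary


def meta_cluster(
    first_year_slopes: Sequence[float],
    length_scales: Sequence[float],
    k: int = 4,
    random_state: int = 0,
) -> np.ndarray:
    """Group mixture components in (first-year slope, log length-scale)
    space by k-means on standardized coordinates.

    Returns one group label per component, with labels ordered by the
    group's mean slope magnitude (0 = slowest progression).
    """
    slopes = np.asarray(first_year_slopes, float)
    ls = np.asarray(length_scales, float)
    if slopes.size != ls.size:
        raise ValueError("slope and length-scale vectors must align")
    if slopes.size < k:
        raise ValueError(f"need at least k={k} components, got {slopes.size}")
    X = StandardScaler().fit_transform(np.column_stack([slopes, np.log(ls)]))
    raw = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(X)
    order = np.argsort([np.abs(slopes[raw == g]).mean() for g in range(k)])
    relabel = np.empty(k, int)
    relabel[order] = np.arange(k)
    return relabel[raw]


def compare_error_distributions(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    test: str = "ks_two_sided",
) -> tuple[float, float]:
    """Compare two per-patient error samples.

    "ks_two_sided": two-sample Kolmogorov–Smirnov on the two CDFs.
    "wilcoxon_one_sided": paired signed-rank with the alternative that
    model A improves on model B (lower error).  Identical paired samples
    give p = 1 (no evidence of improvement).
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    if test == "ks_two_sided":
        res = stats.ks_2samp(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon_one_sided":
        if a.size != b.size:
            raise ValueError("wilcoxon requires paired samples of equal length")
        if np.all(a == b):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="less")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def cluster_enrichment(
    results: MoGPResults, attribute: Mapping[str, bool]
) -> pd.DataFrame:
    """Hypergeometric enrichment of a binary subject attribute per cluster.

    For each cluster the p-value is the upper-tail probability of seeing
    at least the observed number of attribute-positive members when
    drawing the cluster's membership from the cohort without
    replacement.  Subjects lacking the attribute are excluded from the
    totals.
    """
    known = {s for s in results.assignments if s in attribute}
    dropped = set(results.assignments) - known
    if dropped:
        logger.info("enrichment: %d subjects lack the attribute and are excluded", len(dropped))
    M = len(known)
    K = sum(bool(attribute[s]) for s in known)
    rows = []
    for cl in results.clusters:
        members = [s for s in cl.member_ids if s in known]
        n = len(members)
        k = sum(bool(attribute[s]) for s in members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if n else np.nan
        rows.append((cl.cluster_id, n, k, min(p, 1.0) if n else np.nan))
    return pd.DataFrame(rows, columns=["cluster", "n", "n_positive", "p_value"])
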