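"""Dirichlet-process mixture of Gaussian processes for trajectory clustering.

Each mixture component is a GP over time-from-onset with a negative
linear mean and (by default) a squared-exponential kernel; the Dirichlet
process prior lets the number of components be learned from the data.
Inference is collapsed Gibbs sampling over cluster assignments — the
Chinese-restaurant-process conditional, with each cluster's GP marginal
likelihood collapsed over its pooled member visits — interleaved with
type-II maximum-likelihood re-optimization of each cluster's
hyperparameters.  The returned state is the one with the highest log
joint posterior seen along the chain.

A monotonic inductive bias is enforced two ways: the prior mean slope is
constrained non-positive, and a subject may only enter a cluster whose
mean function at the subject's first measured visit is not substantially
below the subject's score there (the admissibility margin) — i.e. a
still-healthy subject cannot join a cluster that has already declined
past them.

The API follows the model/results convention: build a
:class:`MixtureOfGPs` from anchored trajectories, call :meth:`fit`, and
work with the returned :class:`MoGPResults`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .data import PatientTrajectory, ScoreScale, TrajectoryError
from .gp import (
    GPHyperparams,
    GPPosterior,
    HyperPriors,
    default_bounds,
    optimize_hyperparams,
)

__all__ = [
    "MoGPConfig",
    "MixtureOfGPs",
    "MoGPResults",
    "Cluster",
    "MembershipPrediction",
    "monotonic_admissibility",
    "assignment_distribution",
    "default_component_hyper",
]


def default_component_hyper(scale: ScoreScale) -> GPHyperparams:
    """Prior-mean hyperparameters used to seed components and score the
    new-cluster option.

    Signal sd a quarter of the scale span (trajectories wander well away
    from the mean line), noise sd ~6% of the span (a few ALSFRS-R
    points), length-scale 1 yr, mean slope −0.175·span per year (a
    typical observed median decline rate).
    """
    span = scale.span
    return GPHyperparams(
        signal_variance=(span / 4.0) ** 2,
        length_scale=1.0,
        noise_variance=(span / 16.0) ** 2,
        mean_slope=-0.175 * span,
        mean_intercept=scale.y_max,
    )


@dataclass(frozen=True)
class MoGPConfig:
    """Fitting configuration for the DP mixture.

    margin : admissibility margin in score points; default 5 on the
        ALSFRS-R scale, scaled proportionally for other scales.
    alpha : DP concentration; larger values favour more clusters.
    n_sweeps : Gibbs sweep budget; early stop after ``early_stop``
        consecutive sweeps with no assignment moves.
    """

    alpha: float = 1.0
    margin: float | None = None
    n_sweeps: int = 50
    early_stop: int = 5
    kernel: str = "se"
    init_clusters: int | None = None
    opt_maxiter: int = 30
    jitter_frac: float = 1e-6
    use_priors: bool = True
    bounds: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")

    def resolved_margin(self, scale: ScoreScale) -> float:
        if self.margin is not None:
            return self.margin
        return 5.0 * scale.span / 48.0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["bounds"] is not None:
            d["bounds"] = {k: list(v) for k, v in d["bounds"].items()}
        return d


@dataclass(frozen=True)
class Cluster:
    """A fitted mixture component: members, hyperparameters, posterior."""

    cluster_id: int
    member_ids: tuple[str, ...]
    hyper: GPHyperparams
    posterior: GPPosterior

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def mean_function(self, times) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and pointwise variance over ``times``.

        The 0.95 interval is mean ± 1.96·sqrt(variance).
        """
        return self.posterior(times)


@dataclass(frozen=True)
class MembershipPrediction:
    """Predicted cluster membership for an out-of-model subject."""

    subject_id: str
    cluster_id: int
    log_scores: Mapping[int, float]
    confidence: float
    low_confidence: bool = False


def monotonic_admissibility(
    traj: PatientTrajectory, posterior: GPPosterior, margin: float
) -> bool:
    """True iff the subject's first measured score does not exceed the
    cluster mean there by more than ``margin`` points."""
    first = traj.first_measured()
    if not np.isfinite(margin):
        return True
    mean, _ = posterior([first.t])
    return bool(first.y <= mean[0] + margin)


def assignment_distribution(
    traj: PatientTrajectory,
    clusters: Sequence[tuple[int, GPPosterior]],
    alpha: float,
    margin: float,
    new_cluster_posterior: GPPosterior,
) -> np.ndarray:
    """Collapsed CRP conditional over {existing clusters..., new cluster}.

    ``clusters`` holds (size, posterior-without-this-subject) pairs.
    Existing cluster k gets unnormalized weight n_k · p(y | cluster k);
    the new-cluster option gets α · p(y | prior); inadmissible clusters
    get exactly zero.  Returns probabilities summing to 1, new-cluster
    option last.
    """
    t, y = traj.t, traj.y
    logw = np.full(len(clusters) + 1, -np.inf)
    for i, (n_k, post) in enumerate(clusters):
        if n_k <= 0:
            continue
        if monotonic_admissibility(traj, post, margin):
            logw[i] = math.log(n_k) + post.predictive_logpdf(t, y)
    logw[-1] = math.log(alpha) + new_cluster_posterior.predictive_logpdf(t, y)
    norm = logsumexp(logw)
    p = np.exp(logw - norm)
    return p / p.sum()


class _ClusterState:
    """Mutable fitting state for one component."""

    __slots__ = ("members", "hyper", "posterior")

    def __init__(self, members: list[str], hyper: GPHyperparams):
        self.members = members
        self.hyper = hyper
        self.posterior: GPPosterior | None = None

    def rebuild(self, subjects, kernel, jitter_frac):
        t = np.concatenate([subjects[s][0] for s in self.members])
        y = np.concatenate([subjects[s][1] for s in self.members])
        self.posterior = GPPosterior.fit(t, y, self.hyper, kernel, jitter_frac)


class MixtureOfGPs:
    """Dirichlet-process mixture of GPs over anchored trajectories.

    Parameters
    ----------
    trajectories : anchored :class:`PatientTrajectory` instances sharing
        one scale.  Scores are modelled on their native scale.
    kernel : "se" for the full model, "linear" for the linear-kernel
        benchmark; everything else in the inference engine is shared so
        the comparison isolates the kernel choice.
    config : :class:`MoGPConfig`; individual keyword overrides accepted.
    """

    def __init__(
        self,
        trajectories: Sequence[PatientTrajectory],
        kernel: str | None = None,
        config: MoGPConfig | None = None,
        **overrides,
    ):
        if not trajectories:
            raise TrajectoryError("cohort is empty")
        scale = trajectories[0].scale
        for tr in trajectories:
            if not tr.anchored:
                raise TrajectoryError(f"{tr.subject_id!r} is not anchored")
            if tr.scale != scale:
                raise TrajectoryError("all trajectories must share one scale")
            if tr.n_measured == 0:
                raise TrajectoryError(f"{tr.subject_id!r} has no measured visits")
        ids = [tr.subject_id for tr in trajectories]
        if len(set(ids)) != len(ids):
            raise TrajectoryError("duplicate subject ids in cohort")
        config = config or MoGPConfig()
        if kernel is not None:
            overrides["kernel"] = kernel
        if overrides:
            config = replace(config, **overrides)
        self.config = config
        self.scale = scale
        self.trajectories = {tr.subject_id: tr for tr in trajectories}
        self._subjects = {tr.subject_id: (tr.t, tr.y) for tr in trajectories}
        self.base_hyper = default_component_hyper(scale)
        self.priors: HyperPriors | None = None
        if config.use_priors:
            from .gp import default_priors

            self.priors = default_priors(scale.y_max)

    # ------------------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self._subjects)

    def _optimize_cluster(self, state: _ClusterState) -> None:
        t = np.concatenate([self._subjects[s][0] for s in state.members])
        y = np.concatenate([self._subjects[s][1] for s in state.members])
        fitted, _ = optimize_hyperparams(
            t,
            y,
            state.hyper,
            bounds=self.config.bounds or default_bounds(self.scale.y_max),
            priors=self.priors,
            kernel=self.config.kernel,
            jitter_frac=self.config.jitter_frac,
            maxiter=self.config.opt_maxiter,
        )
        state.hyper = fitted
        state.rebuild(self._subjects, self.config.kernel, self.config.jitter_frac)

    def _log_joint(self, states: dict[int, _ClusterState]) -> float:
        n = self.n_subjects
        a = self.config.alpha
        lj = gammaln(a) - gammaln(a + n) + len(states) * math.log(a)
        for st in states.values():
            lj += gammaln(len(st.members))
            lj += st.posterior.log_marginal_likelihood
            if self.priors is not None:
                lj += self.priors.logpdf(st.hyper)
        return float(lj)

    def fit(self, seed: int = 0) -> "MoGPResults":
        """Run collapsed Gibbs + hyperparameter optimization; return the
        maximum-log-joint state.  Deterministic given ``seed``."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        ids = sorted(self._subjects)
        n = len(ids)
        margin = cfg.resolved_margin(self.scale)

        k0 = cfg.init_clusters or max(2, min(n, n // 10 + 1))
        init_labels = rng.integers(0, k0, size=n)
        states: dict[int, _ClusterState] = {}
        assign: dict[str, int] = {}
        for lbl in np.unique(init_labels):
            members = [ids[i] for i in np.flatnonzero(init_labels == lbl)]
            states[int(lbl)] = _ClusterState(members, self.base_hyper)
            for s in members:
                assign[s] = int(lbl)
        next_cid = int(max(states) + 1)
        for st in states.values():
            self._optimize_cluster(st)

        prior_post = GPPosterior.fit(
            np.empty(0), np.empty(0), self.base_hyper, cfg.kernel, cfg.jitter_frac
        )

        trace_rows = []
        best = {"log_joint": -np.inf, "assign": None, "hypers": None}

        def record(sweep, phase):
            lj = self._log_joint(states)
            trace_rows.append(
                {"sweep": sweep, "phase": phase, "log_joint": lj, "n_clusters": len(states)}
            )
            if lj > best["log_joint"]:
                best["log_joint"] = lj
                best["assign"] = dict(assign)
                best["hypers"] = {cid: st.hyper for cid, st in states.items()}
            return lj

        record(0, "init")
        quiet = 0
        for sweep in range(1, cfg.n_sweeps + 1):
            moves = 0
            for s in rng.permutation(ids):
                s = str(s)
                old = assign[s]
                src = states[old]
                src.members.remove(s)
                if src.members:
                    src.rebuild(self._subjects, cfg.kernel, cfg.jitter_frac)
                else:
                    del states[old]
                cids = sorted(states)
                options = [(len(states[c].members), states[c].posterior) for c in cids]
                probs = assignment_distribution(
                    self.trajectories[s], options, cfg.alpha, margin, prior_post
                )
                choice = int(rng.choice(len(probs), p=probs))
                if choice < len(cids):
                    new = cids[choice]
                    states[new].members.append(s)
                else:
                    new = next_cid
                    next_cid += 1
                    states[new] = _ClusterState([s], self.base_hyper)
                states[new].rebuild(self._subjects, cfg.kernel, cfg.jitter_frac)
                assign[s] = new
                if new != old:
                    moves += 1
            record(sweep, "assignment")
            for st in states.values():
                self._optimize_cluster(st)
            record(sweep, "hyper")
            quiet = quiet + 1 if moves == 0 else 0
            if quiet >= cfg.early_stop:
                break

        # restore and finalize the best state
        final_states: dict[int, _ClusterState] = {}
        for cid, hyper in best["hypers"].items():
            members = sorted(s for s, c in best["assign"].items() if c == cid)
            if not members:
                continue
            st = _ClusterState(members, hyper)
            st.rebuild(self._subjects, cfg.kernel, cfg.jitter_frac)
            final_states[cid] = st
        # relabel clusters by size (largest first) for stable presentation
        order = sorted(final_states, key=lambda c: (-len(final_states[c].members), c))
        clusters = []
        assignments = {}
        for new_cid, cid in enumerate(order):
            st = final_states[cid]
            clusters.append(
                Cluster(new_cid, tuple(st.members), st.hyper, st.posterior)
            )
            for s in st.members:
                assignments[s] = new_cid

        return MoGPResults(
            model=self,
            clusters=clusters,
            assignments=assignments,
            alpha=cfg.alpha,
            trace=pd.DataFrame(trace_rows),
            seed=seed,
            log_joint=best["log_joint"],
        )


@dataclass
class MoGPResults:
    """Fitted DP mixture of GPs.

    Carries the component set, the subject→cluster assignment map, the
    per-sweep log-joint trace, and the seed/config needed to reproduce
    the fit exactly.
    """

    model: MixtureOfGPs
    clusters: list[Cluster]
    assignments: dict[str, int]
    alpha: float
    trace: pd.DataFrame
    seed: int
    log_joint: float

    # ------------------------------------------------------------------

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def scale(self) -> ScoreScale:
        return self.model.scale

    def cluster(self, cluster_id: int) -> Cluster:
        return self.clusters[cluster_id]

    def cluster_mean_function(self, cluster_id: int, times) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and pointwise variance of one cluster at ``times``."""
        return self.clusters[cluster_id].mean_function(times)

    def predict(
        self, traj: PatientTrajectory, margin: float | None = None
    ) -> MembershipPrediction:
        """Predict cluster membership for a subject not in the model.

        Scores every admissible existing cluster by the DP posterior
        predictive (log cluster size + predictive log-likelihood of the
        subject's visits under the cluster posterior); never creates a
        new cluster.  If no cluster is admissible, the cluster whose
        mean at the first visit is closest is returned, flagged
        low-confidence.
        """
        if traj.scale != self.scale:
            raise TrajectoryError("trajectory scale differs from model scale")
        margin = self.model.config.resolved_margin(self.scale) if margin is None else margin
        t, y = traj.t, traj.y
        scores: dict[int, float] = {}
        admissible: dict[int, bool] = {}
        for cl in self.clusters:
            admissible[cl.cluster_id] = monotonic_admissibility(traj, cl.posterior, margin)
            scores[cl.cluster_id] = math.log(cl.size) + cl.posterior.predictive_logpdf(t, y)
        ok = [cid for cid, a in admissible.items() if a]
        if ok:
            vals = np.array([scores[c] for c in ok])
            probs = np.exp(vals - logsumexp(vals))
            best = ok[int(np.argmax(vals))]
            conf = float(probs[int(np.argmax(vals))])
            return MembershipPrediction(traj.subject_id, best, scores, conf, False)
        first = traj.first_measured()
        gaps = {
            cl.cluster_id: abs(float(cl.posterior([first.t])[0][0]) - first.y)
            for cl in self.clusters
        }
        best = min(gaps, key=gaps.get)
        return MembershipPrediction(traj.subject_id, best, scores, 0.0, True)

    def shuffle_cluster_labels(self, seed: int = 0) -> "MoGPResults":
        """Negative control: permute subject→cluster assignments uniformly
        at random, leaving cluster posteriors fixed."""
        rng = np.random.default_rng(seed)
        sids = sorted(self.assignments)
        labels = [self.assignments[s] for s in sids]
        shuffled = dict(zip(sids, (labels[i] for i in rng.permutation(len(labels)))))
        clusters = [
            replace(
                cl,
                member_ids=tuple(sorted(s for s, c in shuffled.items() if c == cl.cluster_id)),
            )
            for cl in self.clusters
        ]
        return replace(self, clusters=clusters, assignments=shuffled)

    def admissibility_violations(self, margin: float | None = None) -> list[tuple[str, int]]:
        """Post-hoc audit: (subject, cluster) pairs violating the
        monotonic admissibility constraint in the final model."""
        margin = self.model.config.resolved_margin(self.scale) if margin is None else margin
        out = []
        for cl in self.clusters:
            for s in cl.member_ids:
                if not monotonic_admissibility(self.model.trajectories[s], cl.posterior, margin):
                    out.append((s, cl.cluster_id))
        return out

    # ------------------------------------------------------------------

    def summary(self) -> str:
        """Cluster summary table, largest clusters first."""
        rows = []
        for cl in self.clusters:
            mean1 = float(cl.mean_function([1.0])[0][0])
            rows.append(
                {
                    "cluster": cl.cluster_id,
                    "n": cl.size,
                    "first_year_slope": (self.scale.y_max - mean1) / 1.0,
                    "length_scale": cl.hyper.length_scale,
                    "mean_slope": cl.hyper.mean_slope,
                    "noise_sd": math.sqrt(cl.hyper.noise_variance),
                }
            )
        df = pd.DataFrame(rows)
        header = (
            f"Mixture of Gaussian processes ({self.model.config.kernel} kernel)\n"
            f"subjects: {self.model.n_subjects}   clusters: {self.n_clusters}   "
            f"alpha: {self.alpha:g}   seed: {self.seed}   log joint: {self.log_joint:.2f}\n"
        )
        return header + df.to_string(index=False, float_format=lambda v: f"{v:.3f}")

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for cl in self.clusters:
            mean1 = float(cl.mean_function([1.0])[0][0])
            rows.append(
                (cl.cluster_id, cl.size, (self.scale.y_max - mean1),
                 cl.hyper.length_scale, cl.hyper.mean_slope,
                 math.sqrt(cl.hyper.noise_variance))
            )
        return pd.DataFrame(
            rows,
            columns=["cluster", "n", "first_year_slope", "length_scale", "mean_slope", "noise_sd"],
        )

    # ------------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to JSON sufficient to reconstruct posteriors exactly."""
        payload = {
            "kernel": self.model.config.kernel,
            "config": self.model.config.to_dict(),
            "scale": {"name": self.scale.name, "y_max": self.scale.y_max, "y_min": self.scale.y_min},
            "alpha": self.alpha,
            "seed": self.seed,
            "log_joint": self.log_joint,
            "assignments": self.assignments,
            "clusters": [
                {"cluster_id": cl.cluster_id, "members": list(cl.member_ids),
                 "hyper": asdict(cl.hyper)}
                for cl in self.clusters
            ],
            "subjects": {
                sid: {"t": tr.t.tolist(), "y": tr.y.tolist(), "anchored": tr.anchored}
                for sid, tr in self.model.trajectories.items()
            },
            "trace": self.trace.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "MoGPResults":
        d = json.loads(Path(path).read_text())
        scale = ScoreScale(d["scale"]["name"], d["scale"]["y_max"], d["scale"]["y_min"])
        trajs = [
            PatientTrajectory.from_arrays(
                sid, rec["t"], rec["y"], scale, anchored=rec["anchored"]
            )
            for sid, rec in d["subjects"].items()
        ]
        cfg_d = dict(d["config"])
        if cfg_d.get("bounds"):
            cfg_d["bounds"] = {k: tuple(v) for k, v in cfg_d["bounds"].items()}
        model = MixtureOfGPs(trajs, config=MoGPConfig(**cfg_d))
        clusters = []
        for rec in d["clusters"]:
            hyper = GPHyperparams(**rec["hyper"])
            members = tuple(rec["members"])
            t = np.concatenate([model._subjects[s][0] for s in members])
            y = np.concatenate([model._subjects[s][1] for s in members])
            post = GPPosterior.fit(t, y, hyper, model.config.kernel, model.config.jitter_frac)
            clusters.append(Cluster(rec["cluster_id"], members, hyper, post))
        return cls(
            model=model,
            clusters=clusters,
            assignments={k: int(v) for k, v in d["assignments"].items()},
            alpha=d["alpha"],
            trace=pd.DataFrame(d["trace"]),
            seed=d["seed"],
            log_joint=d["log_joint"],
        )


def fit_mogp(
    trajectories: Sequence[PatientTrajectory],
    config: MoGPConfig | None = None,
    seed: int = 0,
    **overrides,
) -> MoGPResults:
    """Convenience wrapper: build and fit the SE-kernel mixture."""
    return MixtureOfGPs(trajectories, config=config, **overrides).fit(seed=seed)
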