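"""DP mixture: admissibility, collapsed conditional, fitting, prediction."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score

from trajgp.data import ALSFRSR, add_onset_anchor
from trajgp.gp import GPHyperparams, GPPosterior, kernel_matrix, linear_mean
from trajgp.model import (
    MixtureOfGPs,
    MoGPConfig,
    assignment_distribution,
    default_component_hyper,
    monotonic_admissibility,
)

from conftest import make_traj

HYPER = GPHyperparams(signal_variance=9.0, length_scale=1.0, noise_variance=1.0,
                      mean_slope=-6.0, mean_intercept=48.0)


def _posterior(t, y, h=HYPER):
    return GPPosterior.fit(np.asarray(t, float), np.asarray(y, float), h, jitter_frac=0.0)


class TestAdmissibility:
    def test_first_visit_far_above_cluster_mean_is_inadmissible(self):
        # cluster tracks a steep decline; a near-ceiling subject cannot join
        post = _posterior([0.5, 1.0], [30.0, 24.0])
        traj = add_onset_anchor(make_traj("s", [0.5, 1.0], [47.0, 45.0]))
        assert not monotonic_admissibility(traj, post, margin=5.0)

    def test_equality_within_margin_passes(self):
        post = _posterior([0.5], [30.0])
        mean_at_half = float(post([0.5])[0][0])
        traj = add_onset_anchor(make_traj("s", [0.5], [mean_at_half]))
        assert monotonic_admissibility(traj, post, margin=5.0)

    def test_infinite_margin_disables_constraint(self):
        post = _posterior([0.5], [5.0])
        traj = add_onset_anchor(make_traj("s", [0.5], [48.0]))
        assert monotonic_admissibility(traj, post, margin=np.inf)


class TestAssignmentDistribution:
    def test_crp_prior_arithmetic_when_likelihoods_equal(self):
        """Equal likelihoods across options reduce the conditional to the
        CRP prior: sizes [2, 1], alpha 1 -> [2/4, 1/4, 1/4]."""
        post = _posterior([0.5, 1.5], [44.0, 38.0])
        traj = add_onset_anchor(make_traj("s", [1.0], [41.0]))
        probs = assignment_distribution(
            traj, [(2, post), (1, post)], alpha=1.0, margin=np.inf,
            new_cluster_posterior=post,
        )
        np.testing.assert_allclose(probs, [0.5, 0.25, 0.25], atol=1e-12)

    def test_inadmissible_cluster_gets_exactly_zero(self):
        low = _posterior([0.5, 1.0], [20.0, 15.0])
        high = _posterior([0.5, 1.0], [46.0, 44.0])
        prior = _posterior([], [])
        traj = add_onset_anchor(make_traj("s", [0.5, 1.0], [47.0, 46.0]))
        probs = assignment_distribution(
            traj, [(3, low), (3, high)], alpha=1.0, margin=3.0,
            new_cluster_posterior=prior,
        )
        assert probs[0] == 0.0
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-12)

    def test_matches_exhaustive_partition_enumeration(self):
        """The collapsed conditional for the third subject equals the ratio
        of full joint partition probabilities (CRP exchangeable partition
        function x dense multivariate-normal cluster marginals)."""
        rng = np.random.default_rng(17)
        alpha = 1.3
        subj = {}
        for sid in "abc":
            t = np.sort(rng.uniform(0.2, 3, 3))
            y = np.clip(48 - 8 * t + rng.normal(0, 2, 3), 0, 48)
            subj[sid] = (t, y)

        def cluster_marglik(members):
            t = np.concatenate([subj[s][0] for s in members])
            y = np.concatenate([subj[s][1] for s in members])
            K = kernel_matrix(t, t, HYPER) + HYPER.noise_variance * np.eye(t.size)
            return multivariate_normal(linear_mean(t, HYPER), K).logpdf(y)

        def log_joint(partition):
            lp = len(partition) * math.log(alpha)
            for block in partition:
                lp += gammaln(len(block)) + cluster_marglik(block)
            return lp

        # 'a' and 'b' sit in separate clusters; enumerate options for 'c'
        options = [[["a", "c"], ["b"]], [["a"], ["b", "c"]], [["a"], ["b"], ["c"]]]
        logw = np.array([log_joint(p) for p in options])
        oracle = np.exp(logw - logw.max())
        oracle /= oracle.sum()

        traj_c = make_traj("c", *subj["c"], anchored=False)
        probs = assignment_distribution(
            traj_c,
            [(1, _posterior(*subj["a"])), (1, _posterior(*subj["b"]))],
            alpha=alpha,
            margin=np.inf,
            new_cluster_posterior=_posterior([], []),
        )
        np.testing.assert_allclose(probs, oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        clusters = []
        for _ in range(int(rng.integers(1, 4))):
            t = np.sort(rng.uniform(0.1, 3, 4))
            y = np.clip(48 - rng.uniform(2, 14) * t + rng.normal(0, 2, 4), 0, 48)
            clusters.append((int(rng.integers(1, 9)), _posterior(t, y)))
        traj = add_onset_anchor(
            make_traj("s", [0.5, 1.5], np.clip(rng.uniform(10, 47, 2)[::-1].cumsum()[::-1] / 2 + 10, 0, 48))
        )
        probs = assignment_distribution(
            traj, clusters, alpha=0.7, margin=5.0, new_cluster_posterior=_posterior([], [])
        )
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-12)
        assert np.all(probs >= 0)


class TestFit:
    def test_identical_trajectories_collapse_to_one_cluster(self):
        t = [0.5, 1.0, 1.5, 2.0]
        y = [42.0, 36.0, 30.0, 24.0]
        trajs = [add_onset_anchor(make_traj(f"s{i}", t, y)) for i in range(20)]
        res = MixtureOfGPs(trajs, config=MoGPConfig(n_sweeps=15)).fit(seed=0)
        assert res.n_clusters == 1
        assert res.clusters[0].size == 20

    def test_two_well_separated_groups_recovered_exactly(self, two_group_cohort, two_group_fit):
        _, truth = two_group_cohort
        pred = [two_group_fit.assignments[s] for s in truth.subject_id]
        assert adjusted_rand_score(truth.cluster, pred) == 1.0
        assert two_group_fit.n_clusters == 2

    def test_same_seed_reproduces_assignments_and_trace(self, two_group_cohort, two_group_fit):
        trajs, _ = two_group_cohort
        again = MixtureOfGPs(trajs, config=MoGPConfig(n_sweeps=20)).fit(seed=5)
        assert again.assignments == two_group_fit.assignments
        assert again.trace.equals(two_group_fit.trace)

    def test_assignments_form_partition_without_empty_clusters(self, two_group_cohort, two_group_fit):
        trajs, _ = two_group_cohort
        assert sorted(two_group_fit.assignments) == sorted(tr.subject_id for tr in trajs)
        sizes = [cl.size for cl in two_group_fit.clusters]
        assert all(s > 0 for s in sizes)
        assert sum(sizes) == len(trajs)
        members = [s for cl in two_group_fit.clusters for s in cl.member_ids]
        assert sorted(members) == sorted(two_group_fit.assignments)

    def test_no_admissibility_violations_post_hoc(self, two_group_fit):
        assert two_group_fit.admissibility_violations() == []

    def test_log_joint_non_decreasing_over_hyper_steps(self, two_group_fit):
        tr = two_group_fit.trace
        for sweep, grp in tr[tr.phase != "init"].groupby("sweep"):
            a = grp.loc[grp.phase == "assignment", "log_joint"]
            h = grp.loc[grp.phase == "hyper", "log_joint"]
            if len(a) and len(h):
                assert float(h.iloc[0]) >= float(a.iloc[0]) - 1e-6

    def test_trace_log_joint_finite(self, two_group_fit):
        assert np.isfinite(two_group_fit.trace.log_joint).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(Exception, match="empty"):
            MixtureOfGPs([])

    def test_unanchored_cohort_rejected(self):
        with pytest.raises(Exception, match="not anchored"):
            MixtureOfGPs([make_traj("a", [0.5, 1.0, 1.5], [44, 40, 36])])


class TestPredictMembership:
    def test_trajectory_on_cluster_mean_recovers_cluster(self, two_group_fit):
        for cl in two_group_fit.clusters:
            grid = np.array([0.5, 1.0, 1.5, 2.0])
            mean, _ = cl.mean_function(grid)
            traj = add_onset_anchor(
                make_traj("new", grid, np.clip(mean, 0, 48))
            )
            pred = two_group_fit.predict(traj)
            assert pred.cluster_id == cl.cluster_id
            others = [v for c, v in pred.log_scores.items() if c != cl.cluster_id]
            assert all(pred.log_scores[cl.cluster_id] > v for v in others)

    def test_single_cluster_model_gives_confidence_one(self):
        t, y = [0.5, 1.0, 1.5], [42.0, 36.0, 30.0]
        trajs = [add_onset_anchor(make_traj(f"s{i}", t, y)) for i in range(6)]
        res = MixtureOfGPs(trajs, config=MoGPConfig(n_sweeps=10)).fit(seed=1)
        assert res.n_clusters == 1
        pred = res.predict(add_onset_anchor(make_traj("new", [0.7], [40.0])))
        assert pred.cluster_id == 0 and pred.confidence == 1.0

    def test_no_admissible_cluster_flagged_low_confidence(self, two_group_fit):
        # late near-ceiling subject: every fitted cluster mean has declined
        traj = add_onset_anchor(make_traj("new", [3.5, 4.0], [48.0, 47.0]))
        pred = two_group_fit.predict(traj, margin=1.0)
        assert pred.low_confidence
        # falls back to the cluster whose mean at 3.5 yr is closest to 48
        gaps = {
            cl.cluster_id: abs(float(cl.mean_function([3.5])[0][0]) - 48.0)
            for cl in two_group_fit.clusters
        }
        assert pred.cluster_id == min(gaps, key=gaps.get)

    def test_simulated_members_recovered(self, two_group_cohort, two_group_fit):
        """Held-out subjects drawn from each group's generative curve land
        in that group's cluster in nearly every replicate."""
        rng = np.random.default_rng(99)
        slope_to_cid = {}
        for slope in (-12.0, -2.0):
            t = np.array([0.4, 0.9, 1.4, 1.9])
            probe = add_onset_anchor(make_traj("probe", t, np.clip(48 + slope * t, 0, 48)))
            slope_to_cid[slope] = two_group_fit.predict(probe).cluster_id
        assert slope_to_cid[-12.0] != slope_to_cid[-2.0]
        hits = 0
        for rep in range(50):
            slope = (-12.0, -2.0)[rep % 2]
            t = np.sort(rng.uniform(0.3, 2.0, 4))
            y = np.clip(48 + slope * t + rng.normal(0, 1.0, 4), 0, 48)
            pred = two_group_fit.predict(add_onset_anchor(make_traj("h", t, y)))
            hits += pred.cluster_id == slope_to_cid[slope]
        assert hits >= 48  # >= 95%


class TestShuffleAndMeans:
    def test_shuffle_preserves_size_multiset_and_partition(self, two_group_fit):
        sh = two_group_fit.shuffle_cluster_labels(seed=2)
        assert sorted(cl.size for cl in sh.clusters) == sorted(
            cl.size for cl in two_group_fit.clusters
        )
        assert sorted(sh.assignments) == sorted(two_group_fit.assignments)

    def test_single_cluster_shuffle_is_identity(self):
        t, y = [0.5, 1.0, 1.5], [42.0, 36.0, 30.0]
        trajs = [add_onset_anchor(make_traj(f"s{i}", t, y)) for i in range(5)]
        res = MixtureOfGPs(trajs, config=MoGPConfig(n_sweeps=8)).fit(seed=1)
        sh = res.shuffle_cluster_labels(seed=7)
        assert sh.assignments == res.assignments

    def test_shuffled_control_degrades_fit(self, two_group_cohort, two_group_fit):
        trajs, _ = two_group_cohort
        sh = two_group_fit.shuffle_cluster_labels(seed=3)
        assert sh.assignments != two_group_fit.assignments

        def total_rmse(res):
            tot = 0.0
            for tr in trajs:
                ev = tr.measured()
                pred, _ = res.cluster_mean_function(res.assignments[tr.subject_id], ev.t)
                tot += float(np.sqrt(np.mean((pred - ev.y) ** 2)))
            return tot

        assert total_rmse(sh) > total_rmse(two_group_fit)

    def test_cluster_mean_matches_direct_gp_on_pooled_data(self, two_group_fit):
        from trajgp.gp import gp_posterior

        cl = two_group_fit.clusters[0]
        model = two_group_fit.model
        t = np.concatenate([model.trajectories[s].t for s in cl.member_ids])
        y = np.concatenate([model.trajectories[s].y for s in cl.member_ids])
        grid = np.linspace(0, 3, 25)
        mean_o, var_o = gp_posterior(t, y, cl.hyper, grid)
        mean, var = cl.mean_function(grid)
        np.testing.assert_allclose(mean, mean_o, atol=1e-10)
        np.testing.assert_allclose(var, var_o, atol=1e-10)

    def test_anchored_cluster_mean_pinned_near_max_at_onset(self, two_group_fit):
        for cl in two_group_fit.clusters:
            mean0 = float(cl.mean_function([0.0])[0][0])
            assert abs(mean0 - 48.0) < 1.5

    def test_mean_reverts_to_linear_mean_far_beyond_data(self, two_group_fit):
        cl = two_group_fit.clusters[0]
        far = 60.0
        mean_far = float(cl.mean_function([far])[0][0])
        prior_far = cl.hyper.mean_intercept + cl.hyper.mean_slope * far
        assert abs(mean_far - prior_far) < 1e-3


class TestSerialization:
    def test_roundtrip_reconstructs_posteriors_exactly(self, two_group_fit, tmp_path):
        from trajgp.model import MoGPResults

        p = tmp_path / "model.json"
        two_group_fit.save(p)
        back = MoGPResults.load(p)
        assert back.assignments == two_group_fit.assignments
        assert back.alpha == two_group_fit.alpha
        grid = np.linspace(0, 3, 17)
        for cl, cl2 in zip(two_group_fit.clusters, back.clusters):
            assert cl.hyper == cl2.hyper
            assert cl.member_ids == cl2.member_ids
            m1, v1 = cl.mean_function(grid)
            m2, v2 = cl2.mean_function(grid)
            assert np.array_equal(m1, m2) and np.array_equal(v1, v2)

    def test_saved_file_bytes_stable_across_reruns(self, two_group_cohort, tmp_path):
        trajs, _ = two_group_cohort
        paths = []
        for i in (1, 2):
            res = MixtureOfGPs(trajs, config=MoGPConfig(n_sweeps=12)).fit(seed=9)
            p = tmp_path / f"m{i}.json"
            res.save(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


def test_default_component_hyper_scales_with_instrument():
    h48 = default_component_hyper(ALSFRSR)
    from trajgp.data import SUBSCORE

    h12 = default_component_hyper(SUBSCORE)
    assert h48.mean_intercept == 48.0 and h12.mean_intercept == 12.0
    np.testing.assert_allclose(h48.signal_variance / h12.signal_variance, 16.0)
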