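"""Unit and property tests for the edge-network / entropy pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from edgentropy import (CommunityProfile, EdgeCommunityLabels,
                        EdgeTimeSeries, RoiTimeSeries, SubnetworkMap,
                        aggregate_entropy, cluster_edges, community_profile,
                        compute_edge_time_series, nodal_entropy,
                        residualize_covariates, zscore_timeseries)
from edgentropy.edge_network import SUBNETWORK_LABELS


def _ts(values, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"R{i:03d}" for i in range(values.shape[0])]
    return RoiTimeSeries(values, ids)


class TestZscore:
    def test_already_standardized_row_unchanged(self):
        out = zscore_timeseries(_ts([[1.0, -1.0]]))
        np.testing.assert_allclose(out.values, [[1.0, -1.0]])

    def test_population_sd_convention(self):
        out = zscore_timeseries(_ts([[0.0, 1.0, 2.0]]))
        np.testing.assert_allclose(out.values[0],
                                   [-1.2247449, 0.0, 1.2247449], atol=1e-6)

    def test_constant_region_raises_with_name(self):
        with pytest.raises(ValueError, match="R001"):
            zscore_timeseries(_ts([[1, 2, 3], [5, 5, 5]]))


class TestEdgeTimeSeries:
    def test_anticorrelated_pair(self):
        z = zscore_timeseries(_ts([[-1, 1], [1, -1]]))
        ets = compute_edge_time_series(z)
        np.testing.assert_allclose(ets.values, [[-1.0, -1.0]])
        raw = np.array([[-1.0, 1.0], [1.0, -1.0]])
        r = np.corrcoef(raw)[0, 1]
        assert abs(ets.values[0].mean() - r) < 1e-12

    def test_identical_rows_give_unit_mean(self, rng):
        x = rng.standard_normal(50)
        z = zscore_timeseries(_ts(np.vstack([x, x + 0.0])))
        ets = compute_edge_time_series(z)
        np.testing.assert_allclose(ets.values[0], z.values[0] ** 2)
        assert abs(ets.values[0].mean() - 1.0) < 1e-12

    def test_edge_count_formula(self, rng):
        z = zscore_timeseries(_ts(rng.standard_normal((200, 5))))
        assert compute_edge_time_series(z).n_edges == 19_900

    def test_single_region_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_edge_time_series(_ts(rng.standard_normal((1, 10))))

    def test_time_mean_equals_pearson_on_random_inputs(self, rng):
        """Time-averaging the eTS recovers the Pearson correlation."""
        for _ in range(20):
            raw = rng.standard_normal((20, 100))
            z = zscore_timeseries(_ts(raw))
            ets = compute_edge_time_series(z)
            r = np.corrcoef(raw)
            iu, ju = np.triu_indices(20, k=1)
            dev = np.abs(ets.values.mean(axis=1) - r[iu, ju]).max()
            assert dev < 1e-10


class TestClusterEdges:
    def test_k1_sse_equals_total_scatter(self, rng):
        ets = EdgeTimeSeries(rng.standard_normal((30, 12)), np.empty((0, 2)))
        lab = cluster_edges(ets, k=1, n_restarts=3, seed=0)
        assert np.all(lab.labels == 1)
        total = ((ets.values - ets.values.mean(axis=0)) ** 2).sum()
        assert abs(lab.sse - total) < 1e-8 * total

    def test_recovers_two_planted_patterns(self, rng):
        p1, p2 = rng.standard_normal((2, 60))
        truth = np.repeat([0, 1], 40)
        rows = np.where(truth[:, None] == 0, p1, p2) \
            + 0.3 * rng.standard_normal((80, 60))
        lab = cluster_edges(EdgeTimeSeries(rows, np.empty((0, 2))), k=2,
                            n_restarts=25, seed=1)
        assert adjusted_rand_score(truth, lab.labels) == 1.0

    def test_selected_sse_is_minimum_of_restarts(self, rng):
        ets = EdgeTimeSeries(rng.standard_normal((100, 20)), np.empty((0, 2)))
        lab = cluster_edges(ets, k=5, n_restarts=25, seed=3)
        assert lab.restart_sse.size == 25
        assert lab.sse <= lab.restart_sse.min() + 1e-12
        assert lab.sse == lab.restart_sse.min()

    def test_k_larger_than_edges_rejected(self, rng):
        ets = EdgeTimeSeries(rng.standard_normal((3, 5)), np.empty((0, 2)))
        with pytest.raises(ValueError):
            cluster_edges(ets, k=4)


class TestCommunityProfile:
    def test_brute_force_four_region_example(self):
        # edges (1,2)(1,3)(1,4)(2,3)(2,4)(3,4) labeled A,A,B,A,B,B
        labels = EdgeCommunityLabels(np.array([1, 1, 2, 1, 2, 2]), 2, 0.0)
        prof = community_profile(labels, 4)
        np.testing.assert_allclose(prof.values[0], [2 / 3, 1 / 3])
        np.testing.assert_allclose(prof.values[3], [0.0, 1.0])

    def test_single_community_is_point_mass(self):
        labels = EdgeCommunityLabels(np.ones(6, dtype=int), 1, 0.0)
        prof = community_profile(labels, 4)
        np.testing.assert_allclose(prof.values, np.ones((4, 1)))

    def test_rows_sum_to_one(self, rng):
        n = 12
        e = n * (n - 1) // 2
        labels = EdgeCommunityLabels(rng.integers(1, 6, size=e), 5, 0.0)
        prof = community_profile(labels, n)
        np.testing.assert_allclose(prof.values.sum(axis=1), 1.0, atol=1e-12)

    def test_incomplete_labeling_rejected(self):
        with pytest.raises(ValueError):
            community_profile(EdgeCommunityLabels(np.ones(5, dtype=int), 1,
                                                  0.0), 4)


class TestNodalEntropy:
    def test_point_mass_is_zero(self):
        prof = CommunityProfile(np.eye(10)[:3], 3)
        assert np.all(nodal_entropy(prof, 10).values == 0.0)

    def test_uniform_is_one(self):
        prof = CommunityProfile(np.full((2, 10), 0.1), 2)
        np.testing.assert_allclose(nodal_entropy(prof, 10).values, 1.0,
                                   atol=1e-12)

    def test_two_thirds_one_third_closed_form(self):
        row = np.zeros(10)
        row[:2] = [2 / 3, 1 / 3]
        prof = CommunityProfile(row[None], 1)
        np.testing.assert_allclose(nodal_entropy(prof, 10).values[0],
                                   0.27643, atol=1e-5)

    def test_relabeling_leaves_entropy_unchanged(self, rng):
        n, k = 10, 6
        e = n * (n - 1) // 2
        raw = rng.integers(1, k + 1, size=e)
        perm = rng.permutation(k) + 1
        a = nodal_entropy(community_profile(
            EdgeCommunityLabels(raw, k, 0.0), n), k)
        b = nodal_entropy(community_profile(
            EdgeCommunityLabels(perm[raw - 1], k, 0.0), n), k)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_entropy_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.full(8, 0.3), size=5)
        ent = nodal_entropy(CommunityProfile(p, 5), 8)
        assert np.all((ent.values >= 0) & (ent.values <= 1))

    def test_negative_profile_rejected(self):
        with pytest.raises(ValueError):
            nodal_entropy(CommunityProfile(np.array([[1.5, -0.5]]), 1), 2)


class TestAggregateEntropy:
    def _map(self, n):
        from edgentropy import default_subnetwork_map
        return default_subnetwork_map(n)

    def test_constant_entropy_propagates(self):
        from edgentropy import NodalEntropy
        ids = [f"R{i:03d}" for i in range(14)]
        agg = aggregate_entropy(NodalEntropy(np.full(14, 0.5), 10), ids,
                                self._map(14))
        assert all(abs(v - 0.5) < 1e-12 for v in agg.values())

    def test_global_is_weighted_mean_of_subnetworks(self, rng):
        from edgentropy import NodalEntropy
        n = 21
        ids = [f"R{i:03d}" for i in range(n)]
        sm = self._map(n)
        ent = NodalEntropy(rng.random(n), 10)
        agg = aggregate_entropy(ent, ids, sm)
        weighted = sum(
            agg[lbl] * len(sm.members(lbl)) for lbl in SUBNETWORK_LABELS) / n
        assert abs(agg["global"] - weighted) < 1e-12
        assert abs(agg["global"] - ent.values.mean()) < 1e-12

    def test_empty_subnetwork_raises_with_name(self):
        from edgentropy import NodalEntropy
        sm = SubnetworkMap({"R000": "visual", "R001": "visual"})
        sm2 = SubnetworkMap(dict(sm.assignment))
        with pytest.raises(ValueError, match="somatomotor"):
            aggregate_entropy(NodalEntropy(np.array([0.1, 0.2]), 10),
                              ["R000", "R001"], sm2)


class TestResidualize:
    def test_exact_covariate_feature_becomes_orthogonal(self, rng):
        age = rng.normal(30, 5, size=40)
        feat = 2.0 * age
        resid = residualize_covariates(feat[:, None], age[:, None])
        r = resid.ravel()
        # the fit is exact: only the preserved intercept remains, and the
        # residual component is orthogonal to age (annihilator property)
        cov = (r - r.mean()) @ (age - age.mean()) / len(age)
        assert abs(cov) < 1e-10
        assert np.abs(r - r.mean()).max() < 1e-8

    def test_uncorrelated_feature_nearly_unchanged(self, rng):
        cov = rng.standard_normal((200, 2))
        feat = rng.standard_normal(200)
        resid = residualize_covariates(feat[:, None], cov)
        # OLS adjustment on independent covariates is O(1/sqrt(n))
        assert np.abs(resid.ravel() - feat).max() < 0.5

    def test_residuals_orthogonal_and_intercept_preserved(self, rng):
        cov = rng.standard_normal((50, 3))
        feats = rng.standard_normal((50, 4)) + 5.0
        resid = residualize_covariates(feats, cov)
        for j in range(3):
            assert np.abs((resid - resid.mean(0)).T @ cov[:, j]).max() < 1e-6
        np.testing.assert_allclose(resid.mean(axis=0), feats.mean(axis=0),
                                   atol=0.6)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="collinear"):
            residualize_covariates(rng.standard_normal((20, 2)),
                                   np.ones((20, 1)))


def test_group_scope_clustering_shares_centroids(small_cohort):
    """Group-level centroids give a valid, deterministic entropy table."""
    from edgentropy import build_entropy_table, default_subnetwork_map
    cfg, subjects, manifest, _ = small_cohort
    subnets = default_subnetwork_map(cfg.n_regions)
    a = build_entropy_table(subjects[:8], manifest.iloc[:8], subnets,
                            k=5, n_restarts=3, seed=1,
                            clustering_scope="group",
                            covariate_mode="off")
    b = build_entropy_table(subjects[:8], manifest.iloc[:8], subnets,
                            k=5, n_restarts=3, seed=1,
                            clustering_scope="group",
                            covariate_mode="off")
    assert a.equals(b)
    nodal = [c for c in a.columns if c.startswith("nodal_")]
    vals = a[nodal].to_numpy()
    assert np.all((vals >= 0) & (vals <= 1))


def test_pipeline_recovers_planted_mixing_entropy():
    """Nodal entropy estimated from BOLD tracks the planted mixing entropy."""
    from scipy.stats import spearmanr

    from edgentropy import SyntheticConfig, simulate_bold, subject_entropy
    cfg = SyntheticConfig(seed=11)
    ts, truth = simulate_bold(cfg, 0)
    ent, _ = subject_entropy(ts, k=10, n_restarts=25, seed=1)
    rho = spearmanr(ent.values, truth.planted_entropy).statistic
    assert rho >= 0.8
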