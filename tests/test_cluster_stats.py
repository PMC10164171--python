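"""Cluster-based permutation machinery, with brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import sparse, stats

from oscbind import cluster_stats
from oscbind.cluster_stats import (
    ClusterDomain,
    channel_adjacency,
    element_stats_paired_t,
    element_stats_wilcoxon_vs,
    form_clusters,
    grid_adjacency,
    permutation_cluster_test,
)
from oscbind.synthetic import sensor_positions


def chain_adjacency(n):
    rows = list(range(n - 1)) + list(range(1, n))
    cols = list(range(1, n)) + list(range(n - 1))
    return sparse.csr_matrix(
        (np.ones(len(rows), bool), (rows, cols)), shape=(n, n)
    )


class TestElementStats:
    def test_equal_inputs_give_zero_t(self):
        a = np.random.default_rng(0).standard_normal((6, 4))
        t, p = element_stats_paired_t(a, a)
        assert np.allclose(t, 0.0)
        assert np.allclose(p, 1.0)

    def test_constant_difference_is_maximal_statistic(self):
        a = np.zeros((5, 3))
        b = a - 2.0
        t, p = element_stats_paired_t(a, b)
        assert np.all(np.isposinf(t))
        assert np.allclose(p, 0.0)

    def test_small_fixture_matches_direct_formula(self):
        # n = 5 printed fixture
        a = np.array([[1.2], [0.7], [1.9], [1.1], [0.8]])
        b = np.array([[0.9], [0.6], [1.0], [1.3], [0.2]])
        t, p = element_stats_paired_t(a, b)
        d = (a - b).ravel()
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t[0] == pytest.approx(t_hand)
        ref = stats.ttest_rel(a.ravel(), b.ravel())
        assert t[0] == pytest.approx(ref.statistic)
        assert p[0] == pytest.approx(ref.pvalue)

    def test_wilcoxon_all_above_null_is_maximal(self):
        x = 0.5 + np.abs(np.random.default_rng(1).standard_normal((8, 3))) + 0.01
        T, p = element_stats_wilcoxon_vs(x, 0.5)
        assert np.allclose(T, 8 * 9 / 2)

    def test_wilcoxon_symmetric_values_give_p_near_one(self):
        x = 0.5 + np.array([[1.0], [-1.0], [2.0], [-2.0], [3.0], [-3.0]])
        T, p = element_stats_wilcoxon_vs(x, 0.5)
        assert T[0] == 0
        assert p[0] == 1.0

    def test_wilcoxon_statistic_matches_bruteforce_signed_ranks(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 5)) + 0.3
        T, _ = element_stats_wilcoxon_vs(x, 0.0)
        for j in range(5):
            d = x[:, j]
            ranks = stats.rankdata(np.abs(d))
            assert T[j] == pytest.approx(np.sum(np.sign(d) * ranks))

    def test_all_equal_to_null_gives_zero_statistic(self):
        x = np.full((6, 2), 0.5)
        T, p = element_stats_wilcoxon_vs(x, 0.5)
        assert np.allclose(T, 0.0)
        assert np.allclose(p, 1.0)


class TestAdjacency:
    def test_channel_adjacency_symmetric_no_self(self):
        adj = channel_adjacency(sensor_positions(20))
        assert (adj != adj.T).nnz == 0
        assert adj.diagonal().sum() == 0
        # every channel has at least one neighbor
        assert np.all(np.asarray(adj.sum(axis=1)).ravel() > 0)

    def test_grid_adjacency_six_connectivity(self):
        coords = np.array(
            [[x, y, z] for x in range(3) for y in range(3) for z in range(3)],
            dtype=float,
        )
        adj = grid_adjacency(coords, 1.0)
        center = 13  # (1,1,1)
        assert adj[center].sum() == 6
        corner = 0
        assert adj[corner].sum() == 3


class TestFormClusters:
    def test_no_supra_threshold_elements(self):
        domain = ClusterDomain(chain_adjacency(5), 5, 4)
        stat = np.zeros(20)
        p = np.ones(20)
        assert form_clusters(stat, p, 0.05, domain) == []

    def test_isolated_channel_discarded_by_neighbor_rule(self):
        domain = ClusterDomain(chain_adjacency(5), 5, 1)
        stat = np.zeros(5)
        p = np.ones(5)
        stat[2], p[2] = 3.0, 0.01  # single channel, no significant neighbor
        out = form_clusters(stat, p, 0.05, domain, min_neighbor_pairs=2)
        assert out == []
        out2 = form_clusters(stat, p, 0.05, domain, min_neighbor_pairs=0)
        assert len(out2) == 1

    def test_planted_block_recovered_with_exact_sum(self):
        n_ch, n_t = 8, 60
        domain = ClusterDomain(chain_adjacency(n_ch), n_ch, n_t)
        stat = np.zeros((n_ch, n_t))
        p = np.ones((n_ch, n_t))
        stat[2:7, 5:55] = 4.0 + np.random.default_rng(0).random((5, 50))
        p[2:7, 5:55] = 0.01
        out = form_clusters(stat.ravel(), p.ravel(), 0.05, domain, min_neighbor_pairs=2)
        assert len(out) == 1
        members, ssum, sign = out[0]
        assert len(members) == 5 * 50
        assert ssum == pytest.approx(stat[2:7, 5:55].sum())
        assert sign == 1


def brute_force_max_cluster_dist(diffs, adjacency, alpha_element, min_pairs=0):
    """Independent oracle: enumerate all sign patterns, cluster by graph
    search over supra-threshold same-sign elements, record the max
    same-sign cluster sums."""
    S, L = diffs.shape
    tcrit = stats.t.isf(alpha_element / 2, S - 1)
    adj = adjacency.toarray()
    out = []
    for signs in itertools.product([1, -1], repeat=S):
        d = diffs * np.array(signs)[:, None]
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, m / (sd / np.sqrt(S)), 0.0)
        best = {1: 0.0, -1: 0.0}
        for sign in (1, -1):
            mask = (np.abs(t) > tcrit) & (np.sign(t) == sign)
            seen = set()
            for start in np.flatnonzero(mask):
                if start in seen:
                    continue
                comp, stack = [], [start]
                seen.add(start)
                while stack:
                    u = stack.pop()
                    comp.append(u)
                    for v in np.flatnonzero(adj[u]):
                        if mask[v] and v not in seen:
                            seen.add(v)
                            stack.append(v)
                pairs = {
                    tuple(sorted((u, v)))
                    for u in comp
                    for v in comp
                    if u < v and adj[u, v]
                }
                if min_pairs and len(pairs) < min_pairs:
                    continue
                best[sign] = max(best[sign], abs(t[comp].sum()))
        out.append(best)
    return out


class TestPermutation:
    def test_exact_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        S, L = 6, 7
        diffs = rng.standard_normal((S, L)) + 0.8
        adj = chain_adjacency(L)
        domain = ClusterDomain(adj, L, 1)
        report = permutation_cluster_test(
            diffs, domain, n_permutations=100, seed=0, stat="t", exact=True
        )
        oracle = brute_force_max_cluster_dist(diffs, adj, 0.05)
        assert report.n_permutations == 2**S
        for c in report.clusters:
            ref = [b[c.sign] for b in oracle]
            p_one = np.mean([r >= abs(c.stat_sum) - 1e-12 for r in ref])
            assert c.p_cluster == pytest.approx(min(1.0, 2 * p_one))

    def test_strong_effect_reaches_permutation_floor(self):
        rng = np.random.default_rng(4)
        S, L, T = 12, 6, 10
        diffs = 5.0 + 0.3 * rng.standard_normal((S, L, T))
        domain = ClusterDomain(chain_adjacency(L), L, T)
        report = permutation_cluster_test(
            diffs, domain, n_permutations=500, seed=1, stat="t"
        )
        top = report.largest()
        assert top.sign == 1
        assert top.p_cluster == pytest.approx(2.0 / 501.0)

    def test_thousand_draw_floor_is_0_002(self):
        # the two-tailed Monte-Carlo floor at 1000 draws
        rng = np.random.default_rng(5)
        diffs = 5.0 + 0.2 * rng.standard_normal((15, 5))
        domain = ClusterDomain(chain_adjacency(5), 5, 1)
        report = permutation_cluster_test(
            diffs, domain, n_permutations=1000, seed=2, stat="t"
        )
        assert report.largest().p_cluster == pytest.approx(2.0 / 1001.0, rel=1e-9)
        assert report.largest().p_cluster == pytest.approx(0.002, abs=2e-4)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        S, L = 8, 9
        diffs = rng.standard_normal((S, L)) + 0.6
        adj = chain_adjacency(L)
        perm = rng.permutation(L)
        adj_p = adj[perm][:, perm]
        r1 = permutation_cluster_test(
            diffs, ClusterDomain(adj, L, 1), n_permutations=200, seed=3, stat="t",
            exact=True,
        )
        r2 = permutation_cluster_test(
            diffs[:, perm], ClusterDomain(sparse.csr_matrix(adj_p), L, 1),
            n_permutations=200, seed=3, stat="t", exact=True,
        )
        stats1 = sorted(round(c.stat_sum, 9) for c in r1.clusters)
        stats2 = sorted(round(c.stat_sum, 9) for c in r2.clusters)
        assert stats1 == pytest.approx(stats2)
        assert sorted(c.p_cluster for c in r1.clusters) == pytest.approx(
            sorted(c.p_cluster for c in r2.clusters)
        )

    def test_null_family_wise_error_near_alpha(self):
        # micro-scale calibration of the whole machinery
        rng = np.random.default_rng(7)
        S, L, T = 8, 10, 5
        domain = ClusterDomain(chain_adjacency(L), L, T)
        rejections = 0
        reps = 120
        for _ in range(reps):
            diffs = rng.standard_normal((S, L, T))
            report = permutation_cluster_test(
                diffs, domain, n_permutations=200, seed=int(rng.integers(2**31)),
                stat="t",
            )
            rejections += int(report.any_significant)
        assert 0.005 <= rejections / reps <= 0.12

    def test_wilcoxon_mode_detects_planted_shift(self):
        rng = np.random.default_rng(8)
        vals = 0.5 + 0.08 + 0.02 * rng.standard_normal((12, 8))
        domain = ClusterDomain(chain_adjacency(8), 8, 1)
        report = permutation_cluster_test(
            vals - 0.5, domain, n_permutations=500, seed=4, stat="wilcoxon"
        )
        assert report.any_significant
        assert report.largest().sign == 1
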