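"""MVPA variants: chance calibration, planted-pattern recovery, transfer,
re-insertion, group tests, generalization summaries."""

import numpy as np
import pytest
from scipy.stats import norm

from oscbind import cluster_stats, decode
from oscbind.containers import DecodingConfig


CFG = DecodingConfig(seed=11)


def gaussian_classes(rng, n_per_class, n_voxels, n_times, effect=0.0,
                     effect_voxels=(), effect_times=None):
    """Two-class course with an optional mean shift at chosen voxels/times."""
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_voxels, n_times))
    y = np.array(["nogo_nonoverlap"] * n_per_class + ["nogo_overlap"] * n_per_class)
    tsel = slice(None) if effect_times is None else effect_times
    for v in effect_voxels:
        X[n_per_class:, v, tsel] += effect
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestTemporalMVPA:
    def test_chance_level_on_label_free_data(self, rng):
        X, y = gaussian_classes(rng, 40, 10, 8)
        auc = decode.temporal_mvpa(X, y, CFG)
        assert 0.45 <= auc.mean() <= 0.55

    def test_planted_pattern_at_single_time(self, rng):
        X, y = gaussian_classes(
            rng, 40, 10, 8, effect=3.0, effect_voxels=range(10), effect_times=4
        )
        auc = decode.temporal_mvpa(X, y, CFG)
        assert auc[4] > 0.9
        assert abs(auc[0] - 0.5) < 0.12

    def test_gaussian_separation_matches_closed_form(self, rng):
        d = 1.0
        X, y = gaussian_classes(rng, 250, 1, 1, effect=d, effect_voxels=[0])
        auc = decode.temporal_mvpa(X, y, CFG)
        assert auc[0] == pytest.approx(norm.cdf(d / np.sqrt(2)), abs=0.05)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 4, 3))
        y = np.array(["nogo_overlap"] * 20)
        with pytest.raises(ValueError):
            decode.temporal_mvpa(X, y, CFG)

    def test_determinism(self, rng):
        X, y = gaussian_classes(rng, 20, 6, 5, effect=0.5, effect_voxels=[1])
        a = decode.temporal_mvpa(X, y, CFG)
        b = decode.temporal_mvpa(X, y, CFG)
        assert np.array_equal(a, b)

    def test_heldout_noise_feature_stays_at_chance(self, rng):
        # leakage canary: a feature carrying no label information must not
        # decode above chance on held-out folds
        X, y = gaussian_classes(rng, 50, 1, 6)
        auc = decode.temporal_mvpa(X, y, CFG)
        assert abs(auc.mean() - 0.5) < 0.06


class TestTemporalGeneralization:
    def test_stationary_pattern_generalizes_broadly(self, rng):
        X, y = gaussian_classes(
            rng, 30, 8, 6, effect=2.0, effect_voxels=range(8)
        )
        gen = decode.temporal_generalization(X, y, CFG)
        assert gen.min() > 0.85

    def test_sign_flip_anti_generalizes(self, rng):
        n_per, V, T = 40, 6, 6
        X, y = gaussian_classes(rng, n_per, V, T)
        ov = y == "nogo_overlap"
        X[ov, :, :3] += 2.0
        X[ov, :, 3:] -= 2.0
        gen = decode.temporal_generalization(X, y, CFG)
        assert gen[0, 0] > 0.85 and gen[4, 4] > 0.85
        assert gen[0, 4] < 0.3 and gen[4, 0] < 0.3

    def test_diagonal_matches_temporal_mvpa(self, rng):
        X, y = gaussian_classes(rng, 30, 5, 6, effect=1.0, effect_voxels=[0, 2])
        gen = decode.temporal_generalization(X, y, CFG)
        auc_t = decode.temporal_mvpa(X, y, CFG)
        assert np.mean(np.abs(np.diag(gen) - auc_t)) < 0.02


class TestCrossBand:
    def test_shared_pattern_transfers(self, rng):
        Xa, y = gaussian_classes(rng, 40, 8, 5)
        Xb = rng.standard_normal(Xa.shape)
        ov = y == "nogo_overlap"
        pattern = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        Xa[ov] += 1.5 * pattern[:, None]
        Xb[ov] += 1.5 * pattern[:, None]
        out = decode.cross_band_mvpa(Xa, Xb, y, CFG)
        assert out["auc_time"].mean() > 0.8

    def test_orthogonal_pattern_does_not_transfer(self, rng):
        Xa, y = gaussian_classes(rng, 40, 8, 5)
        Xb = rng.standard_normal(Xa.shape)
        ov = y == "nogo_overlap"
        Xa[ov, :4, :] += 1.5  # train pattern on voxels 0-3
        Xb[ov, 4:, :] += 1.5  # test pattern on disjoint voxels
        out = decode.cross_band_mvpa(Xa, Xb, y, CFG)
        assert abs(out["auc_time"].mean() - 0.5) < 0.1

    def test_off_diagonal_coupling_block(self, rng):
        # early training pattern predicts late test pattern
        Xa, y = gaussian_classes(rng, 40, 6, 6)
        Xb = rng.standard_normal(Xa.shape)
        ov = y == "nogo_overlap"
        pattern = np.array([1.0, -1, 1, -1, 1, -1])
        Xa[ov][:, :, :2]  # noqa: B018 - shape doc
        Xa[np.ix_(ov, range(6), range(2))] += 2.0 * pattern[None, :, None]
        Xb[np.ix_(ov, range(6), range(4, 6))] += 2.0 * pattern[None, :, None]
        out = decode.cross_band_mvpa(Xa, Xb, y, CFG)
        gen = out["auc_gen"]
        assert gen[:2, 4:].mean() > 0.8
        assert abs(gen[3:, :2].mean() - 0.5) < 0.15


class TestSpatialMVPA:
    def test_effect_voxels_rank_highest(self, rng):
        X, y = gaussian_classes(
            rng, 40, 12, 6, effect=2.0, effect_voxels=[3, 4]
        )
        auc = decode.spatial_mvpa(X, y, np.ones(6, bool), CFG)
        assert set(np.argsort(-auc)[:2]) == {3, 4}
        noise_auc = np.delete(auc, [3, 4])
        assert np.abs(noise_auc - 0.5).max() < 0.2

    def test_empty_mask_rejected(self, rng):
        X, y = gaussian_classes(rng, 10, 3, 4)
        with pytest.raises(ValueError):
            decode.spatial_mvpa(X, y, np.zeros(4, bool), CFG)


class TestReinsert:
    def test_excluded_positions_zeroed(self):
        included = np.r_[np.arange(0, 100), np.arange(130, 216)]
        vals = 0.5 + 0.1 * np.random.default_rng(0).random(len(included))
        full, chance = decode.reinsert_voxel_map(vals, included, 216)
        assert (full == 0).sum() == 30
        assert (chance == 0).sum() == 30
        assert np.array_equal(full[included], vals)
        assert np.all(chance[included] == 0.5)

    def test_all_included_no_zeros(self):
        vals = np.full(10, 0.6)
        full, chance = decode.reinsert_voxel_map(vals, np.arange(10), 10)
        assert not np.any(full == 0)


class TestGroupTest:
    def test_planted_region_significant(self, rng):
        vals = 0.5 + 0.01 * rng.standard_normal((10, 12))
        vals[:, 3:7] += 0.1
        adj = cluster_stats.grid_adjacency(
            np.c_[np.arange(12), np.zeros(12), np.zeros(12)].astype(float), 1.0
        )
        domain = cluster_stats.ClusterDomain(adj, 12, 1)
        mask, report = decode.group_test_vs_chance(vals, 0.5, domain, seed=0)
        assert report.any_significant
        assert mask[3:7].all()

    def test_chance_maps_mostly_clean(self, rng):
        adj = cluster_stats.grid_adjacency(
            np.c_[np.arange(10), np.zeros(10), np.zeros(10)].astype(float), 1.0
        )
        domain = cluster_stats.ClusterDomain(adj, 10, 1)
        n_sig = 0
        for k in range(25):
            vals = 0.5 + 0.05 * rng.standard_normal((9, 10))
            _, report = decode.group_test_vs_chance(vals, 0.5, domain, seed=k)
            n_sig += int(report.any_significant)
        assert n_sig <= 4

    def test_too_few_subjects_rejected(self, rng):
        domain = cluster_stats.ClusterDomain(None, 1, 4)
        with pytest.raises(ValueError):
            decode.group_test_vs_chance(
                0.5 * np.ones((3, 1, 4)), 0.5, domain
            )


class TestGeneralizationDuration:
    def test_saturated_mask_spans_window(self):
        T = 11
        times = np.linspace(0, 1.0, T)
        out = decode.generalization_duration(np.ones((T, T), bool), times)
        assert out.mean_duration_ms == pytest.approx(1100.0, rel=0.01)  # T * dt
        assert out.frac_significant == 1.0

    def test_band_around_diagonal(self):
        T = 101
        times = np.linspace(0, 1.0, T)
        mask = np.zeros((T, T), bool)
        for i in range(T):
            lo, hi = max(0, i - 10), min(T, i + 11)
            mask[i, lo:hi] = True  # +/-100 ms at 10 ms sampling
        out = decode.generalization_duration(mask, times)
        assert out.mean_duration_ms == pytest.approx(210.0, abs=25.0)

    def test_empty_mask(self):
        times = np.linspace(0, 1, 5)
        out = decode.generalization_duration(np.zeros((5, 5), bool), times)
        assert out.mean_duration_ms == 0.0
        assert out.frac_significant == 0.0
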