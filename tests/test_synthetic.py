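"""Task design, behavior, forward model and planted-effect generators."""

import numpy as np
import pytest

from oscbind import synthetic
from oscbind.containers import GroundTruth, TaskDesign


class TestTaskEvents:
    def test_full_design_counts(self):
        design = TaskDesign()
        events = synthetic.generate_task_events(design, seed=0)
        conds = np.array([e.condition for e in events])
        assert len(events) == 560
        for c in ("go_nonoverlap", "go_overlap"):
            assert (conds == c).sum() == 196
        for c in ("nogo_nonoverlap", "nogo_overlap"):
            assert (conds == c).sum() == 84
        go = np.char.startswith(conds.astype(str), "go")
        assert go.mean() == pytest.approx(0.70, abs=1e-9)

    def test_blocks_balanced_and_onsets_increasing(self):
        design = TaskDesign()
        events = synthetic.generate_task_events(design, seed=1)
        onsets = np.array([e.onset_ms for e in events])
        assert np.all(np.diff(onsets) > 0)
        itis = np.diff(onsets) - design.response_window_ms
        # ITIs only between consecutive trials of the same session layout
        assert itis.min() >= design.iti_range_ms[0] - 1e-9
        assert itis.max() <= design.iti_range_ms[1] + 1e-9
        for b in range(design.n_blocks):
            blk = [e for e in events if e.block_index == b]
            assert len(blk) == 80
            bc = np.array([e.condition for e in blk])
            assert (bc == "go_overlap").sum() == 28
            assert (bc == "nogo_overlap").sum() == 12

    def test_minimal_design(self):
        design = TaskDesign(
            n_go_per_condition=1, n_nogo_per_condition=1, n_blocks=1
        )
        events = synthetic.generate_task_events(design, seed=0)
        assert sorted(e.condition for e in events) == sorted(
            ["go_nonoverlap", "go_overlap", "nogo_nonoverlap", "nogo_overlap"]
        )

    def test_determinism(self):
        design = TaskDesign()
        a = synthetic.generate_task_events(design, seed=42)
        b = synthetic.generate_task_events(design, seed=42)
        assert a == b

    def test_indivisible_blocks_rejected(self):
        with pytest.raises(ValueError):
            TaskDesign(n_go_per_condition=10, n_nogo_per_condition=5, n_blocks=7)


class TestBehavior:
    def test_null_binding(self):
        truth = GroundTruth(behavioral_binding_fa=0.0)
        df = synthetic.simulate_behavior(TaskDesign(), truth, 400, seed=0)
        wide = df.pivot(index="subject", columns="condition", values="nogo_fa_rate")
        diff = (wide["overlap"] - wide["nonoverlap"]).mean()
        assert abs(diff) < 2.0

    def test_planted_binding_recovered(self):
        truth = GroundTruth(behavioral_binding_fa=35.0)
        df = synthetic.simulate_behavior(TaskDesign(), truth, 200, seed=0)
        wide = df.pivot(index="subject", columns="condition", values="nogo_fa_rate")
        diff = (wide["overlap"] - wide["nonoverlap"]).mean()
        assert diff == pytest.approx(35.0, abs=2.0)
        rt = df.pivot(index="subject", columns="condition", values="go_rt_ms")
        assert (rt["overlap"] - rt["nonoverlap"]).mean() > 0

    def test_single_subject_bounds(self):
        df = synthetic.simulate_behavior(TaskDesign(), GroundTruth(), 1, seed=3)
        assert len(df) == 2
        assert df["nogo_fa_rate"].between(0, 100).all()
        assert df["go_hit_rate"].between(0, 100).all()
        assert (df["go_rt_ms"] > 0).all()


class TestLeadField:
    def test_lattice_geometry(self, small_leadfield):
        lf = small_leadfield
        assert lf.n_voxels == 216
        d = np.linalg.norm(lf.grid_coords[1] - lf.grid_coords[0])
        assert d == pytest.approx(1.0)
        # neighbors along each axis exist at exactly one spacing
        from scipy.spatial.distance import pdist

        dists = pdist(lf.grid_coords[:10])
        assert np.min(dists) == pytest.approx(1.0)

    def test_full_rank_gain(self, small_leadfield):
        for v in range(0, 216, 37):
            assert np.linalg.matrix_rank(small_leadfield.gain[:, v, :]) == 3

    def test_spherical_gain_decays_with_distance(self):
        lf = synthetic.make_leadfield(30, (6, 6, 6), 1.0, model="spherical", seed=0)
        # source near the top of the grid: closest sensor sees more gain
        v = int(np.argmax(lf.grid_coords[:, 2]))
        g = np.linalg.norm(lf.gain[:, v, :], axis=1)
        d = np.linalg.norm(lf.channel_positions - lf.grid_coords[v], axis=1)
        near, far = np.argmin(d), np.argmax(d)
        assert g[near] > g[far]

    def test_center_dipole_closed_form(self):
        # dipole at the sphere centre: V = 3 q.r_hat / R^2
        from oscbind.synthetic import SENSOR_RADIUS_CM, _sphere_potential

        e = synthetic.sensor_positions(25)
        g = _sphere_potential(e, np.zeros((1, 3)), SENSOR_RADIUS_CM)
        expected = 3.0 * (e / SENSOR_RADIUS_CM) / SENSOR_RADIUS_CM**2
        assert np.allclose(g[:, 0, :], expected)

    def test_surface_mean_zero(self, rng):
        # no net monopole: potential integrates to ~0 over the sphere
        from oscbind.synthetic import SENSOR_RADIUS_CM, _sphere_potential

        e = rng.standard_normal((8000, 3))
        e = SENSOR_RADIUS_CM * e / np.linalg.norm(e, axis=1, keepdims=True)
        g = _sphere_potential(e, np.array([[1.0, -2.0, 3.0]]), SENSOR_RADIUS_CM)
        assert np.abs(g.mean(axis=0)).max() < 2e-2 * np.abs(g).max()

    def test_determinism(self):
        a = synthetic.make_leadfield(8, (3, 3, 3), 1.0, "random_full_rank", seed=5)
        b = synthetic.make_leadfield(8, (3, 3, 3), 1.0, "random_full_rank", seed=5)
        assert np.array_equal(a.gain, b.gain)

    def test_coincident_sensors_rejected(self):
        pos = synthetic.sensor_positions(8)
        pos[3] = pos[0]
        with pytest.raises(ValueError, match="coincident"):
            synthetic.make_leadfield(
                8, (3, 3, 3), 1.0, "random_full_rank", channel_positions=pos
            )

    def test_atlas_exclusions_present(self, small_leadfield):
        labels = set(small_leadfield.labels)
        assert "cerebellar" in labels
        included = small_leadfield.included_voxels()
        assert 0 < len(included) < 216


class TestSubjectEEG:
    def test_determinism_and_shape(self, small_leadfield, scaled_design):
        truth = synthetic.default_ground_truth()
        kw = dict(
            noise_sd=0.2, sfreq=128.0, epoch_window=(-0.7, 1.65), seed=9,
            n_trials_per_condition=8,
        )
        a = synthetic.simulate_subject_eeg(scaled_design, truth, small_leadfield, **kw)
        b = synthetic.simulate_subject_eeg(scaled_design, truth, small_leadfield, **kw)
        assert np.array_equal(a.data, b.data)
        assert a.data.shape == (16, 12, int(round(2.35 * 128)))
        assert sorted(np.unique(a.condition_labels)) == [
            "nogo_nonoverlap", "nogo_overlap",
        ]

    def test_null_effect_is_exchangeable(self, small_leadfield, scaled_design):
        truth = synthetic.default_ground_truth(effect_amplitude=0.0)
        ep = synthetic.simulate_subject_eeg(
            scaled_design, truth, small_leadfield, noise_sd=1.0,
            epoch_window=(-0.7, 1.65), seed=0, n_trials_per_condition=40,
        )
        ov = ep.condition_labels == "nogo_overlap"
        # raw variance carries no condition information
        v_ov = ep.data[ov].var(axis=(0, 2))
        v_non = ep.data[~ov].var(axis=(0, 2))
        assert np.allclose(v_ov, v_non, rtol=0.15)

    def test_sensor_theta_difference_positive_near_source(self, sphere_leadfield):
        from oscbind import timefreq
        from oscbind.containers import THETA_BAND

        design = TaskDesign.scaled(30)
        truth = synthetic.default_ground_truth(effect_amplitude=0.5)
        ep = synthetic.simulate_subject_eeg(
            design, truth, sphere_leadfield, noise_sd=0.1,
            epoch_window=(-0.7, 1.65), seed=4,
        )
        tfr = timefreq.morlet_tfr(ep, np.arange(4.0, 7.5), decim=4)
        course = timefreq.band_power(tfr, THETA_BAND)
        sel = course.time_window_mask(0.2, 0.9)
        ov = ep.condition_labels == "nogo_overlap"
        diff = (
            course.power[ov][:, :, sel].mean(axis=(0, 2))
            - course.power[~ov][:, :, sel].mean(axis=(0, 2))
        )
        # broad positive theta shift: most channels up, mean clearly positive
        assert diff.mean() > 0
        assert (diff > 0).mean() > 0.6

    def test_orthogonal_patterns_have_zero_inner_product(self):
        truth = synthetic.default_ground_truth(shared_pattern=False)
        ww = [
            synthetic.planted_difference_pattern(truth, 216, band)
            for band in ("theta", "alpha")
        ]
        # restricted to the discriminative blocks the patterns are disjoint
        w_t = np.zeros(216)
        w_t[list(truth.theta_effect_voxels)] = ww[0][list(truth.theta_effect_voxels)]
        w_a = np.zeros(216)
        w_a[list(truth.alpha_effect_voxels)] = ww[1][list(truth.alpha_effect_voxels)]
        assert np.dot(w_t, w_a) == 0.0

    def test_shared_pattern_blocks_identical(self):
        truth = synthetic.default_ground_truth(shared_pattern=True)
        assert truth.theta_effect_voxels == truth.alpha_effect_voxels

    def test_short_epoch_rejected(self, small_leadfield, scaled_design):
        truth = synthetic.default_ground_truth()
        with pytest.raises(ValueError, match="envelope"):
            synthetic.simulate_subject_eeg(
                scaled_design, truth, small_leadfield,
                epoch_window=(-0.1, 0.6), seed=0,
            )
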