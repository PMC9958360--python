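import numpy as np
import pytest

from imsync import SyntheticConfig, generate_dyad_trial, generate_study
from imsync.landmarks import CONDITIONS
from imsync.synchrony import corr_columns
from imsync.synthetic import (
    burst_kernel, generate_velocity_trial, homologous_response_matrix,
    study_manifest, uniform_response_matrix,
)


class TestConfigValidation:
    def test_defaults_are_study_layout(self):
        cfg = SyntheticConfig()
        assert cfg.n_dyads == 23
        assert cfg.trials_per_condition == 3
        assert cfg.duration == 120.0
        assert len(study_manifest(cfg)) == 23 * 12

    def test_infeasible_lag_rejected(self):
        with pytest.raises(ValueError, match="coupling_lag"):
            SyntheticConfig(duration=10.0, coupling_lag=15.0)

    def test_bad_response_matrix_rejected(self):
        m = np.full((10, 10), 0.2)
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(cross_part_matrix=tuple(map(tuple, m)))

    def test_response_matrix_presets(self):
        assert np.allclose(uniform_response_matrix().sum(axis=1), 1.0)
        assert np.allclose(homologous_response_matrix(), np.eye(10))


class TestBurstKernel:
    def test_fast_rise_slow_decay(self):
        t = np.linspace(0, 3, 3000)
        k = burst_kernel(t, rise=0.1, decay=0.5)
        t_peak = t[np.argmax(k)]
        assert k.max() == pytest.approx(1.0, abs=1e-3)
        # rises to peak quickly, decays slowly after
        assert t_peak < 0.3
        half_decay = t[np.argmax((t > t_peak) & (k < 0.5))] - t_peak
        assert half_decay > t_peak

    def test_positive_skew(self):
        t = np.linspace(0, 4, 4000)
        k = burst_kernel(t, 0.1, 0.5)
        w = k / k.sum()
        mean = (t * w).sum()
        sd = np.sqrt(((t - mean) ** 2 * w).sum())
        skew = (((t - mean) / sd) ** 3 * w).sum()
        assert skew > 0.5

    def test_causal(self):
        assert burst_kernel(np.array([-0.5, -0.01]), 0.1, 0.5).tolist() == [0, 0]


class TestVelocityTrials:
    def test_nonnegative_and_shaped(self, rng):
        cfg = SyntheticConfig(duration=30.0)
        va, vb, truth = generate_velocity_trial(cfg, ("Far", "Vision"), rng)
        assert va.shape == (900, 10) and vb.shape == (900, 10)
        assert va.min() >= 0 and vb.min() >= 0

    def test_fixed_seed_bit_identical(self):
        cfg = SyntheticConfig(duration=20.0)
        out1 = generate_velocity_trial(cfg, ("Near", "Vision"),
                                       np.random.default_rng(9))
        out2 = generate_velocity_trial(cfg, ("Near", "Vision"),
                                       np.random.default_rng(9))
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_uncoupled_partners_uncorrelated(self, rng):
        # condition-averaged coefficients (3 trials, the analysed quantity)
        # center on zero; single-trial r retains burst-autocorrelation noise
        cfg = SyntheticConfig(coupling_prob=0.0, coupled_conditions=(),
                              missing_frac=0.0, outlier_frac=0.0)
        mats = []
        for _ in range(3):
            va, vb, truth = generate_velocity_trial(cfg, ("Far", "Vision"), rng)
            assert len(truth.responses) == 0
            mats.append(corr_columns(va, vb))
        assert np.abs(np.mean(mats, axis=0)).mean() < 0.05

    def test_truth_structure(self, rng):
        cfg = SyntheticConfig(duration=60.0, coupling_prob=1.0)
        _va, _vb, truth = generate_velocity_trial(cfg, ("Far", "Vision"), rng)
        assert truth.coupled
        assert len(truth.responses) > 0
        for stim_p, t, sp, rp, lag in truth.responses:
            assert lag >= 0.0
            assert 0 <= t < cfg.duration
        # No-Vision trials carry no responses under the default coupling map
        _va, _vb, truth_nv = generate_velocity_trial(cfg, ("Far", "NoVision"), rng)
        assert not truth_nv.coupled and len(truth_nv.responses) == 0

    def test_near_gain_scales_amplitude(self):
        cfg = SyntheticConfig(duration=120.0, coupling_prob=0.0,
                              coupled_conditions=(), proximity_amplitude_gain=2.0)
        rng = np.random.default_rng(12)
        far, _b, _ = generate_velocity_trial(cfg, ("Far", "Vision"), rng)
        near, _b, _ = generate_velocity_trial(cfg, ("Near", "Vision"), rng)
        assert np.ptp(near, axis=0).mean() > 1.3 * np.ptp(far, axis=0).mean()


class TestLandmarkTrials:
    def test_corruption_fractions(self, rng):
        cfg = SyntheticConfig(duration=30.0, missing_frac=0.08,
                              outlier_frac=0.01)
        a, b, truth = generate_dyad_trial(cfg, ("Far", "NoVision"), rng)
        assert a.missing_mask.mean() == pytest.approx(0.08, abs=0.01)
        assert truth.corruption["a"]["outlier_mask_count"] > 0

    def test_downstream_velocity_reflects_part_scales(self, rng):
        from imsync import preprocess_trial
        cfg = SyntheticConfig(duration=60.0, missing_frac=0.0, outlier_frac=0.0)
        a, _b, _ = generate_dyad_trial(cfg, ("Far", "NoVision"), rng)
        panel = preprocess_trial(a)
        # hands (scaled 1.4/2.6) should out-range head and torso (0.6/0.4)
        ranges = dict(zip(panel.part_names, panel.part_range))
        assert ranges["RightHand"] > ranges["Torso"]
        assert ranges["RightHand"] > ranges["Head"]


class TestStudy:
    def test_default_study_trial_count(self):
        cfg = SyntheticConfig(n_dyads=4, duration=10.0)
        study = generate_study(cfg, level="velocity")
        assert study.n_dyads == 4
        total = sum(len(cell) for d in study.trials for cell in d)
        assert total == 4 * 12
        assert len(study.truth) == 4 * 12

    def test_landmark_level_layout(self):
        cfg = SyntheticConfig(n_dyads=2, trials_per_condition=1, duration=5.0)
        manifest, data, truths = generate_study(cfg, level="landmarks")
        assert len(manifest) == 8
        assert len(data) == 8
        a, b = next(iter(data.values()))
        assert a.n_frames == 150

    def test_study_reproducible(self):
        cfg = SyntheticConfig(n_dyads=2, duration=10.0, seed=21)
        s1 = generate_study(cfg, level="velocity")
        s2 = generate_study(cfg, level="velocity")
        np.testing.assert_array_equal(s1.trials[0][0][0][0],
                                      s2.trials[0][0][0][0])

    def test_coupling_preserves_total_movement_rate(self):
        """Response thinning keeps overall movement volume comparable across
        coupled and uncoupled conditions."""
        rng = np.random.default_rng(5)
        cfg = SyntheticConfig(duration=120.0, missing_frac=0.0, outlier_frac=0.0)
        n_vis, n_novis = [], []
        for _ in range(12):
            _va, _vb, t_v = generate_velocity_trial(cfg, ("Far", "Vision"), rng)
            _va, _vb, t_n = generate_velocity_trial(cfg, ("Far", "NoVision"), rng)
            n_vis.append(len(t_v.events[0]) + len(t_v.events[1]))
            n_novis.append(len(t_n.events[0]) + len(t_n.events[1]))
        assert np.mean(n_vis) == pytest.approx(np.mean(n_novis), rel=0.2)
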