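import numpy as np
import pytest

from imsync import (
    PreprocessConfig, compute_velocity, interpolate_missing, moving_mean,
    preprocess_trial, remove_outliers, velocity_range,
)
from imsync.landmarks import LANDMARK_NAMES, default_grouping
from imsync.preprocess import (
    flag_artifact_trials, group_and_normalize, window_frames,
)
from tests.conftest import make_series


class TestWindowFrames:
    @pytest.mark.parametrize("seconds,rate,expected", [
        (1.0, 30.0, 31),   # 30 frames -> nearest odd, ties up
        (1.0, 29.0, 29),
        (0.1, 30.0, 3),
        (0.01, 30.0, 1),
        (1.0, 5.0, 5),
    ])
    def test_nearest_odd(self, seconds, rate, expected):
        assert window_frames(seconds, rate) == expected


class TestRemoveOutliers:
    def test_constant_trajectory_no_removal(self, constant_series):
        cleaned, frac = remove_outliers(constant_series)
        assert frac == 0.0
        assert not cleaned.missing_mask.any()

    def test_single_planted_outlier_flagged(self, rng):
        n = 1000
        coords = np.zeros((n, len(LANDMARK_NAMES), 2))
        coords[:, 0, 0] = rng.standard_normal(n)
        coords[500, 0, 0] = 10.0
        series = make_series(coords)
        cleaned, _ = remove_outliers(series, 3.0)
        # brute-force 3-SD rule on the same data
        x = coords[:, 0, 0]
        expected = np.abs(x - x.mean()) > 3.0 * x.std()
        assert cleaned.missing_mask[500, 0]
        np.testing.assert_array_equal(cleaned.missing_mask[:, 0], expected)

    def test_five_planted_spikes_recovered(self, rng):
        n = 2000
        coords = np.zeros((n, len(LANDMARK_NAMES), 2))
        coords[:, 3, :] = rng.standard_normal((n, 2))
        spikes = [100, 500, 900, 1300, 1700]
        for i, s in enumerate(spikes):
            coords[s, 3, 0] = 8.0 * (-1) ** i
        cleaned, _ = remove_outliers(make_series(coords), 3.0)
        flagged = np.flatnonzero(cleaned.missing_mask[:, 3])
        assert set(spikes) <= set(flagged.tolist())
        # nothing far from the spikes should be flagged spuriously at 8 SD
        assert len(flagged) <= len(spikes) + int(0.01 * n)


class TestInterpolate:
    def test_single_gap_midpoint(self):
        coords = np.ones((3, len(LANDMARK_NAMES), 2))
        coords[0, 5] = 1.0
        coords[2, 5] = 3.0
        conf = np.full((3, len(LANDMARK_NAMES)), 0.9)
        conf[1, 5] = 0.0
        coords[1, 5] = np.nan
        out = interpolate_missing(make_series(coords, conf))
        np.testing.assert_allclose(out.coords[1, 5], [2.0, 2.0])
        assert not out.missing_mask.any()

    def test_no_gaps_identity(self, random_series):
        out = interpolate_missing(random_series)
        np.testing.assert_array_equal(out.coords, random_series.coords)

    def test_random_gaps_match_piecewise_linear_oracle(self, rng):
        n = 200
        coords = np.zeros((n, len(LANDMARK_NAMES), 2))
        y = np.cumsum(rng.standard_normal(n))
        coords[:, 0, 0] = y
        conf = np.full((n, len(LANDMARK_NAMES)), 0.9)
        missing = rng.random(n) < 0.3
        missing[[0, -1]] = False
        conf[missing, 0] = 0.0
        coords[missing, 0] = np.nan
        out = interpolate_missing(make_series(coords, conf))

        # independent piecewise-linear oracle
        def oracle(t, tv, yv):
            res = np.empty_like(t, dtype=float)
            for i, ti in enumerate(t):
                if ti <= tv[0]:
                    res[i] = yv[0]
                elif ti >= tv[-1]:
                    res[i] = yv[-1]
                else:
                    j = np.searchsorted(tv, ti)
                    if tv[j] == ti:
                        res[i] = yv[j]
                    else:
                        w = (ti - tv[j - 1]) / (tv[j] - tv[j - 1])
                        res[i] = yv[j - 1] * (1 - w) + yv[j] * w
            return res

        t = np.arange(n, dtype=float)
        valid = ~missing
        np.testing.assert_allclose(out.coords[:, 0, 0],
                                   oracle(t, t[valid], y[valid]), atol=1e-12)

    def test_edge_gaps_extend_nearest(self):
        coords = np.zeros((4, len(LANDMARK_NAMES), 2))
        coords[:, 2, 0] = [np.nan, 5.0, 7.0, np.nan]
        conf = np.full((4, len(LANDMARK_NAMES)), 0.9)
        conf[[0, 3], 2] = 0.0
        out = interpolate_missing(make_series(coords, conf))
        assert out.coords[0, 2, 0] == 5.0
        assert out.coords[3, 2, 0] == 7.0


class TestMovingMean:
    def test_constant_unchanged(self):
        x = np.full(50, 3.3)
        np.testing.assert_allclose(moving_mean(x, 1.0, 5.0), x)

    def test_shrinking_edges_hand_computed(self):
        x = np.array([1.0, 2, 3, 4, 5])
        out = moving_mean(x, 3 / 5, 5.0)  # 3-frame window
        np.testing.assert_allclose(out, [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_linear_ramp_interior_unchanged(self):
        x = np.arange(20.0)
        out = moving_mean(x, 1.0, 5.0)  # 5-frame window
        np.testing.assert_allclose(out[2:-2], x[2:-2])

    def test_window_longer_than_series_gives_global_mean(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="global mean"):
            out = moving_mean(x, 10.0, 1.0)
        np.testing.assert_allclose(out, 2.0)

    def test_2d_matches_columnwise(self, rng):
        x = rng.standard_normal((40, 3))
        out = moving_mean(x, 1.0, 7.0)
        for j in range(3):
            np.testing.assert_allclose(out[:, j], moving_mean(x[:, j], 1.0, 7.0))


class TestVelocity:
    def test_stationary_point_zero(self):
        coords = np.full((10, 1, 2), 25.0)
        for mode in ("radial_derivative", "frame_displacement"):
            np.testing.assert_allclose(compute_velocity(coords, mode), 0.0)

    def test_unit_motion_along_x(self):
        coords = np.zeros((10, 1, 2))
        coords[:, 0, 0] = np.arange(10.0) + 5
        v_rad = compute_velocity(coords, "radial_derivative")
        v_disp = compute_velocity(coords, "frame_displacement")
        np.testing.assert_allclose(v_rad, 1.0)
        np.testing.assert_allclose(v_disp, 1.0)

    def test_circular_motion_modes_diverge(self):
        t = np.linspace(0, 2 * np.pi, 100)
        coords = np.stack([10 * np.cos(t), 10 * np.sin(t)], axis=1)[:, None, :]
        v_rad = compute_velocity(coords, "radial_derivative")
        v_disp = compute_velocity(coords, "frame_displacement")
        assert np.all(v_rad < 1e-9)        # constant radius
        assert np.all(v_disp > 0.1)        # but real displacement


class TestGroupNormalize:
    def test_zscore_contract(self, rng):
        v = np.abs(rng.standard_normal((500, len(LANDMARK_NAMES))))
        z, _raw = group_and_normalize(v, LANDMARK_NAMES, default_grouping())
        np.testing.assert_allclose(np.nanmean(z, axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.nanstd(z, axis=0), 1.0, atol=1e-9)

    def test_identical_members_equal_member_mean(self, rng):
        v = np.abs(rng.standard_normal((200, len(LANDMARK_NAMES))))
        g = default_grouping()
        idx = g.indices(LANDMARK_NAMES)
        v[:, idx["LeftFoot"]] = v[:, [idx["LeftFoot"][0]]]  # clone members
        _z, raw = group_and_normalize(v, LANDMARK_NAMES, g)
        part_pos = list(g.parts).index  # PART_NAMES order used internally
        from imsync.landmarks import PART_NAMES
        j = PART_NAMES.index("LeftFoot")
        np.testing.assert_allclose(raw[:, j], v[:, idx["LeftFoot"][0]])

    def test_single_landmark_group_is_identity(self, rng):
        from imsync.landmarks import PART_NAMES
        v = np.abs(rng.standard_normal((200, len(LANDMARK_NAMES))))
        g = default_grouping()
        idx = g.indices(LANDMARK_NAMES)
        _z, raw = group_and_normalize(v, LANDMARK_NAMES, g)
        j = PART_NAMES.index("LeftKnee")
        np.testing.assert_allclose(raw[:, j], v[:, idx["LeftKnee"][0]])


class TestQCAndRange:
    def _panel(self, raw):
        from imsync.synthetic import velocity_panel_from_raw
        return velocity_panel_from_raw(raw, "p", "t", 30.0)

    def test_identical_trials_none_flagged(self, rng):
        raw = np.abs(rng.standard_normal((100, 10)))
        panels = [self._panel(raw.copy()) for _ in range(6)]
        report = flag_artifact_trials(panels)
        assert report["n_flagged"] == 0

    def test_injected_variance_flagged(self, rng):
        panels = [self._panel(np.abs(rng.standard_normal((100, 10))))
                  for _ in range(8)]
        bad = np.abs(rng.standard_normal((100, 10))) * 100
        panels.append(self._panel(bad))
        report = flag_artifact_trials(panels, factor=10.0)
        assert report["n_flagged"] == 1
        assert panels[-1].qc_flag

    def test_infinite_threshold_flags_none(self, rng):
        panels = [self._panel(np.abs(rng.standard_normal((100, 10)) * (i + 1)))
                  for i in range(5)]
        assert flag_artifact_trials(panels, factor=np.inf)["n_flagged"] == 0

    def test_range_values(self):
        raw = np.tile(np.array([0.1, 0.9, 0.4])[:, None], (1, 10))
        panel = self._panel(raw)
        np.testing.assert_allclose(velocity_range(panel), 0.8)
        double = self._panel(2 * raw)
        np.testing.assert_allclose(velocity_range(double), 1.6)

    def test_constant_series_zero_range(self):
        panel = self._panel(np.full((50, 10), 0.7))
        np.testing.assert_allclose(velocity_range(panel), 0.0)


class TestFullChain:
    def test_deterministic(self, random_series):
        p1 = preprocess_trial(random_series)
        p2 = preprocess_trial(random_series)
        np.testing.assert_array_equal(p1.velocity, p2.velocity)
        np.testing.assert_array_equal(p1.part_range, p2.part_range)

    def test_raw_velocity_nonnegative(self, random_series):
        panel = preprocess_trial(random_series)
        assert np.nanmin(panel.raw_velocity) >= 0
        assert np.nanmin(panel.part_range) >= 0

    def test_clean_input_provenance(self):
        from imsync.synthetic import SyntheticConfig, generate_dyad_trial
        cfg = SyntheticConfig(duration=10.0, missing_frac=0.0, outlier_frac=0.0)
        a, _b, _ = generate_dyad_trial(cfg, ("Far", "Vision"),
                                       np.random.default_rng(2))
        panel = preprocess_trial(a)
        assert panel.provenance["missing_frac"] == 0.0
        # the 3-SD rule trims a small natural tail even without planted spikes
        assert panel.provenance["outlier_frac"] < 0.02

    def test_planted_corruption_recovered(self):
        from imsync.synthetic import SyntheticConfig, generate_dyad_trial
        cfg = SyntheticConfig(duration=30.0, missing_frac=0.1, outlier_frac=0.0)
        a, _b, _ = generate_dyad_trial(cfg, ("Far", "Vision"),
                                       np.random.default_rng(3))
        panel = preprocess_trial(a)
        assert panel.provenance["missing_frac"] == pytest.approx(0.1, abs=0.02)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(outlier_sd=-1)
        with pytest.raises(ValueError):
            PreprocessConfig(velocity_mode="teleport")
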