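"""Detrending, MAD spike detection, confound construction/regression,
mirror averaging."""

import numpy as np
import pytest

from conedrive.boldprep import (
    BoldSeries,
    build_motion_regressors,
    combine_confounds,
    detect_spikes,
    linear_detrend,
    mirror_average,
    motion_confounds,
    regress_confounds,
)


def series_from_flat(flat: np.ndarray, shape=(4, 4, 2)) -> BoldSeries:
    n_vox, n_tr = flat.shape
    assert n_vox == np.prod(shape)
    return BoldSeries(flat.reshape(shape + (n_tr,)))


class TestDetrend:
    def test_pure_line_becomes_constant(self):
        t = np.arange(100.0)
        flat = 5.0 + 0.3 * t[None, :] * np.ones((32, 1))
        out = linear_detrend(series_from_flat(flat))
        expected = 5.0 + 0.3 * t.mean()
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        s = series_from_flat(rng.standard_normal((32, 100)))
        once = linear_detrend(s)
        twice = linear_detrend(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)

    def test_sinusoid_preserved(self):
        """A sinusoid even about the series midpoint has zero projection on
        the (centered) line, so it rides through detrending unchanged; a
        general line+sinusoid matches the polyfit residual oracle."""
        t = np.arange(120.0)
        wave = np.cos(2 * np.pi * (t - t.mean()) / 24.0)
        flat = 100.0 + 2.0 * t[None, :] + 5.0 * wave[None, :] * np.ones((32, 1))
        out = linear_detrend(series_from_flat(flat)).data.reshape(32, -1)
        np.testing.assert_allclose(out[0] - out[0].mean(), 5.0 * wave, atol=1e-6)

        generic = 10.0 - 0.7 * t + 3.0 * np.sin(2 * np.pi * t / 30.0 + 0.3)
        flat2 = generic[None, :] * np.ones((32, 1))
        out2 = linear_detrend(series_from_flat(flat2)).data.reshape(32, -1)
        slope, intercept = np.polyfit(t, generic, 1)
        oracle = generic - (slope * t + intercept) + generic.mean()
        np.testing.assert_allclose(out2[0], oracle, atol=1e-9)


class TestDetectSpikes:
    def test_constructed_spike_exactly_flagged(self):
        rng = np.random.default_rng(1)
        flat = 100 + rng.standard_normal((1000, 120))
        flat[:50, 60] += 10.0  # 5% of voxels jump 10 SD at TR 60
        events = detect_spikes(series_from_flat(flat, (10, 10, 10)))
        assert list(events.flagged_trs) == [60]
        cols = events.confound_columns(120)
        assert cols.shape == (120, 1) and cols[60, 0] == 1.0 and cols.sum() == 1.0

    def test_constant_series_no_flags(self):
        flat = np.full((32, 50), 7.0)
        events = detect_spikes(series_from_flat(flat))
        assert len(events.flagged_trs) == 0

    def test_negative_spike_ignored_one_sided(self):
        rng = np.random.default_rng(2)
        flat = 100 + rng.standard_normal((1000, 120))
        flat[:100, 30] -= 10.0
        one_sided = detect_spikes(series_from_flat(flat, (10, 10, 10)))
        two_sided = detect_spikes(series_from_flat(flat, (10, 10, 10)), two_sided=True)
        assert 30 not in one_sided.flagged_trs
        assert 30 in two_sided.flagged_trs

    def test_null_specificity(self):
        """False-flag rate on iid Gaussian volumes < 1% of TRs across seeds."""
        flagged = total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            flat = rng.standard_normal((600, 80))
            events = detect_spikes(series_from_flat(flat, (10, 10, 6)))
            flagged += len(events.flagged_trs)
            total += 80
        assert flagged / total < 0.01

    def test_injected_spike_sensitivity(self):
        """At a realistic volume size, spikes of 8 voxel-MADs hitting 2% of
        voxels are caught essentially always."""
        n_vox, n_hit = 2560, 52  # 2% of a 16x16x10 volume
        caught = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            flat = rng.standard_normal((n_vox, 80))
            mads = np.median(np.abs(flat - np.median(flat, 1, keepdims=True)), 1)
            tr = int(rng.integers(0, 80))
            flat[:n_hit, tr] += 8.0 * mads[:n_hit]
            if tr in detect_spikes(series_from_flat(flat, (16, 16, 10))).flagged_trs:
                caught += 1
        assert caught >= 99


class TestMotionConfounds:
    def test_24_regressors_built(self):
        rng = np.random.default_rng(3)
        mp = rng.standard_normal((100, 6))
        X = build_motion_regressors(mp)
        assert X.shape == (100, 24)
        np.testing.assert_array_equal(X[:, :6], mp)
        np.testing.assert_array_equal(X[0, 6:12], 0.0)  # derivative first row
        np.testing.assert_allclose(X[:, 12:18], mp**2)

    def test_pca_variance_threshold(self):
        rng = np.random.default_rng(4)
        mp = rng.standard_normal((200, 6))
        conf = motion_confounds(mp)
        assert conf.variance_explained >= 0.95
        assert conf.k < 24

    def test_rank_one_motion_compresses(self):
        """Perfectly proportional motion parameters need few components."""
        t = np.linspace(0, 1, 150)
        base = np.sin(2 * np.pi * 3 * t)
        mp = np.outer(base, np.arange(1, 7) * 0.1)
        conf = motion_confounds(mp)
        assert conf.k <= 4
        assert conf.variance_explained >= 0.95

    def test_zero_motion_yields_no_columns(self):
        with pytest.warns(UserWarning):
            conf = motion_confounds(np.zeros((50, 6)))
        assert conf.k == 0

    def test_bad_schema_rejected(self):
        with pytest.raises(ValueError):
            motion_confounds(np.zeros((50, 4)))


class TestRegressConfounds:
    def test_orthogonal_confound_leaves_signal(self):
        t = np.arange(128.0)
        signal = np.sin(2 * np.pi * t / 16)
        conf = np.cos(2 * np.pi * t / 16)[:, None]  # orthogonal over full cycles
        flat = 100 + signal[None, :] * np.ones((32, 1))
        from conedrive.boldprep import ConfoundMatrix

        out = regress_confounds(series_from_flat(flat), ConfoundMatrix(conf, ("c",)))
        np.testing.assert_allclose(out.data, flat.reshape(out.data.shape), atol=1e-9)

    def test_confound_signal_removed(self):
        rng = np.random.default_rng(5)
        c = rng.standard_normal(100)
        flat = 50 + 3.0 * c[None, :] * np.ones((32, 1))
        from conedrive.boldprep import ConfoundMatrix

        out = regress_confounds(series_from_flat(flat), ConfoundMatrix(c[:, None], ("c",)))
        # the voxel mean (including the confound's mean contribution) is restored
        np.testing.assert_allclose(out.data, flat.mean(), atol=1e-9)

    def test_matches_projection_oracle(self):
        """Residuals equal the closed-form projection (I - C C^+) y."""
        rng = np.random.default_rng(6)
        C = rng.standard_normal((80, 3))
        flat = rng.standard_normal((32, 80))
        from conedrive.boldprep import ConfoundMatrix

        out = regress_confounds(series_from_flat(flat), ConfoundMatrix(C, ("a", "b", "c")))
        Cc = C - C.mean(0)
        P = np.eye(80) - Cc @ np.linalg.pinv(Cc)
        means = flat.mean(1, keepdims=True)
        expected = (flat - means) @ P.T + means
        np.testing.assert_allclose(out.data.reshape(32, 80), expected, atol=1e-9)

    def test_rank_deficient_columns_dropped_not_fatal(self):
        rng = np.random.default_rng(7)
        c = rng.standard_normal(60)
        C = np.column_stack([c, 2 * c])
        from conedrive.boldprep import ConfoundMatrix

        with pytest.warns(UserWarning):
            regress_confounds(
                series_from_flat(rng.standard_normal((32, 60))), ConfoundMatrix(C, ("a", "b"))
            )


class TestMirrorAverage:
    def test_symmetric_input_is_fixed_point(self):
        rng = np.random.default_rng(8)
        half = rng.standard_normal((5, 8, 6))
        v = np.concatenate([half, half[::-1]], axis=0)
        np.testing.assert_allclose(mirror_average(v), v, atol=1e-12)

    def test_output_exactly_symmetric_and_idempotent(self):
        rng = np.random.default_rng(9)
        v = rng.standard_normal((10, 8, 6))
        out = mirror_average(v)
        np.testing.assert_array_equal(out, np.flip(out, axis=0))
        np.testing.assert_array_equal(mirror_average(out), out)

    def test_unilateral_activation_halved(self):
        v = np.zeros((10, 8, 6))
        v[2, 4, 3] = 1.0
        out = mirror_average(v)
        assert out[2, 4, 3] == 0.5 and out[7, 4, 3] == 0.5
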