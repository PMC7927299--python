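import numpy as np
import pandas as pd
import pytest

from capdyn.preprocess import (
    Volume4D,
    bandpass,
    censor_frames,
    compute_fd,
    dct_basis,
    dct_frequencies,
    extract_global_signal,
    preprocess_volume,
    regress_nuisance,
    smooth_spatial,
)
from capdyn.synthetic import MOTION_COLUMNS


def motion_table(params):
    return pd.DataFrame(np.asarray(params, dtype=float), columns=list(MOTION_COLUMNS))


class TestComputeFd:
    def test_constant_motion_gives_zero(self):
        fd = compute_fd(motion_table(np.tile([1.0, -2.0, 0.5, 0.01, 0.0, -0.02], (10, 1))))
        assert np.allclose(fd, 0.0)

    def test_closed_form_single_step(self):
        # one step of 0.1 mm on each translation and 0.002 rad on each rotation:
        # fd = 3*0.1 + 50 * 3*0.002 = 0.6 mm
        params = np.zeros((2, 6))
        params[1] = [0.1, 0.1, 0.1, 0.002, 0.002, 0.002]
        fd = compute_fd(params)
        assert fd[0] == 0.0
        assert fd[1] == pytest.approx(0.6)

    def test_single_frame(self):
        assert compute_fd(np.zeros((1, 6))).tolist() == [0.0]

    def test_wrong_columns_rejected(self):
        with pytest.raises(ValueError):
            compute_fd(np.zeros((5, 4)))


class TestCensorFrames:
    def test_interior_spike_one_back_two_forward(self):
        info = censor_frames(np.array([0, 0, 0.8, 0, 0, 0.0]), tr=1.0, min_retained_seconds=0)
        assert sorted(np.flatnonzero(~info.keep_mask)) == [1, 2, 3, 4]
        assert sorted(np.flatnonzero(info.keep_mask)) == [0, 5]

    def test_brute_force_window_oracle(self):
        rng = np.random.default_rng(11)
        fd = rng.uniform(0, 1.0, size=60)
        info = censor_frames(fd, tr=1.0, min_retained_seconds=0)
        dropped = set()
        for t in range(60):  # enumerate the rule frame by frame
            if fd[t] > 0.7:
                dropped.update(i for i in (t - 1, t, t + 1, t + 2) if 0 <= i < 60)
        assert set(np.flatnonzero(~info.keep_mask)) == dropped

    def test_spike_at_origin_has_no_precedent(self):
        info = censor_frames(np.array([0.9, 0, 0, 0, 0.0]), tr=1.0, min_retained_seconds=0)
        assert sorted(np.flatnonzero(~info.keep_mask)) == [0, 1, 2]

    def test_all_below_threshold_keeps_all(self):
        info = censor_frames(np.full(300, 0.3), tr=1.0)
        assert info.keep_mask.all() and not info.excluded and info.n_dropped == 0

    def test_minimum_duration_flag(self):
        fd = np.zeros(100)
        fd[::4] = 0.9  # censor almost everything
        info = censor_frames(fd, tr=1.0, min_retained_seconds=240.0)
        assert info.excluded
        assert info.retained_seconds == info.keep_mask.sum() * 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        fd = rng.uniform(0, 1.0, size=80)
        first = censor_frames(fd, tr=1.0, min_retained_seconds=0)
        again = censor_frames(np.where(first.keep_mask, fd, 0.0), tr=1.0, min_retained_seconds=0)
        assert (again.keep_mask >= first.keep_mask).all()
        assert (again.keep_mask[first.keep_mask]).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            censor_frames(np.array([]), tr=1.0)


class TestDctBasis:
    def test_component_frequencies_at_study_length(self):
        # 594 frames at TR 1.057 s: the three lowest nonzero DCT frequencies
        f = dct_frequencies(594, 1.057, 3)
        assert np.round(f, 4).tolist() == [0.0008, 0.0016, 0.0024]

    def test_columns_orthonormal_and_zero_mean(self):
        b = dct_basis(120, 2.0, 5)
        assert np.allclose(b.T @ b, np.eye(5), atol=1e-10)
        # no constant (zero-frequency) component
        assert np.allclose(b.sum(axis=0), 0.0, atol=1e-9)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            dct_basis(10, 1.0, 10)


class TestRegressNuisance:
    def test_confound_column_fully_removed(self):
        rng = np.random.default_rng(0)
        conf = rng.standard_normal((100, 3))
        ts = conf[:, [1]].copy()
        res = regress_nuisance(ts, conf)
        assert np.linalg.norm(res) / np.linalg.norm(ts) < 1e-10

    def test_orthogonal_confounds_leave_demeaned_signal(self):
        t = np.arange(64)
        ts = np.cos(2 * np.pi * 8 * t / 64)[:, None] + 5.0
        conf = np.cos(2 * np.pi * 3 * t / 64)[:, None]
        res = regress_nuisance(ts, conf)
        assert np.allclose(res[:, 0], ts[:, 0] - ts[:, 0].mean(), atol=1e-10)

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(1)
        ts = rng.standard_normal((200, 7))
        conf = rng.standard_normal((200, 4))
        res = regress_nuisance(ts, conf)
        assert np.abs(res.T @ conf).max() < 1e-8

    def test_zero_variance_confound_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        ts = rng.standard_normal((50, 2))
        conf = np.column_stack([np.ones(50), rng.standard_normal(50)])
        with pytest.warns(RuntimeWarning):
            res = regress_nuisance(ts, conf)
        assert res.shape == ts.shape

    def test_overdetermined_rejected(self):
        with pytest.raises(ValueError):
            regress_nuisance(np.zeros((5, 1)), np.ones((5, 6)))


class TestBandpass:
    tr = 1.057

    def _amplitude_ratio(self, freq):
        t = np.arange(600) * self.tr
        sig = np.sin(2 * np.pi * freq * t)[:, None]
        out = bandpass(sig, tr=self.tr)
        core = slice(100, 500)  # avoid edge transients
        return np.abs(out[core, 0]).max() / np.abs(sig[core, 0]).max()

    def test_passband_preserved(self):
        assert self._amplitude_ratio(0.05) >= 0.95

    def test_stopband_attenuated(self):
        assert self._amplitude_ratio(0.30) <= 0.10

    def test_dc_removed(self):
        out = bandpass(np.full((200, 1), 3.0), tr=1.0)
        assert np.abs(out).max() < 1e-6

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((100, 1)), tr=1.0, low=0.01, high=0.6)


class TestSmoothSpatial:
    def _vol(self, data, voxel=2.5):
        return Volume4D(
            data=data,
            affine=np.diag([voxel, voxel, voxel, 1.0]),
            mask=np.ones(data.shape[:3], bool),
            tr=1.0,
        )

    def test_constant_volume_unchanged(self):
        vol = self._vol(np.full((10, 10, 10, 2), 4.0))
        out = smooth_spatial(vol, fwhm=6.0)
        assert np.allclose(out.data, 4.0, atol=1e-9)

    def test_impulse_spreads_with_expected_sigma(self):
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        out = smooth_spatial(self._vol(data), fwhm=6.0).data[..., 0]
        # second moment along an axis equals sigma^2 in voxel units;
        # sigma = 6 / 2.3548 / 2.5 = 1.019 voxels
        x = np.arange(21)
        marginal = out.sum(axis=(1, 2))
        var = ((x - 10) ** 2 * marginal).sum() / marginal.sum()
        assert np.sqrt(var) == pytest.approx(6.0 / np.sqrt(8 * np.log(2)) / 2.5, rel=0.02)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)  # mass conserved

    def test_small_fwhm_approaches_identity(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((8, 8, 8, 1))
        out = smooth_spatial(self._vol(data), fwhm=1e-3)
        assert np.allclose(out.data, data, atol=1e-6)


class TestGlobalSignal:
    def test_constant_volume(self):
        vol = Volume4D(np.full((4, 4, 4, 5), 2.5), np.eye(4), np.ones((4, 4, 4), bool), 1.0)
        assert np.allclose(extract_global_signal(vol), 2.5)

    def test_two_voxel_mean(self):
        data = np.zeros((2, 1, 1, 1))
        data[0, 0, 0, 0], data[1, 0, 0, 0] = 1.0, 3.0
        vol = Volume4D(data, np.eye(4), np.ones((2, 1, 1), bool), 1.0)
        assert extract_global_signal(vol)[0] == pytest.approx(2.0)

    def test_empty_mask_rejected(self):
        vol = Volume4D(np.zeros((2, 2, 2, 2)), np.eye(4), np.ones((2, 2, 2), bool), 1.0)
        with pytest.raises(ValueError):
            extract_global_signal(vol, np.zeros((2, 2, 2), bool))


class TestPipeline:
    def test_gsr_zeroes_global_mean(self):
        rng = np.random.default_rng(4)
        shape = (6, 6, 6)
        data = rng.standard_normal(shape + (80,)) + 100
        vol = Volume4D(data, np.diag([2.5] * 3 + [1.0]), np.ones(shape, bool), 1.0)
        motion = motion_table(np.cumsum(rng.normal(0, 0.005, (80, 6)), axis=0))
        # check the regression step directly: after GSR the global mean is ~0
        from capdyn.preprocess import build_confounds, regress_nuisance

        conf = build_confounds(vol, motion, gsr=True)
        resid = regress_nuisance(vol.timeseries(), conf)
        gs = resid.mean(axis=1)
        assert np.linalg.norm(gs) / np.sqrt(len(gs)) < 1e-8

    def test_full_pipeline_returns_censor_and_volume(self):
        rng = np.random.default_rng(6)
        shape = (6, 6, 6)
        data = rng.standard_normal(shape + (120,)).astype(np.float32) + 100
        vol = Volume4D(data, np.diag([2.5] * 3 + [1.0]), np.ones(shape, bool), 1.0)
        steps = np.column_stack(
            [rng.normal(0, 0.005, (120, 3)), rng.normal(0, 1e-4, (120, 3))]
        )
        params = np.cumsum(steps, axis=0)
        params[60, 0] += 1.5  # one censorable spike
        out, censor = preprocess_volume(vol, motion_table(params), min_retained_seconds=60)
        assert out.data.shape == vol.data.shape
        assert not censor.keep_mask[60] and not censor.keep_mask[59]
        assert censor.keep_mask.sum() == 120 - 5  # {59,60,61,62} from spike + return step at 61 adds 63
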