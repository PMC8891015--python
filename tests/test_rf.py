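import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from t4circuit import rf, stimuli, synth
from t4circuit.rf import RFRejection, UndefinedPD
from t4circuit.stimuli import make_white_noise


@pytest.fixture(scope="module")
def noise_movie():
    return make_white_noise(16, 16, 120.0, seed=21)


class TestDriftCorrect:
    def test_constant_maps_to_zero(self):
        out = rf.drift_correct(np.full(5000, -60.0), 1000.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_removes_slow_ramp_keeps_fast_wiggle(self):
        fs = 100.0
        t = np.arange(0, 400.0, 1 / fs)
        ramp = 0.05 * t
        wiggle = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz, far above 1/(60 s)
        out = rf.drift_correct(ramp + wiggle, fs)
        mid = slice(int(100 * fs), int(300 * fs))
        # Gaussian low-pass at sigma=60 s passes the ramp, not the wiggle
        assert np.sqrt(np.mean((out[mid] - wiggle[mid]) ** 2)) < 0.05

    def test_subtracting_the_smoother_reduces_noise_variance(self, rng):
        # trace much longer than the filter so the sample variance is stable
        x = rng.normal(0, 1, 20000)
        assert rf.drift_correct(x, 100.0, sigma_s=1.0).var() <= x.var()


class TestReverseCorrelate:
    def test_linear_in_vm(self, noise_movie, rng):
        v1 = rng.normal(0, 1, noise_movie.n_frames)
        v2 = rng.normal(0, 1, noise_movie.n_frames)
        k1 = rf.reverse_correlate(noise_movie, v1).kernel
        k2 = rf.reverse_correlate(noise_movie, v2).kernel
        k12 = rf.reverse_correlate(noise_movie, 2.0 * v1 + v2).kernel
        np.testing.assert_allclose(k12, 2.0 * k1 + k2, atol=1e-10)
        np.testing.assert_allclose(
            rf.reverse_correlate(noise_movie, np.zeros(noise_movie.n_frames)).kernel,
            0.0)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_planted_pixel_and_delay_recovered(self, noise_movie, sign):
        delay_frames = 7
        iy, ix = 9, 4
        src = noise_movie.frames[:, iy, ix] - 0.5
        vm = sign * np.roll(src, delay_frames)
        vm[:delay_frames] = 0.0
        kern = rf.reverse_correlate(noise_movie, vm)
        idx, zpeak = kern.extremum()
        assert (idx[1], idx[2]) == (iy, ix)
        assert kern.lags_s[idx[0]] == pytest.approx(
            delay_frames / noise_movie.frame_rate)
        assert np.sign(zpeak) == sign

    def test_short_trace_rejected(self, noise_movie):
        with pytest.raises(ValueError):
            rf.reverse_correlate(noise_movie, np.zeros(10))


class TestZscoreCenterFilter:
    def make_planted(self, peak, where=(8, 8), n=(16, 16), seed=0):
        rng = np.random.default_rng(seed)
        kern = rng.normal(0, 1.0, (40,) + n)
        kern[12, where[0], where[1]] = peak
        return rf.SpatioTemporalRF(kern, np.arange(40) / 60.0, 2.8)

    def test_strong_central_peak_accepted_and_centred(self):
        out = rf.zscore_center_filter(self.make_planted(12.0), peak_sd=4.0,
                                      edge_margin_deg=8.4)
        assert not isinstance(out, RFRejection)
        assert out.center_px == (8, 8)
        assert out.peak_sd > 4.0
        assert out.peak_lag_s == pytest.approx(12 / 60.0)

    def test_weak_peak_rejected(self):
        out = rf.zscore_center_filter(self.make_planted(2.5), peak_sd=4.0,
                                      edge_margin_deg=0.0)
        # a 2.5-sigma plant cannot clear a 4-sigma criterion by itself;
        # occasional noise bins may, so only check the typed outcome shape
        if isinstance(out, RFRejection):
            assert out.reason == "peak below criterion"
            assert out.peak_sd < 4.0

    def test_edge_peak_rejected(self):
        out = rf.zscore_center_filter(self.make_planted(12.0, where=(1, 1)),
                                      peak_sd=4.0, edge_margin_deg=8.4)
        assert isinstance(out, RFRejection)
        assert "edge" in out.reason


class TestAverageRFs:
    def centered(self, center, n=(15, 15), peak=10.0):
        kern = np.zeros((5,) + n)
        kern[2, center[0], center[1]] = peak
        kern[0, 0, 0] = 1e-3  # break flatness
        raw = rf.SpatioTemporalRF(kern, np.arange(5) / 60.0, 2.8)
        out = rf.zscore_center_filter(raw, peak_sd=2.0, edge_margin_deg=0.0)
        assert not isinstance(out, RFRejection)
        return out

    def test_identical_rfs_average_to_input(self):
        a = self.centered((7, 7))
        mean = rf.average_rfs([a, a, a], upsample=1, smooth_sd_px=0.0)
        ilag = int(np.argmin(np.abs(a.lags_s - a.peak_lag_s)))
        np.testing.assert_allclose(mean, a.z[ilag])

    def test_opposite_offsets_cancel_after_centring(self):
        a = self.centered((6, 7))
        b = self.centered((8, 7))
        mean = rf.average_rfs([a, b], upsample=1, smooth_sd_px=0.0)
        # both peaks land on the common centre after recentring
        assert np.unravel_index(np.argmax(mean), mean.shape) == (6, 7)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rf.average_rfs([])


class TestDirectionStatistics:
    def test_single_direction_pd_and_ldir(self):
        dirs = np.arange(0, 360, 45)
        mags = np.zeros(8)
        mags[2] = 3.0  # 90 degrees
        assert rf.preferred_direction(dirs, mags) == pytest.approx(90.0)
        assert rf.ldir(dirs, mags) == pytest.approx(1.0)

    def test_symmetric_responses_have_undefined_pd_and_zero_ldir(self):
        dirs = np.arange(0, 360, 45)
        with pytest.raises(UndefinedPD):
            rf.preferred_direction(dirs, np.ones(8))
        assert rf.ldir(np.array([0.0, 180.0]), np.array([2.0, 2.0])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_cosine_tuning_recovers_peak_direction(self):
        dirs = np.arange(0, 360, 45)
        mags = np.maximum(np.cos(np.deg2rad(dirs - 45.0)), 0.0)
        assert rf.preferred_direction(dirs, mags) == pytest.approx(45.0, abs=1e-9)

    def test_broadening_decreases_ldir(self):
        dirs = np.arange(0, 360, 10.0)
        for kappa, kappa2 in [(4.0, 2.0), (2.0, 1.0)]:
            narrow = np.exp(kappa * np.cos(np.deg2rad(dirs)))
            broad = np.exp(kappa2 * np.cos(np.deg2rad(dirs)))
            assert rf.ldir(dirs, broad) < rf.ldir(dirs, narrow)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=12),
           st.floats(0.1, 50.0))
    def test_ldir_bounded_and_scale_invariant(self, mags, scale):
        mags = np.asarray(mags)
        if mags.sum() <= 0:
            return
        dirs = np.linspace(0, 360, mags.size, endpoint=False)
        v = rf.ldir(dirs, mags)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert rf.ldir(dirs, scale * mags) == pytest.approx(v, rel=1e-9)


class TestTuningFromEdges:
    def test_voigt_fit_recovers_gaussian_bump_amplitude(self):
        fs = 1000.0
        t = np.arange(0, 4.0, 1 / fs)
        trace = -60.0 + 10.0 * np.exp(-0.5 * ((t - 2.0) / 0.1) ** 2)
        curve = rf.tuning_from_edges({0.0: trace, 180.0: trace}, fs,
                                     normalize=False)
        assert curve.magnitudes[0] == pytest.approx(10.0, rel=0.02)

    def test_flat_trace_has_zero_amplitude(self):
        trace = np.full(4000, -60.0)
        curve = rf.tuning_from_edges({0.0: trace, 90.0: trace}, normalize=False)
        np.testing.assert_allclose(curve.magnitudes, 0.0, atol=1e-6)

    def test_alignment_and_normalization(self):
        fs = 1000.0
        t = np.arange(0, 4.0, 1 / fs)
        episodes = {}
        for d in np.arange(0, 360, 45.0):
            amp = 2.0 + 8.0 * np.exp(-0.5 * ((d - 90.0) / 60.0) ** 2)
            episodes[d] = -60.0 + amp * np.exp(-0.5 * ((t - 2.0) / 0.1) ** 2)
        curve = rf.tuning_from_edges(episodes, fs, normalize=True)
        assert curve.normalized
        peak_dir = curve.directions_deg[np.argmax(curve.magnitudes)]
        assert min(peak_dir, 360.0 - peak_dir) <= 45.0  # peak at PD = 0 mod 360
        assert curve.magnitudes.min() == pytest.approx(0.0)
        assert curve.magnitudes.max() == pytest.approx(1.0)


class TestEndToEndRecovery:
    """The full pipeline on a synthetic population recovers the generator."""

    def test_rf_centres_recovered_within_one_pixel(self, gt):
        movie = make_white_noise(20, 20, 120.0, seed=31)
        cells = synth.synth_population(3, 3.0, [0.0], gt, movie, seed=32)
        for cell in cells:
            vm = cell["vm"].v_mv
            kern = rf.reverse_correlate(movie, vm - vm.mean(), vm_fs_hz=1000.0)
            out = rf.zscore_center_filter(kern, edge_margin_deg=0.0)
            assert not isinstance(out, RFRejection)
            iel, iaz = out.center_px
            rec = np.array([movie.azimuths[iaz], movie.elevations[iel]])
            # extremum may land on any of the three input columns
            cx, cy = cell["true_center_deg"]
            columns = np.array([[cx - 4.8, cy], [cx, cy], [cx + 4.8, cy]])
            err = np.min(np.linalg.norm(columns - rec, axis=1))
            assert err <= movie.pixel_pitch + 1e-9

    def test_edge_tuning_argmax_matches_model_prediction(self, gt):
        from t4circuit import point_model as pm
        from t4circuit.stimuli import EdgeSpec, make_edge

        # measured: simulate the circuit for 8 real edge directions
        episodes = {}
        for d in np.arange(0, 360, 45.0):
            movie = make_edge(EdgeSpec("ON", d, 30.0, pad_s=0.5))
            vm, _ = synth.synth_t4_vm(gt, movie)
            episodes[d] = vm
        measured = rf.tuning_from_edges(episodes, normalize=False, voigt=False)
        # predicted: time-shift trick on the PD-aligned inputs
        pd_movie = make_edge(EdgeSpec("ON", 0.0, 30.0, pad_s=0.5))
        v_norm = synth.presyn_v_norm(gt, pd_movie)
        dirs, resp = pm.tuning_prediction(v_norm, gt.synaptic_params,
                                          directions_deg=np.arange(0, 360, 45.0),
                                          already_normalized=True)
        assert measured.directions_deg[np.argmax(measured.magnitudes)] == \
            dirs[np.argmax(resp)]
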