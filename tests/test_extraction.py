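"""Registration, trace extraction, dF/F, deconvolution, response detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirinv.core import Movie, TrialLayout
from pirinv import extraction as ext
from pirinv.segmentation import RegionSet
from pirinv.synth import SimConfig, generate_trial_traces


class TestRegistration:
    def test_planted_integer_shifts_recovered(self, rng):
        base = rng.random((32, 32))
        shifts = [(0, 0), (1, 0), (0, 2), (-1, 1), (2, -2)]
        frames = [np.roll(np.roll(base, dr, 0), dc, 1) for dr, dc in shifts]
        movie = Movie(data=np.array(frames), frame_rate=15.0)
        _, rec = ext.register_frames(movie, n_reference_frames=1)
        # correction shift is minus the applied displacement
        assert np.allclose(rec, -np.array(shifts), atol=0.05)

    def test_identical_frames_give_zero_shifts(self, rng):
        frame = rng.random((16, 16))
        movie = Movie(data=np.tile(frame, (4, 1, 1)), frame_rate=15.0)
        _, shifts = ext.register_frames(movie)
        assert np.allclose(shifts, 0.0)

    def test_subpixel_shift_recovered_within_tenth_pixel(self, rng):
        from scipy.ndimage import fourier_shift
        base = rng.random((64, 64))
        shifted = np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(base),
                                                     (0.5, -0.5))))
        movie = Movie(data=np.stack([base, shifted]), frame_rate=15.0)
        _, shifts = ext.register_frames(movie, upsample_factor=10,
                                        n_reference_frames=1)
        assert np.allclose(shifts[1], (-0.5, 0.5), atol=0.1)


def _one_region(rr, cc, shape, weights=None):
    labels = np.zeros(shape, dtype=np.int32)
    labels[rr, cc] = 1
    rs = RegionSet(labels=labels, pixels={1: (rr, cc)})
    if weights is not None:
        rs.weights[1] = weights
    return rs


class TestTraceExtraction:
    def test_single_pixel_region_returns_pixel_series(self, rng):
        data = rng.random((20, 8, 8))
        movie = Movie(data=data, frame_rate=15.0)
        rs = _one_region(np.array([3]), np.array([4]), (8, 8))
        traces = ext.extract_traces(movie, rs)
        assert np.allclose(traces[0], data[:, 3, 4])

    def test_uniform_weights_equal_plain_mean(self, rng):
        data = rng.random((20, 8, 8))
        movie = Movie(data=data, frame_rate=15.0)
        rr, cc = np.array([1, 1, 2]), np.array([1, 2, 1])
        rs = _one_region(rr, cc, (8, 8), weights=np.full(3, 1 / 3))
        traces = ext.extract_traces(movie, rs)
        assert np.allclose(traces[0], data[:, rr, cc].mean(axis=1))

    def test_weighted_trace_tracks_kernel_at_least_as_well_as_mean(self):
        # donut-weighted average vs plain mean on a noisy planted cell
        rng = np.random.default_rng(3)
        t = np.arange(300)
        kernel = np.zeros(300)
        for onset in (40, 120, 210):
            kernel[onset:] += np.exp(-(t[: 300 - onset]) / 30.0)
        amp = np.array([1.0, 0.8, 0.5, 0.3, 0.1])
        data = np.zeros((300, 4, 4))
        rr = np.array([1, 1, 2, 2, 1])
        cc = np.array([1, 2, 1, 2, 3])
        for k in range(5):
            data[:, rr[k], cc[k]] = amp[k] * kernel + 0.3 * rng.normal(
                size=300)
        movie = Movie(data=data, frame_rate=15.0)
        rs_w = _one_region(rr, cc, (4, 4), weights=amp / amp.sum())
        rs_u = _one_region(rr, cc, (4, 4), weights=np.full(5, 0.2))
        cw = np.corrcoef(ext.extract_traces(movie, rs_w)[0], kernel)[0, 1]
        cu = np.corrcoef(ext.extract_traces(movie, rs_u)[0], kernel)[0, 1]
        assert cw >= cu

    def test_all_zero_weights_error(self, rng):
        movie = Movie(data=rng.random((5, 4, 4)), frame_rate=15.0)
        rs = _one_region(np.array([1, 2]), np.array([1, 2]), (4, 4),
                         weights=np.zeros(2))
        with pytest.raises(ValueError):
            ext.extract_traces(movie, rs)


class TestNeuropilCorrection:
    def test_r_zero_is_identity(self, rng):
        movie = Movie(data=rng.random((10, 16, 16)), frame_rate=15.0,
                      pixel_size=1.0)
        rs = _one_region(np.array([8]), np.array([8]), (16, 16))
        traces = ext.extract_traces(movie, rs)
        assert np.array_equal(ext.neuropil_correct(traces, movie, rs, r=0.0),
                              traces)

    def test_known_background_recovered_exactly(self, rng):
        # movie = cell signal on its pixel + background everywhere else
        background = rng.random(50)
        data = np.tile(background[:, None, None], (1, 21, 21))
        cell = background + np.sin(np.arange(50) / 3.0) + 2.0
        data[:, 10, 10] = cell + 0.5 * background     # contaminated pixel
        movie = Movie(data=data, frame_rate=15.0, pixel_size=1.0)
        rs = _one_region(np.array([10]), np.array([10]), (21, 21))
        traces = ext.extract_traces(movie, rs)
        corrected = ext.neuropil_correct(traces, movie, rs, radius_um=5.0,
                                         r=0.5)
        assert np.allclose(corrected[0], cell)

    def test_empty_neuropil_disk_warns_and_skips(self, rng):
        data = rng.random((10, 4, 4))
        movie = Movie(data=data, frame_rate=15.0, pixel_size=1.0)
        rr, cc = np.mgrid[0:4, 0:4]
        rs = _one_region(rr.ravel(), cc.ravel(), (4, 4))
        traces = ext.extract_traces(movie, rs)
        with pytest.warns(UserWarning):
            out = ext.neuropil_correct(traces, movie, rs, radius_um=2.0)
        assert np.array_equal(out, traces)


class TestDff:
    def test_constant_trace_gives_zero_dff(self):
        dff = ext.compute_dff(np.full(450, 5.0), 15.0)
        assert np.allclose(dff, 0.0)

    def test_fractional_step_recovered(self):
        f = np.full(450, 2.0)
        f[150:] *= 1.3
        dff = ext.compute_dff(f, 15.0)
        assert np.allclose(dff[150:], 0.3)

    def test_f0_is_median_of_seconds_4_to_8(self, rng):
        f = 10.0 + 0.01 * np.arange(450) + rng.normal(size=450)
        dff = ext.compute_dff(f, 15.0)
        f0 = np.median(f[60:120])                 # independent median oracle
        assert np.allclose(dff, (f - f0) / f0)

    def test_nonpositive_f0_marks_trial_invalid(self):
        f = np.zeros(450)
        dff = ext.compute_dff(f, 15.0)
        assert np.isnan(dff).all()


class TestDeconvolution:
    def test_exponential_decay_maps_to_zero(self):
        t = np.arange(450) / 15.0
        f = np.exp(-t / 2.0)
        r = ext.deconvolve(f, tau=2.0, frame_rate=15.0, lowpass=False)
        assert np.abs(r[1:]).max() < 0.01

    def test_constant_maps_to_c_over_tau(self):
        r = ext.deconvolve(np.full(100, 3.0), tau=2.0, frame_rate=15.0,
                           lowpass=False)
        assert np.allclose(r, 1.5)

    def test_impulse_train_recovered(self):
        f = ext.convolve_events([120, 250], [1.0, 0.6], 450, 2.0, 15.0)
        r = ext.deconvolve(f, tau=2.0, frame_rate=15.0, lowpass=False)
        peaks = np.flatnonzero(r > 1.0)
        assert list(peaks) == [120, 250]
        assert r.sum() / 15.0 == pytest.approx(1.6, rel=0.05)

    def test_left_inverse_error_shrinks_with_frame_rate(self):
        errs = {}
        for rate in (15.0, 60.0):
            n = int(30 * rate)
            f = ext.convolve_events([int(8 * rate)], [1.0], n, 2.0, rate)
            r = ext.deconvolve(f, tau=2.0, frame_rate=rate, lowpass=False)
            planted = np.zeros(n)
            planted[int(8 * rate)] = rate          # unit area impulse
            errs[rate] = np.abs(r - planted).sum() / rate
        assert errs[60.0] < errs[15.0]
        assert errs[60.0] < 0.05

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            ext.deconvolve(np.zeros(10), tau=0.0, frame_rate=15.0)

    def test_frame_rate_must_exceed_twice_cutoff(self):
        with pytest.raises(ValueError):
            ext.deconvolve(np.zeros(10), tau=2.0, frame_rate=4.0,
                           cutoff_hz=2.5)


class TestDetection:
    def test_flat_trace_is_neither(self):
        assert ext.detect_responses(np.zeros(450), 15.0) == "none"

    @pytest.mark.parametrize("n_frames,expected", [(25, "act"),
                                                   (15, "none")])
    def test_run_length_rule_at_defaults(self, rng, n_frames, expected):
        dff = 0.02 * rng.normal(size=450)
        sd = dff[:120].std()
        dff[120:120 + n_frames] = 3.0 * sd + 1.0
        assert ext.detect_responses(dff, 15.0) == expected

    def test_suppression_uses_mirrored_threshold(self, rng):
        dff = 0.02 * rng.normal(size=450)
        dff[125:155] = -1.0
        assert ext.detect_responses(dff, 15.0) == "sup"

    def test_window_shorter_than_run_errors(self):
        params = ext.DetectionParams(run_activation=21, response_window=1.0)
        with pytest.raises(ValueError):
            ext.detect_responses(np.zeros(450), 15.0, params)

    @given(offset=st.floats(min_value=0.5, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_flags_invariant_to_constant_fluorescence_offset(self, offset):
        # dF/F normalization removes any constant added to F
        rng = np.random.default_rng(7)
        f = 5.0 + 0.05 * rng.normal(size=450)
        f[120:160] += 2.0
        base = ext.detect_responses(ext.compute_dff(f, 15.0), 15.0)
        shifted = ext.detect_responses(ext.compute_dff(f + offset, 15.0),
                                       15.0)
        assert base == "act"
        # the flag survives any positive offset (threshold rescales with F0)
        assert shifted == base

    def test_noise_free_flags_match_planted_events(self):
        cfg = SimConfig(n_cells=60, trace_noise_sd=0.0, trial_noise_sd=0.0,
                        p_respond=1.0, seed=9)
        tensor, gt = generate_trial_traces(cfg)
        flags = ext.detect_responses_tensor(tensor)
        planted_act = (~np.isnan(gt.event_times)) & \
            (gt.true_response_means[:, :, None] > 0)
        planted_sup = (~np.isnan(gt.event_times)) & \
            (gt.true_response_means[:, :, None] < 0)
        assert ((flags == "act") == planted_act).all()
        assert ((flags == "sup") == planted_sup).all()

    def test_noise_free_activated_fraction_matches_config(self):
        cfg = SimConfig(n_cells=100, trace_noise_sd=0.0, trial_noise_sd=0.0,
                        p_respond=1.0, fraction_activated=0.2,
                        fraction_suppressed=0.1, seed=21)
        tensor, gt = generate_trial_traces(cfg)
        flags = ext.detect_responses_tensor(tensor)
        detected = (flags == "act").any(axis=(1, 2)).mean()
        assert detected == pytest.approx(0.2)


class TestRocCalibration:
    def _trials(self, rng, n_pos=60, n_blank=60, amp=2.0):
        trials, labels = [], []
        for _ in range(n_pos):
            dff = 0.05 * rng.normal(size=450)
            dff[120:190] += amp
            trials.append(dff)
            labels.append(True)
        for _ in range(n_blank):
            trials.append(0.05 * rng.normal(size=450))
            labels.append(False)
        return np.array(trials), np.array(labels)

    def test_separable_data_yields_perfect_point(self, rng):
        trials, labels = self._trials(rng)
        best = ext.calibrate_threshold_roc(trials, labels, 15.0)
        assert best["accuracy"] == 1.0
        assert best["tpr"] == 1.0

    def test_single_candidate_returned_with_empirical_rates(self, rng):
        trials, labels = self._trials(rng, n_pos=20, n_blank=20)
        best = ext.calibrate_threshold_roc(trials, labels, 15.0,
                                           k_grid=[2.0], run_grid=[21])
        assert (best["k"], best["run"]) == (2.0, 21)

    def test_randomized_labels_give_near_zero_youden(self, rng):
        trials, labels = self._trials(rng, n_pos=250, n_blank=250)
        rng.shuffle(labels)
        best = ext.calibrate_threshold_roc(trials, labels, 15.0)
        assert abs(best["youden_j"]) < 0.1

    def test_no_blanks_errors(self, rng):
        trials, _ = self._trials(rng, n_pos=4, n_blank=4)
        with pytest.raises(ValueError):
            ext.calibrate_threshold_roc(trials, np.ones(8, dtype=bool), 15.0)
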