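"""Signal-to-matrix chain: filtering, beat detection, resampling, windows."""

import numpy as np
import pandas as pd
import pytest

from netinfodyn import preprocess as pp
from netinfodyn import synth
from netinfodyn.preprocess import (
    NetworkSeries,
    NoBeatsError,
    PulseDetectionError,
    beat_rr,
    check_stationarity,
    compute_pat,
    detect_r_peaks,
    eeg_band_power,
    filter_ecg,
    resample_1hz,
    resp_at_beats,
    select_window,
    standardize,
)

FS_ECG = 250.0


class TestFilterEcg:
    def test_removes_dc(self):
        out = filter_ecg(np.full(5000, 5.0), FS_ECG)
        assert np.max(np.abs(out[500:-500])) < 1e-3

    @pytest.mark.parametrize("freq,check", [
        (50.0, lambda g: g < 0.1),          # out of band: > 10x attenuation
        (10.0, lambda g: g > 10 ** (-1 / 20)),  # in band: within 1 dB
    ])
    def test_band_edges(self, freq, check):
        t = np.arange(int(20 * FS_ECG)) / FS_ECG
        x = np.sin(2 * np.pi * freq * t)
        y = filter_ecg(x, FS_ECG)
        gain = np.max(np.abs(y[2000:-2000]))
        assert check(gain)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            filter_ecg(np.zeros(100), 30.0)

    def test_preserves_length(self):
        x = np.random.default_rng(0).standard_normal(4000)
        assert len(filter_ecg(x, FS_ECG)) == len(x)


class TestDetectRPeaks:
    def test_default_snr_sensitivity_and_precision(
        self, default_recording, default_peaks, match_events
    ):
        truth = default_recording.truth["beat_times"]
        sens, prec = match_events(default_peaks, truth, tol=0.004)
        assert sens >= 0.99 and prec >= 0.99

    def test_flat_signal_is_explicit_failure(self):
        with pytest.raises(NoBeatsError):
            detect_r_peaks(np.zeros(int(20 * FS_ECG)), FS_ECG)

    def test_degraded_snr_still_sensitive(self, match_events):
        # at 4x the default noise the question is whether beats are found,
        # so matching uses a beat-level (20 ms) window, not sample timing
        rec = synth.synth_recording(duration=400.0, state="REST", seed=7,
                                    ecg_noise_sd=0.2)
        peaks = detect_r_peaks(filter_ecg(rec.ecg, FS_ECG), FS_ECG)
        sens, _ = match_events(peaks, rec.truth["beat_times"], tol=0.02)
        assert sens >= 0.95

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            detect_r_peaks(np.zeros(100), FS_ECG)


class TestBeatRR:
    def test_simple_differences(self):
        b = beat_rr(np.array([0.0, 0.8, 1.6]))
        assert np.allclose(b.rr, [0.8, 0.8])
        assert np.allclose(b.times, [0.8, 1.6])

    def test_false_peak_merged_back(self):
        times = list(np.arange(0.0, 24.0, 0.8))
        times.insert(10, times[9] + 0.3)  # splits one 0.8 into 0.3 + 0.5
        b = beat_rr(np.array(sorted(times)))
        assert np.allclose(b.rr, 0.8, atol=1e-9)

    def test_recovers_generator_truth(self, default_recording, default_peaks):
        b = beat_rr(default_peaks)
        truth_t = default_recording.truth["beat_times"]
        truth_rr = default_recording.truth["rr"]
        # each interval closes at truth_t + truth_rr; match detected beats
        # to the nearest closing time
        closing = truth_t + truth_rr
        idx = np.abs(closing[:, None] - b.times[None, :]).argmin(axis=0)
        err = np.abs(b.rr - truth_rr[idx])
        assert np.max(err) <= 2.0 / FS_ECG

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            beat_rr(np.array([1.0]))


class TestRespAtBeats:
    def test_sine_sampled_at_quarter_period(self):
        fs = 25.0
        t = np.arange(int(10 * fs)) / fs
        resp = np.sin(2 * np.pi * 0.25 * t)
        v = resp_at_beats(resp, fs, np.array([1.0]))
        assert v[0] == pytest.approx(1.0, abs=0.01)

    def test_constant_signal(self):
        v = resp_at_beats(np.full(250, 3.2), 25.0, np.array([2.0, 5.0]))
        assert np.all(v == 3.2)

    def test_peak_outside_span_rejected(self):
        with pytest.raises(ValueError):
            resp_at_beats(np.zeros(25), 25.0, np.array([5.0]))

    def test_tracks_respiration_phase(self, default_recording, default_peaks):
        rec = default_recording
        v = resp_at_beats(rec.resp, rec.rates["resp"], default_peaks)
        truth = np.sin(2 * np.pi * rec.truth["resp_rate_hz"] * default_peaks)
        assert np.corrcoef(v, truth)[0, 1] > 0.99


class TestComputePat:
    def test_constant_pat_recovered(self):
        beats = np.arange(1.0, 60.0, 0.8)
        bvp = synth.render_bvp(beats, np.full(len(beats), 0.25), 61.0,
                               noise_sd=0.001, seed=0)
        pat = compute_pat(beats, bvp, 64.0)
        assert np.max(np.abs(pat - 0.25)) <= 1.0 / 64

    def test_flat_bvp_hard_failure(self):
        beats = np.arange(1.0, 60.0, 0.8)
        with pytest.raises(PulseDetectionError):
            compute_pat(beats, np.zeros(int(61 * 64)), 64.0)

    def test_ramp_recovered_within_two_samples(self):
        beats = np.arange(1.0, 60.0, 0.8)
        truth = np.linspace(0.20, 0.30, len(beats))
        bvp = synth.render_bvp(beats, truth, 61.0, noise_sd=0.001, seed=1)
        pat = compute_pat(beats, bvp, 64.0)
        assert np.max(np.abs(pat - truth)) <= 2.0 / 64

    def test_recording_truth_recovered(self, default_recording, default_peaks):
        pat = compute_pat(default_peaks, default_recording.bvp, 64.0)
        truth = default_recording.truth["pat"]
        assert len(pat) == len(truth)
        assert np.max(np.abs(pat - truth)) <= 2.0 / 64


class TestResample1Hz:
    def test_constant_series(self):
        t = np.arange(0.3, 20.0, 0.8)
        grid, v = resample_1hz(t, np.full(len(t), 0.8))
        assert np.allclose(v, 0.8)
        assert np.all(grid == np.arange(1.0, 20.0))

    def test_linear_ramp_exact(self):
        t = np.arange(0.3, 20.0, 0.8)
        grid, v = resample_1hz(t, 2.0 * t + 1.0)
        assert np.allclose(v, 2.0 * grid + 1.0, atol=1e-6)

    def test_sinusoid_rmse_below_two_percent(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.7, 0.9, 400))
        vals = np.sin(2 * np.pi * t / 10.0)
        grid, v = resample_1hz(t, vals)
        rmse = np.sqrt(np.mean((v - np.sin(2 * np.pi * grid / 10.0)) ** 2))
        assert rmse < 0.02

    def test_grid_outside_span_rejected(self):
        t = np.arange(0.0, 5.0, 0.8)
        with pytest.raises(ValueError, match="span"):
            resample_1hz(t, np.ones(len(t)), grid=np.array([10.0]))


class TestEegBandPower:
    def test_alpha_tone_concentrates_in_alpha(self):
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        eeg = np.sin(2 * np.pi * 10.0 * t)
        _, bands = eeg_band_power(eeg, fs)
        total = sum(bands[b] for b in bands)
        assert np.all(bands["alpha"] / total >= 0.95)

    def test_300s_record_gives_299_epochs(self):
        fs = 256.0
        eeg = np.random.default_rng(1).standard_normal(int(300 * fs))
        t, bands = eeg_band_power(eeg, fs)
        assert len(t) == 299
        assert all(len(bands[b]) == 299 for b in bands)
        assert t[0] == 1.0 and t[-1] == 299.0

    def test_amplitude_scaling_is_quadratic(self):
        fs = 256.0
        eeg = np.random.default_rng(2).standard_normal(int(20 * fs))
        _, b1 = eeg_band_power(eeg, fs)
        _, b3 = eeg_band_power(3.0 * eeg, fs)
        for band in b1:
            assert np.allclose(b3[band], 9.0 * b1[band], rtol=1e-10)

    def test_envelope_step_quadruples_band_power(self):
        env = np.concatenate([np.ones(200), 2.0 * np.ones(201)])
        rec = synth.synth_recording(
            duration=400.0, state="REST", seed=3,
            band_envelopes={"delta": env, "theta": np.ones(401),
                            "alpha": np.ones(401), "beta": np.ones(401)})
        _, bands = eeg_band_power(rec.eeg, 256.0)
        first = np.mean(bands["delta"][10:180])
        second = np.mean(bands["delta"][220:390])
        assert second / first == pytest.approx(4.0, rel=0.25)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            eeg_band_power(np.zeros(100), 256.0)


class TestSelectWindow:
    @staticmethod
    def _df(n, t0=0.0):
        t = np.arange(n) + t0
        rng = np.random.default_rng(0)
        cols = {lab: rng.standard_normal(n) for lab in synth.NODE_LABELS}
        return pd.DataFrame({"t": t, **cols})

    def test_rest_window_starts_at_180(self):
        net = select_window(self._df(480), "REST")
        assert net.N == 300
        assert net.t[0] == 180.0 and net.t[-1] == 479.0

    def test_task_window_starts_at_offset(self):
        net = select_window(self._df(360), "MA", offset_task=60.0)
        assert net.t[0] == 60.0 and net.t[-1] == 359.0

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            select_window(self._df(200), "REST")


class TestStationarity:
    def test_iid_gaussian_passes_at_calibrated_rate(self):
        rng = np.random.default_rng(0)
        passes = sum(
            check_stationarity(rng.standard_normal(300), seed=k).passed
            for k in range(400)
        )
        assert passes / 400 >= 0.90

    def test_mean_step_fails(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        x[150:] += 3.0
        assert not check_stationarity(x, seed=0).passed

    def test_linear_trend_fails(self):
        rng = np.random.default_rng(2)
        fails = sum(
            not check_stationarity(
                rng.standard_normal(300) + np.linspace(-2, 2, 300), seed=k
            ).passed
            for k in range(20)
        )
        assert fails >= 16

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            check_stationarity(np.ones(300))


class TestStandardize:
    @staticmethod
    def _net(X):
        return NetworkSeries(X=X, labels=[f"X{i}" for i in range(len(X))],
                             state="REST")

    def test_row_moments(self):
        out = standardize(self._net(np.array([[1.0, 2.0, 3.0]])))
        assert abs(out.X.mean()) < 1e-12
        assert out.X.var() == pytest.approx(1.0, abs=1e-12)
        assert out.standardized

    def test_idempotent(self):
        x = np.random.default_rng(3).standard_normal((2, 100))
        once = standardize(self._net(x))
        twice = standardize(once)
        assert np.max(np.abs(once.X - twice.X)) < 1e-12

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(self._net(np.vstack([np.ones(10), np.arange(10.0)])))


class TestEndToEnd:
    def test_network_matrix_shape_and_finite(self, default_network):
        assert default_network.X.shape == (7, 300)
        assert np.all(np.isfinite(default_network.X))
        assert default_network.standardized
        assert default_network.labels == synth.NODE_LABELS

    def test_peripheral_rows_track_truth(self, default_recording, default_network):
        from scipy.interpolate import CubicSpline

        rec, net = default_recording, default_network
        bt, rr = rec.truth["beat_times"], rec.truth["rr"]
        c_rr = np.corrcoef(net.X[0], CubicSpline(bt + rr, rr)(net.t))[0, 1]
        c_resp = np.corrcoef(
            net.X[1], np.sin(2 * np.pi * rec.truth["resp_rate_hz"] * net.t))[0, 1]
        c_pat = np.corrcoef(net.X[2], CubicSpline(bt, rec.truth["pat"])(net.t))[0, 1]
        assert c_rr > 0.95 and c_resp > 0.95 and c_pat > 0.95

    def test_rr_modulation_spectral_peak(self):
        """A 10 s respiratory period must surface at 0.1 Hz in the RR row."""
        from scipy import signal as sps

        rec = synth.synth_recording(duration=490.0, state="REST", seed=9,
                                    resp_rate_hz=0.1)
        net = pp.preprocess_recording(rec)
        f, pxx = sps.periodogram(net.X[0], fs=1.0)
        peak = f[np.argmax(pxx[1:]) + 1]
        assert peak == pytest.approx(0.1, abs=0.01)
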