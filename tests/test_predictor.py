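"""Predictor unit tests: spectral criteria, phase extraction, sine fitting,
extrapolation, and the streaming state-machine contracts."""

import numpy as np
import pytest
from scipy.signal import lfilter

from sophase.core import Recording
from sophase.predictor import (
    BufferState,
    DegenerateSignalError,
    NotReadyError,
    PhasePredictor,
    PredictorConfig,
    SineFit,
    _design_bandpass,
    compensate_lead,
    estimate_center_frequency,
    fit_reference_sine,
    instantaneous_phase,
    predict_target_time,
    run_stream,
    so_power_ratio,
)

CFG = PredictorConfig()
FS = CFG.fs
N = CFG.buffer_len
T = np.arange(N) / FS


def _filled(signal):
    st = BufferState(N)
    for x in signal:
        st.append(float(x))
    return st


class TestSpectralCriteria:
    @pytest.mark.parametrize(
        "freq, expected_bin",
        [(1.0, 10 * FS / N), (0.8, 8 * FS / N)],  # 1.0240 Hz, 0.8192 Hz
    )
    def test_center_frequency_snaps_to_fft_bin(self, freq, expected_bin):
        st = _filled(np.sin(2 * np.pi * freq * T))
        assert estimate_center_frequency(st, CFG) == pytest.approx(expected_bin)

    def test_center_frequency_noisy_tone_vs_dense_periodogram(self):
        """The buffer-resolution estimate lands on the bin nearest the dense
        periodogram argmax of the same data."""
        rng = np.random.default_rng(42)
        sig = np.sin(2 * np.pi * 0.7 * T) + 0.3 * rng.standard_normal(N)
        st = _filled(sig)
        # oracle: densely zero-padded spectrum over the search band
        spec = np.abs(np.fft.rfft(sig, n=1 << 18))
        freqs = np.fft.rfftfreq(1 << 18, 1 / FS)
        band = (freqs >= 0.6) & (freqs <= 1.2)
        f_dense = freqs[band][np.argmax(spec[band])]
        bins = np.fft.rfftfreq(N, 1 / FS)
        assert estimate_center_frequency(st, CFG) == pytest.approx(
            bins[np.argmin(np.abs(bins - f_dense))]
        )
        assert estimate_center_frequency(st, CFG) == pytest.approx(7 * FS / N)

    def test_not_ready_before_full(self):
        st = BufferState(N)
        st.append(1.0)
        with pytest.raises(NotReadyError):
            estimate_center_frequency(st, CFG)

    def test_power_ratio_pure_sine(self):
        # a bin-aligned tone keeps essentially all its power in the band
        st = _filled(np.sin(2 * np.pi * (10 * FS / N) * T))
        assert so_power_ratio(st, CFG) > 0.99
        # off-bin tones lose a little to spectral leakage but stay dominant
        st = _filled(np.sin(2 * np.pi * 1.0 * T))
        assert so_power_ratio(st, CFG) > 0.9

    def test_power_ratio_white_noise_matches_flat_spectrum_fraction(self):
        rng = np.random.default_rng(0)
        ratios = [
            so_power_ratio(_filled(rng.standard_normal(N)), CFG) for _ in range(5)
        ]
        expected = (1.2 - 0.6) / (FS / 2)  # ~0.0023 for a flat spectrum
        assert np.mean(ratios) == pytest.approx(expected, rel=0.5)
        assert max(ratios) < 0.05

    def test_power_ratio_equal_power_mixture(self):
        rng = np.random.default_rng(1)
        sine = np.sin(2 * np.pi * 1.0 * T)
        noise = rng.standard_normal(N)
        noise *= np.sqrt(np.mean(sine**2) / np.mean(noise**2))
        st = _filled(sine + noise)
        assert so_power_ratio(st, CFG) == pytest.approx(0.5, abs=0.05)

    def test_power_ratio_zero_buffer_undefined(self):
        st = _filled(np.zeros(N))
        with pytest.raises(DegenerateSignalError):
            so_power_ratio(st, CFG)


class TestInstantaneousPhase:
    F0 = 10 * FS / N  # 1.0240 Hz, an exact FFT bin

    def test_tracks_known_sinusoid_in_fit_window(self):
        sig = np.sin(2 * np.pi * self.F0 * T)
        phase = instantaneous_phase(sig, self.F0, CFG)
        i0, i1 = int(N * 0.80), int(N * 0.95)
        true = (360.0 * self.F0 * T[i0:i1]) % 360.0
        err = ((phase[i0:i1] - true + 180.0) % 360.0) - 180.0
        assert np.max(np.abs(err)) < 10.0

    def test_band_passed_peaks_sit_at_90_degrees(self):
        sig = np.sin(2 * np.pi * self.F0 * T)
        b, a = _design_bandpass(self.F0, CFG)
        filtered = lfilter(b, a, sig)
        phase = instantaneous_phase(sig, self.F0, CFG)
        # stay clear of the buffer end, where Hilbert edge distortion grows
        i0, i1 = int(N * 0.80), int(N * 0.92)
        x = filtered
        peaks = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1
        peaks = peaks[(peaks >= i0) & (peaks < i1)]
        assert peaks.size > 0
        # +90 deg convention minus the filter's own phase lag at F0
        from sophase.predictor import _filter_phase_deg

        corr = _filter_phase_deg(b, a, self.F0, FS)
        err = ((phase[peaks] + corr - 90.0 + 180.0) % 360.0) - 180.0
        assert np.max(np.abs(err)) < 2.0

    def test_dc_buffer_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            instantaneous_phase(np.full(N, 3.7), 1.0, CFG)

    def test_f0_outside_band_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.sin(2 * np.pi * T), 2.5, CFG)


class TestSineFit:
    F0 = 1.0

    def test_self_fit_noiseless(self):
        trace = (360.0 * self.F0 * T + 33.0) % 360.0
        fit = fit_reference_sine(trace, self.F0, CFG)
        assert fit.fit_error < 1e-4
        true_now = (360.0 * self.F0 * T[-1] + 33.0) % 360.0
        err = ((fit.fitted_phase_deg - true_now + 180.0) % 360.0) - 180.0
        assert abs(err) < 2.0

    def test_heavy_phase_noise_rejected(self):
        rng = np.random.default_rng(3)
        trace = (360.0 * self.F0 * T + rng.uniform(-90.0, 90.0, N)) % 360.0
        fit = fit_reference_sine(trace, self.F0, CFG)
        # independent oracle: directly computed MSE of the best grid sine
        i0, i1 = int(N * 0.80), int(N * 0.95)
        y = np.sin(np.radians(trace[i0:i1]))
        w = 2 * np.pi * self.F0
        best = min(
            np.mean((y - np.sin(w * T[i0:i1] + phi)) ** 2)
            for phi in np.radians(np.arange(0.0, 360.0, 0.5))
        )
        assert fit.fit_error > 0.1
        assert fit.fit_error == pytest.approx(best, abs=1e-3)

    @pytest.mark.parametrize("phi0", [0.0, 120.0, 240.0])
    def test_phase_offsets_recovered(self, phi0):
        trace = (360.0 * self.F0 * T + phi0) % 360.0
        fit = fit_reference_sine(trace, self.F0, CFG)
        expected = (360.0 * self.F0 * T[-1] + phi0) % 360.0
        # brute-force grid oracle at 0.1 deg resolution
        i0, i1 = int(N * 0.80), int(N * 0.95)
        y = np.sin(np.radians(trace[i0:i1]))
        w = 2 * np.pi * self.F0
        grid = np.arange(0.0, 360.0, 0.1)
        errs = [
            np.mean((y - np.sin(w * T[i0:i1] + np.radians(g))) ** 2) for g in grid
        ]
        phi_grid = grid[int(np.argmin(errs))]
        oracle = (360.0 * self.F0 * T[-1] + phi_grid) % 360.0
        for ref in (expected, oracle):
            err = ((fit.fitted_phase_deg - ref + 180.0) % 360.0) - 180.0
            assert abs(err) < 1.0

    def test_window_below_half_cycle_degenerate(self):
        cfg = PredictorConfig(fit_window_frac=(0.90, 0.93))
        trace = (360.0 * 0.6 * T) % 360.0
        with pytest.raises(DegenerateSignalError):
            fit_reference_sine(trace, 0.6, cfg)


class TestLeadAndExtrapolation:
    @pytest.mark.parametrize(
        "target, f0, lead, expected",
        [(90.0, 1.0, 0.25, 0.0), (90.0, 0.8, 0.25, 18.0), (270.0, 0.93, 0.0, 270.0)],
    )
    def test_compensate_lead(self, target, f0, lead, expected):
        assert compensate_lead(target, f0, lead) == pytest.approx(expected)

    def test_earliest_target_within_horizon(self):
        fit = SineFit(center_freq_hz=1.0, fitted_phase_deg=350.0, fit_error=0.0)
        dt, idx = predict_target_time(fit, [0.0], 0, CFG)
        assert dt == pytest.approx(10.0 / 360.0)
        assert idx == 0

    def test_zero_phase_difference_means_next_cycle(self):
        fit = SineFit(center_freq_hz=1.0, fitted_phase_deg=0.0, fit_error=0.0)
        assert predict_target_time(fit, [0.0, 180.0], 0, CFG) is None

    def test_slow_so_horizon_boundary(self):
        fit = SineFit(center_freq_hz=0.8, fitted_phase_deg=300.0, fit_error=0.0)
        # nearest target 18 deg is 78 deg away: 270.8 ms, beyond the horizon
        assert predict_target_time(fit, [18.0, 198.0], 0, CFG) is None
        fit = SineFit(center_freq_hz=0.8, fitted_phase_deg=330.0, fit_error=0.0)
        dt, idx = predict_target_time(fit, [18.0, 198.0], 0, CFG)
        assert dt == pytest.approx(48.0 / (360.0 * 0.8))  # 166.7 ms
        assert idx == 0

    def test_empty_target_list_rejected(self):
        fit = SineFit(center_freq_hz=1.0, fitted_phase_deg=0.0, fit_error=0.0)
        with pytest.raises(ValueError):
            predict_target_time(fit, [], 0, CFG)


class TestStreaming:
    def test_white_noise_never_triggers(self, white_noise_run):
        assert white_noise_run == []

    def test_pure_so_timeout_respected(self, pure_so_run):
        _, events = pure_so_run
        samples = np.array([ev.trigger_sample for ev in events])
        assert len(events) >= 1
        assert np.all(np.diff(samples) >= CFG.timeout_samples)

    def test_trigger_count_bounded(self, pure_so_run):
        rec, events = pure_so_run
        assert 1 <= len(events) <= rec.n_samples // CFG.timeout_samples + 1

    def test_empty_recording_empty_events(self):
        rec = Recording(np.empty((1, 0)), FS)
        assert run_stream(rec, CFG) == []

    def test_deterministic_replay(self, sws_recording):
        rec, _, _ = sws_recording
        assert run_stream(rec, CFG) == run_stream(rec, CFG)

    def test_multichannel_requires_selector(self):
        rec = Recording(np.zeros((2, 1000)), FS)
        with pytest.raises(ValueError):
            run_stream(rec, CFG)
        assert run_stream(rec, CFG, channel=1) == []

    def test_up_target_accuracy_on_synthetic(self, stream_run):
        """Achieved up-target phases concentrate within 45 deg of the
        up-state peak on the default synthetic recording."""
        from conftest import achieved_phases
        from sophase.circular import circ_mean_resultant

        _, truth, events = stream_run
        up = achieved_phases(truth, events, target=90.0)
        assert up.size >= 3
        mean, r, _ = circ_mean_resultant(up)
        dev = min(abs(mean - 90.0), 360.0 - abs(mean - 90.0))
        assert dev < 45.0

    def test_decision_to_emission_within_horizon(self, stream_run):
        _, _, events = stream_run
        for ev in events:
            assert ev.trigger_sample - ev.decision_sample <= CFG.horizon_max_s * FS

    def test_sharper_troughs_degrade_down_targeting(self):
        """Cycle asymmetry (sharper down states) hurts down-state targeting
        while up-state targeting stays accurate — sine extrapolation fits the
        rounder up states better."""
        from conftest import achieved_phases
        from sophase.circular import circ_mean_resultant
        from sophase.synth import SyntheticSpec, generate_recording

        def deviations(sharpening):
            spec = SyntheticSpec(duration_s=240.0, seed=1,
                                 trough_sharpening=sharpening)
            rec, truth, _ = generate_recording(spec)
            events = run_stream(rec, CFG)
            out = {}
            for target in (90.0, 270.0):
                a = achieved_phases(truth, events, target=target)
                mean, _, _ = circ_mean_resultant(a)
                out[target] = min(abs(mean - target), 360.0 - abs(mean - target))
            return out

        symmetric = deviations(1.0)
        sharp = deviations(2.2)
        assert sharp[270.0] > symmetric[270.0]
        assert sharp[270.0] > sharp[90.0]
        assert sharp[90.0] < 45.0

    def test_analysis_suspended_while_pending(self):
        """Between a prediction and its emission no new decision is made."""
        t = np.arange(int(40 * FS)) / FS
        pred = PhasePredictor(CFG)
        decisions = []
        for x in 75.0 * np.sin(2 * np.pi * 1.0 * t):
            ev = pred.step(x)
            if ev is not None:
                decisions.append((ev.decision_sample, ev.trigger_sample))
        for (d1, t1), (d2, _) in zip(decisions, decisions[1:]):
            assert d2 >= t1  # next decision only after previous emission
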