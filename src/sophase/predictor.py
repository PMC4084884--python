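"""Streaming slow-oscillation phase prediction for phase-targeted stimulation.

The algorithm keeps a rolling buffer of the most recent samples (~10 s at
512 Hz). On every new sample, while armed, it:

1. estimates the momentary SO frequency as the FFT bin with the largest
   amplitude in the 0.6-1.2 Hz search band;
2. requires SO-band power to be at least a fixed fraction (0.6) of the total
   non-DC power, so predictions are suppressed outside slow-wave sleep;
3. band-pass filters the buffer around the estimated frequency (causal,
   order-1 Butterworth, 1 Hz bandwidth), takes the Hilbert analytic signal,
   and converts its angle to a sin-convention phase (90 deg = peak);
4. least-squares fits a unit sine of the estimated frequency to the
   normalized phase signal over the 80-95 % stretch of the buffer (the most
   recent data clear of filter edge artifacts), rejecting poor fits;
5. extrapolates the fitted sine into the future and schedules a trigger at
   the earliest occurrence of either target phase, provided it lies within a
   250 ms horizon; target phases are lead-compensated so that the middle of a
   stimulus of known duration lands on the targeted phase at the momentary SO
   frequency.

After each emitted trigger a 10,000-sample time-out suppresses predictions;
analysis is also suspended between a prediction and its emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, freqz, hilbert, lfilter

from .core import Recording, make_event_table

__all__ = [
    "PredictorConfig",
    "BufferState",
    "SineFit",
    "TriggerEvent",
    "PredictorError",
    "NotReadyError",
    "DegenerateSignalError",
    "estimate_center_frequency",
    "so_power_ratio",
    "instantaneous_phase",
    "fit_reference_sine",
    "compensate_lead",
    "predict_target_time",
    "PhasePredictor",
    "run_stream",
    "events_to_table",
]


class PredictorError(RuntimeError):
    """Base class for recoverable predictor conditions."""


class NotReadyError(PredictorError):
    """Raised when an operation needs a full buffer that is not full yet."""


class DegenerateSignalError(PredictorError):
    """Raised for all-zero buffers, vanishing band-passed signals, or fit
    windows shorter than one SO cycle."""


@dataclass(frozen=True)
class PredictorConfig:
    """All constants of the real-time algorithm (defaults per the method)."""

    fs: float = 512.0
    buffer_len: int = 5000
    so_search_band: tuple[float, float] = (0.6, 1.2)
    filter_order: int = 1
    filter_bandwidth_hz: float = 1.0
    fit_window_frac: tuple[float, float] = (0.80, 0.95)
    power_ratio_min: float = 0.6
    fit_error_max: float = 0.1
    horizon_max_s: float = 0.250
    timeout_samples: int = 10000
    target_phases_deg: tuple[float, ...] = (90.0, 270.0)
    playback_lead_s: float = 0.250
    #: fit the unit-amplitude phase signal sin(phase) (default) or the raw
    #: band-passed signal with free amplitude
    fit_normalized: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.fit_window_frac
        if not 0 < lo < hi <= 1:
            raise ValueError("fit_window_frac must satisfy 0 < lo < hi <= 1")
        blo, bhi = self.so_search_band
        if not 0 < blo < bhi < self.fs / 2:
            raise ValueError("so_search_band must lie inside (0, fs/2)")


@dataclass
class BufferState:
    """Rolling window of the most recent ``buffer_len`` samples."""

    buffer_len: int
    _buf: np.ndarray = field(init=False)
    _pos: int = field(default=0, init=False)
    count: int = field(default=0, init=False)
    now_sample: int = field(default=-1, init=False)

    def __post_init__(self) -> None:
        self._buf = np.zeros(self.buffer_len)

    def append(self, x: float) -> None:
        self._buf[self._pos] = x
        self._pos = (self._pos + 1) % self.buffer_len
        self.count += 1
        self.now_sample += 1

    @property
    def full(self) -> bool:
        return self.count >= self.buffer_len

    def window(self) -> np.ndarray:
        """The buffered samples in chronological order (oldest first)."""
        if not self.full:
            raise NotReadyError("buffer not yet full")
        return np.concatenate((self._buf[self._pos :], self._buf[: self._pos]))


@dataclass
class SineFit:
    """Result of fitting sin(2*pi*f0*t + phi) over the fit window."""

    center_freq_hz: float
    fitted_phase_deg: float  # phase of the fitted sine at the newest sample
    fit_error: float  # mean squared residual over the fit window
    power_ratio: float = float("nan")


@dataclass(frozen=True)
class TriggerEvent:
    trigger_sample: int
    targeted_phase_deg: float
    adjusted_phase_deg: float
    center_freq_hz: float
    decision_sample: int


def _band_spectrum(window: np.ndarray, cfg: PredictorConfig):
    """One rfft serving both the center-frequency and power-ratio criteria."""
    amp = np.abs(np.fft.rfft(window))
    freqs = np.fft.rfftfreq(window.size, 1.0 / cfg.fs)
    lo, hi = cfg.so_search_band
    band = (freqs >= lo) & (freqs <= hi)
    return amp, freqs, band


def estimate_center_frequency(buffer: BufferState, cfg: PredictorConfig) -> float:
    """FFT-bin frequency with the largest amplitude in the SO search band.

    Bin spacing is fs/buffer_len (0.1024 Hz at the defaults).
    """
    amp, freqs, band = _band_spectrum(buffer.window(), cfg)
    idx = np.flatnonzero(band)
    return float(freqs[idx[np.argmax(amp[idx])]])


def so_power_ratio(buffer: BufferState, cfg: PredictorConfig) -> float:
    """SO-band FFT power divided by total non-DC power up to Nyquist."""
    amp, freqs, band = _band_spectrum(buffer.window(), cfg)
    power = amp**2
    total = power[1:].sum()
    if total == 0:
        raise DegenerateSignalError("all-zero buffer: power ratio undefined")
    return float(power[band & (freqs > 0)].sum() / total)


def _design_bandpass(f0: float, cfg: PredictorConfig):
    half = cfg.filter_bandwidth_hz / 2.0
    lo = max(f0 - half, 1e-3)
    return butter(cfg.filter_order, [lo, f0 + half], btype="bandpass", fs=cfg.fs)


def _filter_phase_deg(b, a, f0: float, fs: float) -> float:
    """Phase response of the causal filter at f0, degrees."""
    _, h = freqz(b, a, worN=[f0], fs=fs)
    return float(np.degrees(np.angle(h[0])))


def instantaneous_phase(
    window: np.ndarray, f0: float, cfg: PredictorConfig
) -> np.ndarray:
    """Causal filter-Hilbert phase of the buffer, degrees, sin convention.

    The buffer is band-pass filtered forward-only (this is the online path),
    the analytic signal is computed, and its angle is shifted by +90 deg so
    that 90 deg falls on band-passed-signal peaks. The filter's own phase
    response at f0 is subtracted, compensating the causal filter delay.
    """
    lo, hi = cfg.so_search_band
    if not lo <= f0 <= hi:
        raise ValueError(f"f0={f0} Hz outside the search band {cfg.so_search_band}")
    b, a = _design_bandpass(f0, cfg)
    filtered = lfilter(b, a, np.asarray(window, dtype=float))
    # degeneracy is judged on the final stretch, past the causal filter's
    # slowly decaying startup transient, and relative to the input scale
    tail = filtered[int(filtered.size * 0.9) :]
    if np.max(np.abs(tail)) < 1e-9 * max(1.0, float(np.max(np.abs(window)))):
        raise DegenerateSignalError("band-passed signal is (near) zero")
    analytic = hilbert(filtered)
    phase = np.degrees(np.angle(analytic)) + 90.0
    phase -= _filter_phase_deg(b, a, f0, cfg.fs)
    return phase % 360.0


def fit_reference_sine(
    phase_trace_deg: np.ndarray, f0: float, cfg: PredictorConfig
) -> SineFit:
    """Least-squares fit of a sine at f0 to the phase signal.

    By default the fit target is the unit-amplitude signal sin(phase), which
    removes cycle-to-cycle amplitude differences; ``fit_error`` is then the
    mean squared residual of a unit sine and ``fit_error_max=0.1`` applies on
    that scale. Only the 80-95 % stretch of the buffer is used.
    """
    y_full = np.sin(np.radians(np.asarray(phase_trace_deg, dtype=float)))
    n = y_full.size
    i0 = int(n * cfg.fit_window_frac[0])
    i1 = int(n * cfg.fit_window_frac[1])
    # phase is identifiable down to about half a cycle; below that the
    # sin/cos regressors become ill-conditioned
    if (i1 - i0) / cfg.fs < 0.5 / f0:
        raise DegenerateSignalError("fit window shorter than half an SO cycle")
    t = np.arange(i0, i1) / cfg.fs
    y = y_full[i0:i1]
    w = 2 * np.pi * f0
    design = np.column_stack([np.sin(w * t), np.cos(w * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    phi = np.arctan2(coef[1], coef[0])
    if cfg.fit_normalized:
        resid = y - np.sin(w * t + phi)
        fit_error = float(np.mean(resid**2))
    else:
        pred = design @ coef
        amp2 = max(float(coef[0] ** 2 + coef[1] ** 2), 1e-30)
        fit_error = float(np.mean((y - pred) ** 2) / amp2)
    t_now = (n - 1) / cfg.fs
    fitted_phase = (360.0 * f0 * t_now + np.degrees(phi)) % 360.0
    return SineFit(center_freq_hz=f0, fitted_phase_deg=float(fitted_phase), fit_error=fit_error)


def compensate_lead(target_phase_deg: float, f0: float, lead_s: float) -> float:
    """Phase at which playback must start so the stimulus middle hits the
    target: (target - 360*f0*lead) mod 360. Slower SOs need smaller leads in
    phase, hence a different start phase."""
    if lead_s < 0:
        raise ValueError("lead_s must be >= 0")
    return (target_phase_deg - 360.0 * f0 * lead_s) % 360.0


def predict_target_time(
    fit: SineFit,
    adjusted_targets_deg,
    now_sample: int,
    cfg: PredictorConfig,
) -> tuple[float, int] | None:
    """Earliest future occurrence of any adjusted target phase.

    Extrapolates phase as fitted_phase + 360*f0*dt and returns (dt_s, index
    of the chosen target) for the overall earliest occurrence, or None when
    that occurrence lies beyond the horizon. A phase difference of exactly 0
    counts as a full cycle away (the *next* occurrence); ties between targets
    break toward the first-listed (up) target.
    """
    targets = np.atleast_1d(np.asarray(adjusted_targets_deg, dtype=float))
    if targets.size == 0:
        raise ValueError("empty target list")
    dphi = (targets - fit.fitted_phase_deg) % 360.0
    dphi[dphi == 0.0] = 360.0
    dts = dphi / (360.0 * fit.center_freq_hz)
    idx = int(np.argmin(dts))  # argmin keeps the first index on ties
    if dts[idx] > cfg.horizon_max_s:
        return None
    return float(dts[idx]), idx


@dataclass
class _Pending:
    trigger_sample: int
    target_deg: float
    adjusted_deg: float
    f0: float
    decision_sample: int


class PhasePredictor:
    """Online state machine: feed samples one at a time via :meth:`step`."""

    def __init__(self, cfg: PredictorConfig | None = None):
        self.cfg = cfg or PredictorConfig()
        self.state = BufferState(self.cfg.buffer_len)
        # allow a first trigger as soon as criteria are met
        self.samples_since_trigger = self.cfg.timeout_samples
        self._pending: _Pending | None = None

    @property
    def armed(self) -> bool:
        """False while waiting out a pending prediction or the time-out."""
        return (
            self._pending is None
            and self.samples_since_trigger >= self.cfg.timeout_samples
        )

    def step(self, new_sample: float) -> TriggerEvent | None:
        cfg = self.cfg
        st = self.state
        st.append(float(new_sample))
        self.samples_since_trigger += 1

        if self._pending is not None:
            # analysis suspended between decision and emission
            if st.now_sample >= self._pending.trigger_sample:
                ev = TriggerEvent(
                    trigger_sample=self._pending.trigger_sample,
                    targeted_phase_deg=self._pending.target_deg,
                    adjusted_phase_deg=self._pending.adjusted_deg,
                    center_freq_hz=self._pending.f0,
                    decision_sample=self._pending.decision_sample,
                )
                self._pending = None
                self.samples_since_trigger = 0
                return ev
            return None

        if not st.full or self.samples_since_trigger < cfg.timeout_samples:
            return None

        try:
            window = st.window()
            amp, freqs, band = _band_spectrum(window, cfg)
            power = amp**2
            total = power[1:].sum()
            if total == 0:
                return None
            ratio = float(power[band & (freqs > 0)].sum() / total)
            if ratio < cfg.power_ratio_min:
                return None
            idx = np.flatnonzero(band)
            f0 = float(freqs[idx[np.argmax(amp[idx])]])
            phase = instantaneous_phase(window, f0, cfg)
            fit = fit_reference_sine(phase, f0, cfg)
            fit.power_ratio = ratio
            if fit.fit_error > cfg.fit_error_max:
                return None
            adjusted = [
                compensate_lead(tp, f0, cfg.playback_lead_s)
                for tp in cfg.target_phases_deg
            ]
            res = predict_target_time(fit, adjusted, st.now_sample, cfg)
        except PredictorError:
            return None
        if res is None:
            return None
        dt_s, which = res
        trig = st.now_sample + int(round(dt_s * cfg.fs))
        pending = _Pending(
            trigger_sample=trig,
            target_deg=cfg.target_phases_deg[which],
            adjusted_deg=adjusted[which],
            f0=f0,
            decision_sample=st.now_sample,
        )
        if trig <= st.now_sample:  # due immediately
            self.samples_since_trigger = 0
            return TriggerEvent(
                trigger_sample=st.now_sample,
                targeted_phase_deg=pending.target_deg,
                adjusted_phase_deg=pending.adjusted_deg,
                center_freq_hz=pending.f0,
                decision_sample=st.now_sample,
            )
        self._pending = pending
        return None


def run_stream(
    recording: Recording,
    cfg: PredictorConfig | None = None,
    channel: str | int | None = None,
) -> list[TriggerEvent]:
    """Replay a recording through the online state machine, deterministically.

    ``channel`` must be given for multichannel recordings (the real-time
    system received one bipolar frontal derivation).
    """
    if recording.n_channels > 1 and channel is None:
        raise ValueError("multichannel recording: a channel selector is required")
    signal = recording.channel(channel if channel is not None else 0)
    pred = PhasePredictor(cfg)
    events: list[TriggerEvent] = []
    for x in signal:
        ev = pred.step(x)
        if ev is not None:
            events.append(ev)
    return events


def events_to_table(events: list[TriggerEvent], up_down_split: bool = True):
    """Convert trigger events to a standard event table.

    Conditions are derived from the targeted phase: 90 deg -> ``up``,
    270 deg -> ``down``, anything else keeps the phase value as label.
    """
    def cond(ev: TriggerEvent) -> str:
        if abs(ev.targeted_phase_deg - 90.0) < 1e-9:
            return "up"
        if abs(ev.targeted_phase_deg - 270.0) < 1e-9:
            return "down"
        return ""

    table = make_event_table(
        [ev.trigger_sample for ev in events],
        labels=[f"{ev.targeted_phase_deg:g}deg@{ev.center_freq_hz:.4f}Hz" for ev in events],
        conditions=[cond(ev) for ev in events],
    )
    table["adjusted_phase_deg"] = [ev.adjusted_phase_deg for ev in events]
    table["center_freq_hz"] = [ev.center_freq_hz for ev in events]
    return table
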