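"""Synthetic slow-wave-sleep EEG with known ground-truth slow-oscillation phase.

The generator produces the signal regime the real-time phase predictor assumes:
a dominant slow oscillation (SO) whose instantaneous frequency wanders inside
0.6-1.2 Hz, asymmetric cycles (sharper down-state troughs than up-state peaks),
a 1/f background, optional up-state-coupled spindle bursts (11-15 Hz), and
arousal segments in which the SO is suppressed and broadband power elevated.
Every recording carries a per-sample ground-truth phase trace (sin convention:
90 deg = up-state peak, 270 deg = down-state trough), so phase-targeting
accuracy can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Recording, make_event_table


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic slow-wave-sleep recording.

    Attributes
    ----------
    duration_s : float
        Recording length in seconds.
    fs : float
        Sampling rate in Hz (>= 100).
    so_freq_range : (float, float)
        Band the SO instantaneous frequency is confined to, Hz.
    so_freq_walk_sd : float
        SD of the per-cycle random-walk step of the SO frequency, Hz.
    so_amplitude : float
        SO amplitude in signal units (microvolt scale).
    trough_sharpening : float
        >= 1; ratio of phase velocity at the trough to that at the peak.
        1 gives a pure frequency-modulated sinusoid.
    noise_exponent : float
        Slope alpha of the 1/f**alpha background power spectrum.
    noise_amplitude : float
        RMS of the background noise, signal units.
    spindle_rate : float
        Spindle bursts per minute.
    spindle_band : (float, float)
        Spindle carrier frequency range, Hz.
    spindle_phase_coupling : float
        SO phase (degrees) at which burst centers are placed.
    spindle_amplitude : float
        Peak envelope amplitude of a burst, signal units.
    arousal_intervals : sequence of (float, float)
        (start_s, end_s) segments with suppressed SO and elevated broadband
        activity.
    n_channels : int
        Extra channels are amplitude-scaled, lag-shifted copies of channel 0
        plus independent background noise.
    seed : int
        Seed for all randomness; identical seeds give identical recordings.
    """

    duration_s: float = 300.0
    fs: float = 512.0
    so_freq_range: tuple[float, float] = (0.6, 1.2)
    so_freq_walk_sd: float = 0.05
    so_amplitude: float = 75.0
    trough_sharpening: float = 1.3
    noise_exponent: float = 1.0
    noise_amplitude: float = 20.0
    spindle_rate: float = 3.0
    spindle_band: tuple[float, float] = (11.0, 15.0)
    spindle_phase_coupling: float = 90.0
    spindle_amplitude: float = 10.0
    arousal_intervals: tuple[tuple[float, float], ...] = ()
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        lo, hi = self.so_freq_range
        if not 0 < lo < hi:
            raise ValueError("so_freq_range must satisfy 0 < low < high")
        if self.trough_sharpening < 1:
            raise ValueError("trough_sharpening must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass
class GroundTruth:
    """Per-sample truth for a synthetic recording (channel 0).

    ``phase_deg`` is the true SO phase in [0, 360) with 90 deg at up-state
    peaks of the noiseless SO component; ``inst_freq_hz`` is its exact rate of
    change / 360 (includes the cycle-asymmetry modulation); ``so_freq_hz`` is
    the underlying random-walk base frequency per sample.
    """

    phase_deg: np.ndarray
    inst_freq_hz: np.ndarray
    so_freq_hz: np.ndarray
    arousal_intervals: tuple[tuple[float, float], ...] = ()


def _reflect(x: float, lo: float, hi: float) -> float:
    # reflecting boundaries for the frequency walk
    span = hi - lo
    y = (x - lo) % (2 * span)
    return lo + (y if y <= span else 2 * span - y)


def _so_phase(spec: SyntheticSpec, rng: np.random.Generator):
    """Integrate the reflecting frequency walk into a continuous phase.

    Returns base phase theta (rad, unwrapped), base frequency per sample, and
    the asymmetry coefficient ``a``.
    """
    n = int(round(spec.duration_s * spec.fs))
    lo, hi = spec.so_freq_range
    # one frequency value per SO cycle, piecewise constant within the cycle
    f_cycle = 0.5 * (lo + hi)
    theta = np.empty(n)
    f_base = np.empty(n)
    ph = 0.0
    next_wrap = 2 * np.pi
    for i in range(n):
        theta[i] = ph
        f_base[i] = f_cycle
        ph += 2 * np.pi * f_cycle / spec.fs
        if ph >= next_wrap:  # completed a cycle: step the walk
            next_wrap += 2 * np.pi
            f_cycle = _reflect(
                f_cycle + rng.normal(0.0, spec.so_freq_walk_sd), lo, hi
            )
    a = (spec.trough_sharpening - 1.0) / (spec.trough_sharpening + 1.0)
    return theta, f_base, a


def _one_over_f_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f**exponent, scaled to given RMS."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    # flatten below 0.3 Hz so the shaping stays integrable; kill DC
    f_eff = np.maximum(freqs, 0.3)
    shape = f_eff ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / np.sqrt(np.mean(x**2)))


def _spindle_train(
    spec: SyntheticSpec,
    phase_deg: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-windowed 11-15 Hz bursts centered on the coupled SO phase."""
    n = phase_deg.size
    out = np.zeros(n)
    n_bursts = int(round(spec.spindle_rate * spec.duration_s / 60.0))
    if n_bursts == 0 or spec.spindle_amplitude == 0:
        return out
    # samples where the phase crosses the coupling phase (one per cycle)
    d = np.diff(((phase_deg - spec.spindle_phase_coupling) % 360.0))
    crossings = np.flatnonzero(d < -180.0) + 1
    if crossings.size == 0:
        return out
    centers = rng.choice(crossings, size=min(n_bursts, crossings.size), replace=False)
    sigma_s = 0.15  # burst envelope SD, ~0.7 s visible duration
    half = int(round(4 * sigma_s * spec.fs))
    t = np.arange(-half, half + 1) / spec.fs
    for c in centers:
        f_sp = rng.uniform(*spec.spindle_band)
        burst = (
            spec.spindle_amplitude
            * np.exp(-(t**2) / (2 * sigma_s**2))
            * np.sin(2 * np.pi * f_sp * t + rng.uniform(0, 2 * np.pi))
        )
        i0, i1 = c - half, c + half + 1
        j0, j1 = max(i0, 0), min(i1, n)
        out[j0:j1] += burst[j0 - i0 : j1 - i0]
    return out


def _arousal_gain(spec: SyntheticSpec, n: int) -> np.ndarray:
    """Multiplicative gain suppressing the SO inside arousal intervals.

    Cosine ramps of 0.5 s at the interval edges avoid step discontinuities.
    """
    gain = np.ones(n)
    ramp = int(round(0.5 * spec.fs))
    for start_s, end_s in spec.arousal_intervals:
        i0 = int(round(start_s * spec.fs))
        i1 = int(round(end_s * spec.fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        gain[i0:i1] = 0.05
        left = np.arange(max(i0 - ramp, 0), i0)
        if left.size:
            gain[left] = np.minimum(
                gain[left], 0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * (left - left[0]) / max(left.size, 1)))
            )
        right = np.arange(i1, min(i1 + ramp, n))
        if right.size:
            gain[right] = np.minimum(
                gain[right], 0.05 + 0.95 * 0.5 * (1 - np.cos(np.pi * (right - i1) / max(right.size, 1)))
            )
    return gain


def generate_recording(
    spec: SyntheticSpec,
) -> tuple[Recording, GroundTruth, pd.DataFrame]:
    """Generate a synthetic SWS recording with ground truth and arousal events.

    Returns
    -------
    recording : Recording
        ``n_channels x n_samples``; channel 0 is the SO channel the predictor
        should be fed.
    truth : GroundTruth
        Per-sample true phase and frequency for channel 0.
    events : DataFrame
        One row per arousal interval (label ``arousal``, sample = start).
    """
    rng = np.random.default_rng(spec.seed)
    theta, f_base, a = _so_phase(spec, rng)
    n = theta.size

    # monotone phase warp: g(theta) = theta + a*(cos theta - 1), g' = 1 - a sin
    warped = theta + a * (np.cos(theta) - 1.0)
    phase_deg = np.degrees(warped) % 360.0
    inst_freq = f_base * (1.0 - a * np.sin(theta))

    so = spec.so_amplitude * np.sin(warped)
    spindles = _spindle_train(spec, phase_deg, rng)
    gain = _arousal_gain(spec, n)

    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        lag = int(round(0.01 * spec.fs)) * ch
        scale = 0.8**ch
        clean = np.roll(so + spindles, lag) * scale
        noise = _one_over_f_noise(
            n, spec.fs, spec.noise_exponent, spec.noise_amplitude, rng
        )
        chan = clean * gain + noise
        # arousals: broadband elevation on top of the suppressed SO
        if spec.arousal_intervals:
            extra = rng.standard_normal(n) * (1.5 * spec.noise_amplitude)
            chan = chan + extra * (1.0 - gain)
        data[ch] = chan

    rec = Recording(data, spec.fs, [f"ch{i}" for i in range(spec.n_channels)])
    truth = GroundTruth(
        phase_deg=phase_deg,
        inst_freq_hz=inst_freq,
        so_freq_hz=f_base,
        arousal_intervals=tuple(spec.arousal_intervals),
    )
    starts = [int(round(s * spec.fs)) for s, _ in spec.arousal_intervals]
    order = np.argsort(starts)
    events = make_event_table(
        [starts[i] for i in order],
        labels=[
            f"arousal:{spec.arousal_intervals[i][0]:g}-{spec.arousal_intervals[i][1]:g}"
            for i in order
        ],
        conditions=[""] * len(starts),
    )
    return rec, truth, events


def kcomplex_template(fs: float, duration_s: float = 1.2) -> np.ndarray:
    """A K-complex-like biphasic waveform (unit peak amplitude).

    Small early positivity, large sharp negativity near 550 ms, and a slower
    late positive rebound -- the canonical evoked K-complex morphology.
    """
    t = np.arange(int(round(duration_s * fs))) / fs
    g = lambda mu, sd: np.exp(-((t - mu) ** 2) / (2 * sd**2))
    w = 0.4 * g(0.25, 0.06) - 1.0 * g(0.55, 0.09) + 0.6 * g(0.90, 0.15)
    return w / np.max(np.abs(w))


def inject_evoked_response(
    recording: Recording,
    events: pd.DataFrame,
    template: np.ndarray,
    scale: float = 1.0,
) -> Recording:
    """Return a copy of ``recording`` with ``scale * template`` added at each
    event onset (all channels). Purely additive, so injection order is
    irrelevant and ``scale=0`` is the identity."""
    template = np.asarray(template, dtype=float)
    data = recording.data.copy()
    n = recording.n_samples
    for s in events["sample"].to_numpy():
        s = int(s)
        if s < 0 or s + template.size > n:
            raise IndexError(f"event at sample {s} extends beyond the recording")
        data[:, s : s + template.size] += scale * template
    return Recording(data, recording.fs, list(recording.channel_names))


def generate_behavior(
    n_subjects: int,
    n_pairs_per_contrast: int,
    p_first: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate two-alternative forced-choice behavior.

    Each subject chooses the first category of every pair with probability
    ``p_first`` (independent Bernoulli draws). Returns one row per subject and
    contrast with the percentage of first-category choices.
    """
    if not 0.0 <= p_first <= 1.0:
        raise ValueError("p_first must be in [0, 1]")
    if n_pairs_per_contrast <= 0:
        raise ValueError("n_pairs_per_contrast must be positive")
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(seed)
    contrasts = ("up_vs_down", "up_vs_new", "down_vs_new")
    rows = []
    for subj in range(n_subjects):
        for contrast in contrasts:
            choices = rng.random(n_pairs_per_contrast) < p_first
            rows.append(
                {
                    "subject": subj,
                    "contrast": contrast,
                    "percent_first": 100.0 * choices.mean(),
                }
            )
    return pd.DataFrame(rows)
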