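"""Event exclusion, epoching, baseline correction, ERPs and fake events.

Fake events are phase-matched control time points: for every stimulus, the
latest moment in the preceding 3 s at which the SO phase rose through the
same value is labelled a fake event. Comparing stimulus epochs with fake
epochs isolates stimulus-evoked activity from spontaneous SO-locked dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .core import Recording, validate_event_table


@dataclass
class EpochSet:
    """Epoched data: events x channels x time, half-open window [t0, t1)."""

    data: np.ndarray
    fs: float
    t0_s: float = -1.0
    t1_s: float = 2.5
    baseline_window_s: tuple[float, float] | None = None
    conditions: list[str] = field(default_factory=list)
    events: pd.DataFrame | None = None
    skipped: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be events x channels x time")
        expected = int(round((self.t1_s - self.t0_s) * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"time axis has {self.data.shape[2]} samples, expected {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Latencies relative to event onset, seconds."""
        return self.t0_s + np.arange(self.data.shape[2]) / self.fs

    def _window_slice(self, window_s: tuple[float, float]) -> slice:
        lo, hi = window_s
        if lo < self.t0_s - 1e-9 or hi > self.t1_s + 1e-9:
            raise ValueError(f"window {window_s} outside epoch extent")
        i0 = int(round((lo - self.t0_s) * self.fs))
        i1 = int(round((hi - self.t0_s) * self.fs))
        return slice(i0, max(i1, i0 + 1))


def exclude_arousal_events(
    events: pd.DataFrame,
    arousal_intervals,
    fs: float,
    margin_s: float = 2.0,
) -> pd.DataFrame:
    """Drop events within ``margin_s`` of any arousal interval.

    An event at time t is removed when t falls in [start - margin, end +
    margin] of any (start_s, end_s) interval.
    """
    validate_event_table(events)
    t = events["sample"].to_numpy() / fs
    keep = np.ones(t.size, dtype=bool)
    for start_s, end_s in arousal_intervals:
        if end_s < start_s:
            raise ValueError("malformed arousal interval (end < start)")
        keep &= ~((t >= start_s - margin_s) & (t <= end_s + margin_s))
    return events.loc[keep].reset_index(drop=True)


def epoch(
    recording: Recording,
    events: pd.DataFrame,
    t0_s: float = -1.0,
    t1_s: float = 2.5,
) -> EpochSet:
    """Cut windows [event + t0*fs, event + t1*fs) around each event.

    Events too close to a recording edge are collected in ``EpochSet.skipped``
    instead of raising.
    """
    validate_event_table(events)
    fs = recording.fs
    n_time = int(round((t1_s - t0_s) * fs))
    samples = events["sample"].to_numpy(dtype=int)
    i0 = samples + int(round(t0_s * fs))
    ok = (i0 >= 0) & (i0 + n_time <= recording.n_samples)
    kept = events.loc[ok].reset_index(drop=True)
    data = np.stack(
        [recording.data[:, j : j + n_time] for j in i0[ok]], axis=0
    ) if ok.any() else np.empty((0, recording.n_channels, n_time))
    return EpochSet(
        data=data,
        fs=fs,
        t0_s=t0_s,
        t1_s=t1_s,
        conditions=list(kept["condition"]),
        events=kept,
        skipped=events.loc[~ok].copy(),
    )


def baseline_correct(
    epochs: EpochSet, window_s: tuple[float, float] = (-0.750, 0.0)
) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    sl = epochs._window_slice(window_s)
    baseline = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return EpochSet(
        data=epochs.data - baseline,
        fs=epochs.fs,
        t0_s=epochs.t0_s,
        t1_s=epochs.t1_s,
        baseline_window_s=window_s,
        conditions=list(epochs.conditions),
        events=epochs.events,
        skipped=epochs.skipped,
    )


def erp(
    epochs: EpochSet, lowpass_hz: float = 35.0
) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass filtered event-related potential and its standard error.

    Each epoch is zero-phase low-pass filtered (4th-order Butterworth) before
    averaging; the standard error across epochs supports the usual shaded
    grand-average display.

    Returns
    -------
    mean, sem : ndarray, channels x time
    """
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to average")
    if lowpass_hz is not None and lowpass_hz < epochs.fs / 2:
        b, a = butter(4, lowpass_hz, btype="lowpass", fs=epochs.fs)
        filtered = filtfilt(b, a, epochs.data, axis=2)
    else:
        filtered = epochs.data
    mean = filtered.mean(axis=0)
    sem = filtered.std(axis=0, ddof=1) / np.sqrt(epochs.n_epochs) \
        if epochs.n_epochs > 1 else np.zeros_like(mean)
    return mean, sem


def match_fake_events(
    stim_events: pd.DataFrame,
    phase_trace: np.ndarray,
    fs: float,
    lookback_s: float = 3.0,
    tolerance_deg: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct phase-matched fake events preceding each stimulus.

    For each stimulus at phase phi, the latest sample in [t - lookback, t)
    where the phase rises through phi (circular difference crossing zero from
    below, within ``tolerance_deg``) becomes a fake event with condition
    ``fake_up``/``fake_down`` mirroring the stimulus condition. Stimuli with
    no qualifying crossing are reported unmatched, never fabricated; each
    stimulus appears exactly once in the union of the two outputs.
    """
    validate_event_table(stim_events)
    phase_trace = np.asarray(phase_trace, dtype=float)
    lb = int(round(lookback_s * fs))
    matched_rows, unmatched_rows = [], []
    for _, row in stim_events.iterrows():
        s = int(row["sample"])
        phi = phase_trace[s]
        w0 = max(s - lb, 0)
        seg = phase_trace[w0:s]
        if seg.size < 2:
            unmatched_rows.append(row)
            continue
        d = ((seg - phi + 180.0) % 360.0) - 180.0
        rising = (
            (d[:-1] < 0)
            & (d[1:] >= 0)
            & (d[1:] - d[:-1] < 180.0)  # exclude wrap-around jumps
            & (np.abs(d[1:]) <= tolerance_deg)
        )
        hits = np.flatnonzero(rising)
        if hits.size == 0:
            unmatched_rows.append(row)
            continue
        fake_sample = w0 + hits[-1] + 1  # latest crossing
        cond = row.get("condition", "")
        matched_rows.append(
            {
                "sample": fake_sample,
                "label": f"fake_for_{s}",
                "condition": "fake_up" if cond == "up" else "fake_down",
                "stim_sample": s,
            }
        )
    matched = pd.DataFrame(
        matched_rows, columns=["sample", "label", "condition", "stim_sample"]
    )
    if len(matched):
        matched = matched.sort_values("sample").reset_index(drop=True)
    unmatched = pd.DataFrame(unmatched_rows).reset_index(drop=True)
    return matched, unmatched
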