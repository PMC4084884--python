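"""Core containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Event-table columns, in file order.
EVENT_COLUMNS = ("sample", "label", "condition")

#: Recognised event conditions.
CONDITIONS = ("up", "down", "novel", "fake_up", "fake_down")


@dataclass
class Recording:
    """A continuous multi-channel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolt-scale arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return a single channel as a 1-D array."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(f"unknown channel {name_or_index!r}") from None
        else:
            idx = int(name_or_index)
        return self.data[idx]


def make_event_table(samples, labels=None, conditions=None) -> pd.DataFrame:
    """Build a sorted-checked event table (columns sample/label/condition)."""
    samples = np.asarray(samples, dtype=int)
    n = samples.size
    table = pd.DataFrame(
        {
            "sample": samples,
            "label": list(labels) if labels is not None else [""] * n,
            "condition": list(conditions) if conditions is not None else [""] * n,
        }
    )
    validate_event_table(table)
    return table


def validate_event_table(table: pd.DataFrame) -> None:
    """Check required columns and strictly increasing sample order."""
    for col in EVENT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"event table missing column {col!r}")
    s = table["sample"].to_numpy()
    if s.size > 1 and np.any(np.diff(s) < 0):
        bad = np.flatnonzero(np.diff(s) < 0) + 1
        raise ValueError(f"event samples not sorted at rows {bad.tolist()}")
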