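"""Readers and writers for the interchange formats.

Signals travel as EDF (the lingua franca of sleep EEG; 16-bit, one data
record per second) or as plain tab-separated numeric text; events and arousal
intervals as tab-separated tables; configuration as flat key=value text.
EDF files are written by a minimal built-in encoder and read back through
MNE's EDF reader, so round trips cross an independent parser.
"""

from __future__ import annotations

import datetime as _dt
import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EVENT_COLUMNS, Recording, validate_event_table

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path) -> None:
    """Write a recording as EDF with one data record per second.

    The sampling rate must be an integer (samples per one-second record).
    The final partial record, if any, is zero-padded; physical units are
    microvolts with a symmetric range covering the data.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / fs))
    phys_max = max(float(np.max(np.abs(recording.data))), 1.0) * 1.0001
    # the header stores the range as printed text: scale with the printed
    # value so writer and reader agree exactly
    phys_max = float(f"{phys_max:.6g}")  # 6 sig figs so "-<max>" fits 8 chars
    phys_min = -phys_max
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_sig)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_sig), 4),
        ]
    )
    sig_fields = [
        [_pad(name, 16) for name in recording.channel_names],
        [_pad("EEG", 80)] * n_sig,
        [_pad("uV", 8)] * n_sig,
        [_pad(f"{phys_min:.6g}", 8)] * n_sig,
        [_pad(f"{phys_max:.6g}", 8)] * n_sig,
        [_pad(str(_EDF_DIG_MIN), 8)] * n_sig,
        [_pad(str(_EDF_DIG_MAX), 8)] * n_sig,
        [_pad("", 80)] * n_sig,
        [_pad(str(fs), 8)] * n_sig,
        [_pad("", 32)] * n_sig,
    ]
    padded = np.zeros((n_sig, n_rec * fs))
    padded[:, : recording.n_samples] = recording.data
    digital = np.clip(
        np.round((padded - phys_min) * scale) + _EDF_DIG_MIN,
        _EDF_DIG_MIN,
        _EDF_DIG_MAX,
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for group in sig_fields:
            fh.write(b"".join(group))
        for rec_i in range(n_rec):
            for ch in range(n_sig):
                fh.write(digital[ch, rec_i * fs : (rec_i + 1) * fs].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file (via MNE) into a Recording in microvolts."""
    import mne

    path = Path(path)
    if path.stat().st_size < 256:
        raise ValueError(f"{path}: truncated EDF header ({path.stat().st_size} bytes)")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # surface parse problems explicitly
        raise ValueError(f"{path}: failed to parse as EDF: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE stores EEG in volts
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def write_delimited(recording: Recording, path) -> None:
    """Write samples as tab-separated text, one column per channel."""
    np.savetxt(path, recording.data.T, delimiter="\t", fmt="%.6f")


def read_delimited(path, fs: float, channel_names=None) -> Recording:
    """Read tab-separated numeric text; the sampling rate must be supplied."""
    if fs is None or fs <= 0:
        raise ValueError("delimited input requires a positive fs")
    data = np.loadtxt(path, delimiter="\t", ndmin=2).T
    return Recording(data, fs, list(channel_names) if channel_names else [])


def read_signal(path, fmt: str | None = None, fs: float | None = None) -> Recording:
    """Dispatch on format (``edf`` or ``delimited``; inferred from suffix)."""
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        return read_edf(path)
    if fmt == "delimited":
        return read_delimited(path, fs)
    raise ValueError(f"unknown signal format {fmt!r}")


def write_signal(recording: Recording, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        write_edf(recording, path)
    elif fmt == "delimited":
        write_delimited(recording, path)
    else:
        raise ValueError(f"unknown signal format {fmt!r}")


def write_events(table: pd.DataFrame, path) -> None:
    """Write an event table as TSV with header ``sample\\tlabel\\tcondition``."""
    validate_event_table(table)
    cols = [c for c in EVENT_COLUMNS] + [
        c for c in table.columns if c not in EVENT_COLUMNS
    ]
    table[cols].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read a TSV event table; enforces the header and sorted samples."""
    table = pd.read_csv(path, sep="\t", dtype={"label": str, "condition": str})
    for col in EVENT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing event column {col!r}")
    table["label"] = table["label"].fillna("")
    table["condition"] = table["condition"].fillna("")
    validate_event_table(table)
    dup = table["sample"].duplicated()
    if dup.any():
        warnings.warn(
            f"{path}: duplicate event samples at rows {list(table.index[dup])}",
            stacklevel=2,
        )
    return table


def write_intervals(intervals, path) -> None:
    """Write (start_s, end_s) intervals as TSV."""
    pd.DataFrame(intervals, columns=["start_s", "end_s"]).to_csv(
        path, sep="\t", index=False
    )


def read_intervals(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def _parse_value(raw: str):
    raw = raw.strip()
    if "," in raw:
        return tuple(_parse_value(part) for part in raw.split(","))
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    return raw


def read_config(path) -> dict:
    """Read a flat ``key = value`` config file; '#' starts a comment."""
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, raw = line.split("=", 1)
        out[key.strip()] = _parse_value(raw)
    return out


def write_config(cfg: dict, path) -> None:
    lines = []
    for key, val in cfg.items():
        if isinstance(val, (tuple, list)):
            val = ",".join(str(v) for v in val)
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def predictor_config_from_dict(d: dict):
    """Build a PredictorConfig from a flat config dict, rejecting unknown keys."""
    from .predictor import PredictorConfig
    import dataclasses

    valid = {f.name for f in dataclasses.fields(PredictorConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PredictorConfig(**d)


#: Provenance of each predictor default: printed method value vs package choice.
CONFIG_PROVENANCE = {
    "fs": "paper",
    "buffer_len": "paper",
    "so_search_band": "paper",
    "filter_order": "paper",
    "filter_bandwidth_hz": "paper",
    "fit_window_frac": "paper",
    "power_ratio_min": "paper",
    "fit_error_max": "paper",
    "horizon_max_s": "paper",
    "timeout_samples": "paper",
    "target_phases_deg": "paper",
    "playback_lead_s": "paper",
    "fit_normalized": "default",
}
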