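"""Shared fixtures: synthetic recordings and predictor replays.

The heavier fixtures (the 300 s streaming replay) are session-scoped so the
predictor runs once and its triggers are reused by the contract, accuracy and
acceptance tests.
"""

import numpy as np
import pytest

from sophase.core import Recording
from sophase.predictor import PredictorConfig, run_stream
from sophase.synth import SyntheticSpec, generate_recording

FS = 512.0


@pytest.fixture(scope="session")
def sws_recording():
    """Default 120 s synthetic SWS recording with ground truth (seed 1)."""
    spec = SyntheticSpec(duration_s=120.0, seed=1)
    rec, truth, events = generate_recording(spec)
    return rec, truth, events


@pytest.fixture(scope="session")
def stream_run():
    """300 s default recording replayed through the online predictor."""
    spec = SyntheticSpec(duration_s=300.0, seed=1)
    rec, truth, _ = generate_recording(spec)
    events = run_stream(rec, PredictorConfig())
    return rec, truth, events


@pytest.fixture(scope="session")
def white_noise_run():
    """60 s of pure white noise replayed through the predictor."""
    rng = np.random.default_rng(0)
    rec = Recording(rng.standard_normal(int(60 * FS))[np.newaxis, :], FS)
    return run_stream(rec, PredictorConfig())


@pytest.fixture(scope="session")
def pure_so_run():
    """120 s noiseless 1 Hz slow oscillation replayed through the predictor."""
    t = np.arange(int(120 * FS)) / FS
    rec = Recording((75.0 * np.sin(2 * np.pi * 1.0 * t))[np.newaxis, :], FS)
    return rec, run_stream(rec, PredictorConfig())


def achieved_phases(truth, events, fs=FS, lead_s=0.250, target=None):
    """Ground-truth phase at trigger + playback lead, per targeted phase."""
    shift = int(round(lead_s * fs))
    out = []
    for ev in events:
        if target is not None and ev.targeted_phase_deg != target:
            continue
        out.append(truth.phase_deg[ev.trigger_sample + shift])
    return np.asarray(out)
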