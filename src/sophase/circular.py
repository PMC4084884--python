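"""Offline phase validation: filter-Hilbert phase and circular statistics.

Targeting performance is scored offline by re-extracting the SO phase with a
zero-phase 0.5-1.5 Hz Butterworth filter and the Hilbert transform, reading
the phase at stimulus markers, and applying circular statistics: the Rayleigh
test of non-uniformity (Z = n*R**2) and the Watson-Williams circular one-way
ANOVA comparing up- versus down-targeted distributions. A recording "passes"
when the up-targeted mean deviates < 45 deg from the up-state peak (90 deg),
the up distribution is non-uniform (P < 0.05), and up and down distributions
differ (P < 0.05); the down distribution is deliberately NOT required to be
accurate on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert
from scipy.stats import f as f_dist


@dataclass
class CircularSummary:
    n: int
    mean_deg: float
    resultant_R: float
    circ_sd_deg: float
    rayleigh_Z: float
    rayleigh_p: float


@dataclass
class InclusionReport:
    mean_up_deviation_deg: float
    up_rayleigh_p: float
    ww_p: float
    included: bool


def offline_phase(signal: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.5-1.5 Hz filter-Hilbert phase, degrees in [0, 360).

    Sin convention: 90 deg at band-passed-signal maxima, 270 deg at minima,
    0 deg at rising zero-crossings.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size <= 4 * fs:
        raise ValueError("signal must be longer than 4 s for stable filtering")
    b, a = butter(2, [0.5, 1.5], btype="bandpass", fs=fs)
    filtered = filtfilt(b, a, signal)
    phase = np.degrees(np.angle(hilbert(filtered))) + 90.0
    return phase % 360.0


def phase_at_events(
    phase_trace: np.ndarray,
    events: pd.DataFrame,
    fs: float,
    marker_offset_s: float = 0.250,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Phase at ``event sample + round(marker_offset_s * fs)`` per event.

    The default 0.25 s offset moves trigger markers to the middle of a 0.5 s
    stimulus. Out-of-bounds events are returned in a skipped-events table,
    never silently dropped.

    Returns
    -------
    angles : ndarray of float, degrees
    skipped : DataFrame of the out-of-bounds rows
    """
    phase_trace = np.asarray(phase_trace)
    shift = int(round(marker_offset_s * fs))
    idx = events["sample"].to_numpy(dtype=int) + shift
    ok = (idx >= 0) & (idx < phase_trace.size)
    skipped = events.loc[~ok].copy()
    return phase_trace[idx[ok]].astype(float), skipped


def circ_mean_resultant(angles_deg) -> tuple[float, float, float]:
    """Vector-average circular mean, resultant length R, and circular SD.

    circ_sd = sqrt(-2*ln R), reported in degrees. For R ~ 0 (perfectly
    balanced angles) the mean direction is undefined and returned as NaN.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle list")
    z = np.exp(1j * a).mean()
    r = float(np.abs(z))
    mean = float(np.degrees(np.angle(z)) % 360.0) if r > 1e-12 else float("nan")
    sd = float(np.degrees(np.sqrt(-2.0 * np.log(max(r, 1e-300)))))
    return mean, r, sd


def circular_distance_deg(a: float, b: float) -> float:
    """Minimum absolute angular difference on the circle, <= 180 deg."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return float(np.minimum(d, 360.0 - d))


def rayleigh_test(angles_deg) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Z = n*R**2 exactly; p uses the standard small-sample-corrected
    approximation (Zar / CircStat):
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with Rn = n*R.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("Rayleigh test requires n >= 2")
    _, r, _ = circ_mean_resultant(a)
    rn = n * r
    z = n * r**2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - rn**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))


def summarize(angles_deg) -> CircularSummary:
    """Full circular summary (mean, R, SD, Rayleigh Z and p)."""
    mean, r, sd = circ_mean_resultant(angles_deg)
    z, p = rayleigh_test(angles_deg)
    return CircularSummary(
        n=len(angles_deg), mean_deg=mean, resultant_R=r, circ_sd_deg=sd,
        rayleigh_Z=z, rayleigh_p=p,
    )


def _vonmises_kappa(r: float) -> float:
    # maximum-likelihood kappa from the mean resultant (Fisher/Best-Fisher)
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams_test(groups) -> tuple[float, float]:
    """Watson-Williams circular one-way ANOVA across >= 2 angle groups.

    F = K * ((sum_i R_i - R) / (k-1)) / ((N - sum_i R_i) / (N-k)) with the
    concentration correction K = 1 + 3/(8*kappa); p from the F(k-1, N-k)
    distribution. A warning is issued when the concentration is too low for
    the test's assumptions.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group requires n >= 2")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    # per-group and pooled resultant vectors
    zs = [np.exp(1j * np.radians(g)).sum() for g in groups]
    r_is = np.array([abs(z) for z in zs])
    r_pooled = abs(sum(zs))
    rw = r_is.sum() / n_total
    kappa = _vonmises_kappa(rw)
    if rw < 0.45 or np.any(ns < 5):
        warnings.warn(
            "Watson-Williams assumptions questionable (low concentration or "
            "small groups); interpret p with caution",
            stacklevel=2,
        )
    correction = 1.0 + 3.0 / (8.0 * kappa)
    num = (r_is.sum() - r_pooled) / (k - 1)
    den = (n_total - r_is.sum()) / (n_total - k)
    if den <= 0:
        return float("inf"), 0.0
    f_stat = correction * num / den
    f_stat = max(f_stat, 0.0)
    p = float(f_dist.sf(f_stat, k - 1, n_total - k))
    return float(f_stat), p


def inclusion_check(up_angles_deg, down_angles_deg) -> InclusionReport:
    """Apply the three subject-inclusion criteria.

    1. up-targeted circular mean within 45 deg of the up-state peak (90 deg);
    2. up-targeted distribution non-uniform (Rayleigh P < 0.05);
    3. up- and down-targeted distributions differ (Watson-Williams P < 0.05).

    Down-targeted accuracy per se is not required.
    """
    up = np.asarray(up_angles_deg, dtype=float)
    down = np.asarray(down_angles_deg, dtype=float)
    if up.size == 0 or down.size == 0:
        raise ValueError("both angle lists must be non-empty")
    mean_up, _, _ = circ_mean_resultant(up)
    deviation = circular_distance_deg(mean_up, 90.0)
    _, p_rayleigh = rayleigh_test(up)
    _, p_ww = watson_williams_test([up, down])
    return InclusionReport(
        mean_up_deviation_deg=deviation,
        up_rayleigh_p=p_rayleigh,
        ww_p=p_ww,
        included=bool(deviation < 45.0 and p_rayleigh < 0.05 and p_ww < 0.05),
    )
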