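# Methods

This note documents the models, algorithms and numerical choices behind
`sophase`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic benchmark does and does not
establish.

## The streaming phase predictor

The predictor treats the slow oscillation (SO) as a locally sinusoidal
process with a slowly wandering frequency. On every new sample, while armed,
it performs:

1. **Frequency estimate.** FFT of the most recent 5000-sample buffer
   (~9.8 s at 512 Hz); the SO frequency f₀ is the bin with the largest
   amplitude in 0.6–1.2 Hz. Bin spacing is fs/N = 0.1024 Hz, so f₀ is
   quantized to about ±0.05 Hz.
2. **Power criterion.** SO-band FFT power must be at least 0.6 of the total
   power. "Total" is taken over all non-DC bins up to Nyquist: the DC bin is
   amplifier offset, physiologically meaningless, and would otherwise
   dominate the denominator.
3. **Phase extraction.** Order-1 Butterworth band-pass of 1 Hz bandwidth
   centered on f₀, applied *causally* (forward only — this is the online
   path; the offline validation uses zero-phase filtering instead). The
   Hilbert analytic angle is shifted by +90° to the sin convention
   (90° = peak of the band-passed signal) and the filter's own phase
   response at f₀, evaluated from its transfer function, is subtracted to
   compensate the causal delay.
4. **Sine fit.** The fit target is sin φ(t), the unit-amplitude projection
   of the extracted phase — normalizing away cycle-to-cycle amplitude
   differences so that the 0.1 fit-error threshold has a fixed scale (mean
   squared residual of a unit sine; an unnormalized variant that fits the
   raw band-passed signal is available behind `fit_normalized=False`).
   Only the 80–95 % stretch of the buffer is fitted: recent enough to be
   predictive, but clear of the Hilbert/filter edge artifacts that corrupt
   the final ~0.5 s. The fit is linear least squares on sin/cos regressors
   at fixed f₀, followed by unit-amplitude renormalization of the phase.
5. **Extrapolation and gating.** Phase advances linearly at f₀; each target
   phase is reached after Δφ/(360·f₀) seconds, where Δφ ∈ (0°, 360°] (a
   zero difference means the *next* cycle). The earliest target wins, ties
   break toward the first-listed (up) target; predictions beyond the 250 ms
   horizon are discarded, trading prediction rate for accuracy. Target
   phases are lead-compensated by 360·f₀·lead so that the middle of a
   0.5 s stimulus (lead 0.25 s) lands on the targeted phase — slower SOs
   thus start playback at a different phase than faster ones.
6. **Scheduling.** On success the algorithm disarms, waits for the
   scheduled sample, emits the trigger, and enters a 10,000-sample
   (~19.5 s) time-out. No analysis happens between decision and emission,
   so the emission-minus-decision latency is bounded by the horizon.

**Degenerate inputs.** An all-zero buffer has an undefined power ratio; a
(near-)zero band-passed signal (judged on the final 10 % of the buffer,
past the causal filter's startup transient, and relative to the input
scale) has undefined phase; a fit window shorter than *half* an SO cycle is
rejected as ill-conditioned. The half-cycle bound is deliberate: the
default window (~1.46 s) is already shorter than one full cycle at the
0.6 Hz end of the search band, yet phase fitting at known frequency remains
well-posed there; only below about half a cycle do the sin/cos regressors
become degenerate.

**Accuracy expectations.** The dominant systematic error is frequency
quantization: a bin error Δf displaces the extrapolated phase by
360·Δf·Δt over the ~1–1.9 s between the fit-window center and the scored
stimulus middle, i.e. up to ~25–35°. Up-target accuracy on defaults is
typically 10–15° mean deviation. Down-target accuracy is systematically
worse when SO cycles are asymmetric: a pure sine fitted to a waveform with
sharp troughs and round peaks locks onto the peaks and misplaces the
troughs. The test suite reproduces this degradation by raising the
generator's `trough_sharpening`.

## Offline validation and circular statistics

Offline phase is extracted with a zero-phase (forward-backward) 2nd-order
Butterworth band-pass at 0.5–1.5 Hz followed by the Hilbert transform and
the same +90° sin-convention shift. Stimulus markers are read 0.250 s after
the trigger (the stimulus middle). Circular statistics follow the standard
toolbox definitions: mean direction and resultant length R by vector
averaging, circular SD = √(−2 ln R), Rayleigh Z = nR² with the
small-sample-corrected p approximation, and the Watson–Williams F with the
1 + 3/(8κ̂) concentration correction, κ̂ estimated from the pooled mean
resultant by the usual piecewise maximum-likelihood approximation (a
warning is raised when concentration or group sizes make the test
assumptions shaky). Circular distance is the minimal absolute angular
difference (≤ 180°). A recording passes inclusion when the up-targeted mean
deviates < 45° from 90°, the up distribution is non-uniform (P < 0.05), and
up and down distributions differ (P < 0.05); down-target accuracy is
intentionally not required on its own.

## Epochs, ERPs and fake events

Epoch windows are half-open, [onset − 1.0 s, onset + 2.5 s), with latencies
relative to event onset; this removes off-by-one ambiguity (1792 samples at
512 Hz). Baseline correction subtracts the per-epoch, per-channel mean over
−750…0 ms. ERPs are computed after zero-phase 4th-order Butterworth
low-pass at 35 Hz and reported with the across-epoch standard error. Events
within 2 s of an arousal interval are excluded.

Fake events isolate stimulus-evoked from spontaneous SO-locked activity:
for each stimulus at phase φ, the *latest* sample in the preceding 3 s
where the phase rises through φ (circular difference crossing zero from
below, within a 2° tolerance) becomes a phase-matched, stimulus-free
control. The latest-match rule keeps the control as physiologically close
to the stimulus as possible; stimuli without a qualifying crossing are
reported unmatched rather than fabricated. Descending-phase matches are not
used — the rising-slope restriction keeps the local waveform context (going
*toward* the same state) comparable.

## Time-frequency decomposition

Complex Morlet kernels e^{i2πtf}·e^{−t²/(2σ²)} are evaluated on
t ∈ [−4σ, 4σ] and L2-normalized; σ = λ/(2πf) with f on a 35-point log grid
over 5–100 Hz and λ on a 35-point log grid over 4–12, paired index-wise.
This pairing gives temporal precision 2σ = 255 ms and spectral precision
1/(πσ) = 2.5 Hz at the 5 Hz end, and 38 ms / 16.7 Hz at 100 Hz. Support
length and normalization are free choices; ±4σ truncates the Gaussian below
3·10⁻⁴ of its peak, and L2 normalization makes expected white-noise power
flat across frequencies (a property the tests check), while the precision
quantities depend only on σ.

Power (squared magnitude) and phase (angle, (−π, π]) are extracted at the
full rate and then decimated to 100 Hz by nearest-sample selection — no
additional anti-alias filtering, since the wavelet's own temporal smoothing
already band-limits the power envelope. dB normalization divides, per
channel and frequency, by the mean power over −200…0 ms across epochs —
per condition by default (up- and down-state pre-stimulus power differ
widely, and a pooled baseline would fold that difference into the
post-stimulus response), pooled across conditions when pre-stimulus
activity is condition-independent (the wake setting). Normalized TFRs carry
a flag and refuse renormalization, since 10·log10 is not idempotent.

## Cluster-based permutation testing

Per-point paired t statistics (paired tests reduce to one-sample tests on
within-subject differences) are thresholded at the two-tailed t critical
value for α = 0.01. Suprathreshold points of common sign form clusters
under grid adjacency (orthogonal neighbors along time and frequency) plus
user-supplied channel neighbor pairs at identical grid coordinates; the
channel neighborhood of a montage is inherently montage-specific, so it is
an input, not a built-in. Cluster mass is the summed t. The null permutes
subjects' condition assignments (sign flips of differences; vectorized,
since sign flips leave per-subject squares unchanged), recording the
extreme positive and negative cluster masses per permutation; each observed
cluster is referred to its own tail's distribution with the (hits+1)/(n+1)
Monte-Carlo correction, and judged significant at p ≤ 0.025 per tail
(0.05 two-sided). When the requested permutation count covers all 2^n sign
patterns, the engine enumerates them exhaustively and the p-values become
exact. Calibration under an i.i.d. Gaussian null (12 subjects, 200
repetitions, 200 permutations) yields a family-wise error rate statistically
compatible with the nominal 0.05; the suite asserts this within the binomial
95 % interval.

Analysis windows of interest are shipped as named presets (sleep: theta
5–10 Hz / 200–800 ms, spindle-beta 11–27 Hz / 700–1200 ms; wake: theta
5–14 Hz / 50–300 ms, alpha 7–15 Hz / 500–800 ms, gamma 55–75 Hz /
750–1100 ms) and scored by inclusive box averaging of dB power.

## The synthetic generator

The generator emulates the signal regime the predictor assumes, not
thalamocortical biophysics:

- **SO**: phase-integrated sinusoid whose base frequency performs a
  reflecting random walk inside 0.6–1.2 Hz, stepped once per cycle with
  SD 0.05 Hz — enough wander to defeat a fixed-frequency shortcut while
  keeping cycles locally sinusoidal. Amplitude 75 (µV scale, frontal SWS
  range).
- **Asymmetry**: a monotone phase warp g(θ) = θ + a(cos θ − 1) with
  a = (ts − 1)/(ts + 1); the phase velocity ratio trough/peak equals the
  `trough_sharpening` parameter ts (default 1.3, mildly sharper troughs;
  ts = 1 recovers a pure FM sinusoid). Ground-truth phase is the warped
  phase, so 90° sits exactly on waveform peaks, and the stored
  instantaneous frequency is its exact derivative/360.
- **Background**: Gaussian noise spectrally shaped to 1/f^α (α = 1),
  flattened below 0.3 Hz and scaled to 20 RMS — about a 4:1 SO-band to
  broadband power split, comfortably above the 0.6 power criterion outside
  arousals.
- **Spindles**: Gaussian-windowed (σ = 0.15 s) 11–15 Hz bursts, 3/min,
  centered where the SO phase crosses 90° (up-state coupling), amplitude
  10.
- **Arousals**: the SO+spindle component is suppressed to 5 % with 0.5 s
  cosine ramps and broadband noise is elevated, so the power criterion
  correctly rejects these segments.
- **Channels** beyond the first are amplitude-scaled (0.8^k), lag-shifted
  (10 ms/channel) copies plus independent background noise — a crude
  traveling-wave stand-in, deliberately not a realistic topography.
- **Evoked responses**: an additive K-complex-like template (small early
  positivity, sharp negativity at ~550 ms, slow late rebound) can be
  injected at chosen events for testing the ERP/TF/cluster chain against a
  known effect.

All randomness flows from one seed; identical specs give bit-identical
recordings.

**What passing tests show — and don't.** The synthetic benchmark
establishes internal correctness: the predictor hits the phases it claims
under the stated SO model, the statistics match their textbook definitions,
and the analysis chain recovers injected effects. It does not establish
performance on real sleep EEG, where SOs are non-sinusoidal beyond a simple
phase warp, amplitude and frequency fluctuate jointly, artifacts are not
limited to scored arousal intervals, and sleep-stage transitions are
gradual. Accuracy figures quoted from the simulator should be read as upper
bounds on real-data performance.

## Problem sizes in the test suite

The suite replays a single 300 s recording through the predictor (shared
across tests via a session fixture), uses 120–240 s recordings for
generator and asymmetry checks, and calibrates the cluster test with 200
null repetitions of 200 permutations on 20×30 single-channel maps — sizes
chosen so the full suite completes in well under a minute while keeping
every stochastic assertion comfortably powered.
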