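# sophase

Real-time slow-oscillation phase targeting and sleep-EEG analysis.

During deep (slow-wave) sleep the EEG is dominated by ~1 Hz slow
oscillations (SOs): alternations between depolarized *up states* (high
excitability) and hyperpolarized *down states*. Whether a stimulus arrives
in the up or the down state changes how the sleeping brain processes it, so
experiments on sleep perception and sleep learning need to deliver stimuli
at a *chosen SO phase*, repeatedly and in real time. `sophase` implements a
complete toolchain for such experiments, exercisable end-to-end on synthetic
slow-wave-sleep EEG with known ground-truth phase:

- **`sophase.predictor`** — the streaming phase-prediction algorithm. A
  rolling ~10 s buffer is Fourier-analyzed to find the momentary SO
  frequency f₀ (FFT argmax in 0.6–1.2 Hz); the signal is band-pass filtered
  (order-1 Butterworth, 1 Hz bandwidth around f₀) and the Hilbert analytic
  phase φ(t) extracted; a unit sine sin(2πf₀t + φ̂) is least-squares fitted
  to sin φ(t) over the 80–95 % stretch of the buffer and extrapolated into
  the future; a trigger fires at the earliest upcoming occurrence of either
  target phase (90° = up peak, 270° = down trough, lead-compensated for
  stimulus duration) if it lies within a 250 ms horizon. Predictions are
  gated by an SO-band power criterion (≥ 0.6 of total non-DC power), a fit
  quality criterion (MSE ≤ 0.1), and a 10,000-sample post-trigger time-out.
- **`sophase.circular`** — offline validation: zero-phase 0.5–1.5 Hz
  filter–Hilbert phase, circular mean/resultant R, Rayleigh test
  (Z = nR²), Watson–Williams circular ANOVA, and the three-part
  subject-inclusion rule (up-target mean within 45° of 90°, up distribution
  non-uniform at P < 0.05, up vs down distributions different at P < 0.05).
- **`sophase.epochs`** — arousal-margin event exclusion, epoching
  (−1.0…+2.5 s), baseline correction (−750…0 ms), 35 Hz low-passed ERPs,
  and *fake events*: phase-matched control time points found in the 3 s
  before each stimulus, used to subtract spontaneous SO-locked activity.
- **`sophase.timefreq`** — complex Morlet decomposition (35 log-spaced
  frequencies 5–100 Hz, cycles 4–12, σ = λ/(2πf)), power/phase extraction,
  100 Hz decimation, and dB baseline normalization
  (10·log10(power/baseline), −200…0 ms, per-condition or pooled).
- **`sophase.cluster`** — cluster-based permutation tests on time×channel
  and time×frequency×channel maps (per-point α = 0.01, 1000 permutations,
  clusters significant at P ≤ 0.025 two-sided), channel-count heat maps,
  window-of-interest averaging, and one-sample t tests for 2AFC behavior.
- **`sophase.synth`** — the synthetic generator: SO with a reflecting
  random-walk frequency in 0.6–1.2 Hz, sharper troughs than peaks, 1/f
  background, up-state-coupled spindle bursts, arousal segments, injectable
  K-complex-like evoked responses, and per-sample ground-truth phase.
- **`sophase.io` / `sophase.cli`** — EDF and delimited-text signals, TSV
  event/interval tables, flat key=value configs, and the `sophase` umbrella
  command (`simulate | predict | validate | erp | tfr | stats | behavior`).

## Worked example

Generate 300 s of synthetic slow-wave sleep, replay it through the online
predictor, and validate targeting with the offline filter–Hilbert phase:

```python
from sophase import SyntheticSpec, generate_recording, PredictorConfig, run_stream
from sophase.circular import offline_phase, phase_at_events, summarize, inclusion_check
from sophase.predictor import events_to_table

rec, truth, _ = generate_recording(SyntheticSpec(duration_s=300.0, seed=1))
events = run_stream(rec, PredictorConfig())          # 15 triggers
table = events_to_table(events)

phase = offline_phase(rec.channel(0), rec.fs)
angles = {}
for cond in ("up", "down"):
    a, _ = phase_at_events(phase, table[table.condition == cond], rec.fs, 0.250)
    angles[cond] = a
    s = summarize(a)
    print(cond, f"n={s.n} mean={s.mean_deg:.1f} R={s.resultant_R:.3f} "
                f"Z={s.rayleigh_Z:.2f} p={s.rayleigh_p:.4g}")
print(inclusion_check(angles["up"], angles["down"]))
```

prints

```
up n=9 mean=100.3 R=0.640 Z=3.69 p=0.02039
down n=6 mean=284.1 R=0.693 Z=2.88 p=0.04922
InclusionReport(mean_up_deviation_deg=10.35, up_rayleigh_p=0.0204,
                ww_p=0.000216, included=True)
```

The marker offset of 0.250 s scores the phase at the *middle* of a 500 ms
stimulus. Up-targeted triggers land on average 10.3° from the up-state peak
(well inside the 45° criterion), the distribution is significantly
non-uniform, and up- and down-targeted distributions differ — the recording
would be *included*. Down-state targeting is visibly less accurate than
up-state targeting, which the sine-extrapolation approach predicts for
asymmetric SO cycles with sharp troughs.

The same pipeline is available from the shell:

```sh
sophase simulate --seed 1 --duration 300 --out rec
sophase predict  --input rec.edf --out events.tsv
sophase validate --signal rec.edf --events events.tsv --out report.json
```

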