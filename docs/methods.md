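# Methods

This note documents the models, parameters and numerical choices behind
`ecgmaf`, and what the synthetic test bed does and does not establish.

## Signal model and assumptions

The contaminated ECG is modelled additively, s = s_ecg + n_ma: the
motion artefact n_ma adds to, rather than modulates, the cardiac
potential. Two structural assumptions drive the two stages:

1. the artefact may be partially predictable from electrode
   acceleration, but the coupling is weak, sporadic and time-varying;
2. successive P-QRS-T cycles are morphologically similar, while the
   artefact strikes different phases of different cycles — so at any
   fixed cardiac phase the artefact is an outlier with respect to the
   recent cycles.

Stage 1 exploits (1) conservatively; stage 2 exploits (2) and does the
bulk of the artefact removal. Stage 2 necessarily fails when (2) is
violated, i.e. when essentially every cycle is corrupted: the column
medians then follow the noise and there is nothing clean to estimate
from. This failure under sustained contamination is expected behaviour,
reproduced by the acceptance run (removal percentages near zero at
100% corrupted beats versus ~90% at 20%).

## Stage 1: adaptive cancelling

Normalized LMS with the accelerometer signal vector magnitude as the
reference. Per sample k: X_r(k) holds the last n reference samples
(zero-padded before the start), n̂ = g·(Wᵀ X_r), ε = s − n̂, and
W ← W + μ_k ε X_r with μ_k = β/(‖X_r‖² + c). For the plain canceller
(AF) g ≡ 1; for the weighted canceller (WAF) g = |ρ_k| clipped to
[0, 1], where ρ_k is the Pearson correlation between reference and ECG
over a trailing window. The absolute value is deliberate:
anti-correlation is still exploitable correlation for cancellation.
The weight update is driven by the same ε that is emitted, so the
emitted decomposition ε + n̂ = s holds exactly.

Parameters:

| parameter | default | meaning / rationale |
|---|---|---|
| n | 8 taps | short FIR suffices for a low-frequency artefact path at 50 Hz |
| β | 0.05 | adaptation time constant n/β = 160 samples ≈ 3–4 cardiac cycles at 70 bpm, so the canceller adapts across beats instead of chasing morphology (or transients) within one; stable for β ∈ (0, 2) |
| c | 1e-3 | step regularizer for a near-zero reference |
| ρ window | 100 samples (2 s) | long enough for a stable correlation estimate, short enough to track coupling changes |

The normalized-LMS step absorbs the conventional factor 2 of the raw
LMS update into μ so that β ∈ (0, 2) is exactly the stability range;
weight-norm boundedness over that range is property-tested on 1e5
white-noise samples. Zero-variance correlation windows yield ρ = 0 by
convention (no evidence of coupling means no filtering).

## Preprocessing

Zero-phase Butterworth bandpass, order 4, nominal band 0.05–130 Hz with
the upper edge clipped to 0.45·fs (at 50 Hz sampling the band is
0.05–22.5 Hz); an IIR notch at 50/60 Hz that degenerates to a warned
pass-through when the mains frequency is at or above Nyquist (as at
50 Hz sampling); and a one-weight LMS baseline canceller with constant
reference 1 (w ← w + 2μ ε, μ = 0.01), i.e. an adaptive DC/drift tracker
subtracted from the signal. The one-weight recursion is evaluated in
closed form as a first-order IIR filter, so it is exactly the sample
recursion at vector speed.

## Stage 2: segmentation and Hampel estimation

R-peaks come from a Pan–Tompkins chain (5–15 Hz bandpass, centered
five-point derivative, squaring, 150 ms moving-window integration, dual
adaptive thresholds, 200 ms refractory period, RR-based search-back),
with each detection localized to the raw-signal maximum within ±60 ms.
All convolution stages are centered, so no group-delay bookkeeping is
needed.

Per-beat segment length is the preceding RR interval clamped to
physiologic bounds: 0.14 s (300 bpm) to 1.2 s (50 bpm). Segments are
R-centered windows [r − l/2, r + l − l/2). The buffer stores the w most
recent segments **aligned on the R peak** at a common center column,
edge-padded to the rectangular width l_max. R-alignment is essential:
with per-beat lengths varying by a few samples, left-aligned rows would
mix cardiac phases within a column and the filter would "correct"
well-aligned beats toward the majority misalignment (observed as a
morphology shift before this choice was made). Column statistics are
restricted to the span where every stored row holds real samples — the
shortest stored beat around the R column.

Hampel parameters per column: median ∅(i), MAD δ(i) scaled by 1.4826
(consistent σ estimator under Gaussian noise), bounds ∅ ± m·δ with
m = 3 by default — the robust analogue of the three-sigma rule; m is
configurable because a tighter threshold risks clipping pathological
morphology. Even-count medians use the mean of the two middle values.
A constant column has δ = 0, making any deviation an outlier; the
replacement value is then the (constant) median, which is the sensible
degenerate behaviour. Replacement is conditional and idempotent:
replaced values are medians, which lie inside the bounds.

Cold start: until the buffer holds 3 rows, segments pass through
unfiltered. HFBE pushes raw segments into the buffer; RHFBE pushes
filtered segments. The filtered signal is reconstructed by overwriting
each beat's window over the stage-1 signal, later beats winning in
overlaps.

Buffer-depth adaptation: grow by 2 (to w_max = 32) when the median
column IQR exceeds 25% of the buffer's median per-row peak amplitude
or when the KL divergence between histograms (16 bins) of the two most
recent 4 s stretches exceeds 0.1 bits; otherwise decay by 1 toward
w_init = 8. The thresholds were chosen to be inert on stationary clean
ECG and are all exposed in configuration. Growth is OR-gated and
shrinkage AND-gated — the conservative combination.

## Synthetic test bed

The generator emulates a 50 Hz chest-worn recording:

- **Clean ECG**: concatenated P-QRS-T cycles, each a sum of five
  Gaussians at fixed offsets/amplitudes relative to R (P 0.15 at
  −0.20 s, Q −0.10 at −0.05 s, R 1.00, S −0.20 at +0.05 s, T 0.30 at
  +0.25 s) — conventional textbook values giving exact ground-truth
  fiducials, plus a white sensor-noise floor (σ = 0.03 of the R
  amplitude). RR intervals carry fractional Gaussian jitter (3%
  default) and are rounded to whole samples so R-peaks land exactly on
  sample indices.
- **Acceleration**: gravity on z plus activity-dependent sinusoids at
  the step frequency (walk ≈ 1.8 Hz amplitude 2 m/s², run ≈ 2.8 Hz
  amplitude 4 m/s²) with axis-specific phases and sensor noise; rest is
  low-variance noise around gravity.
- **Artefact**: κ times a seeded 5-tap FIR of the mean-removed SVM
  (the reference-correlated component) plus (1 − κ) times
  raised-cosine baseline transients of 0.2–1.0 s, each confined to its
  beat's window so that exactly round(fraction · n_beats) beats are
  corrupted; the sum is scaled to a chosen peak amplitude (default 2×
  the R amplitude). The corrupted-beat mask is the synthetic stand-in
  for expert artefact labelling.

Defaults represent the study conditions: one- to five-minute records,
70 bpm, 20% of beats corrupted at 2× R amplitude, weak
accelerometer-artefact coupling.

What the generator does **not** model: arrhythmia and ectopic beats,
morphology drift over time, electrode-impedance physics, broadband
muscle (EMG) noise, and artefact spectra beyond smooth sub-5 Hz
transients. Passing tests therefore show correctness of the algorithms
under the stated model, not clinical performance on pathological or
heavily exercised recordings.

## Evaluation conventions

- Power ratio: mean-square input power over mean-square output power
  (mean rather than sum so unequal activity durations are comparable).
- Beat matching: greedy one-to-one within ±75 ms, a conventional
  tolerance; sensitivity, positive predictivity and F-measure as
  percentages, zero-denominator cases reported as 0 with a flag.
- Heartbeat rate in beats/min (detections per second × 60), so rate
  errors are on the familiar ±1 bpm scale.
- A beat counts as corrupted when its RMSE to the noiseless template
  over its window exceeds 3× the 95th percentile of the clean-beat
  RMSE distribution (≈ the sensor-noise floor); the artefact-removal
  percentage is 100·(n_before − n_after)/n_before and can be negative
  when a filter corrupts additional beats.

## Problem sizes

The test suite and the acceptance script use 1–5 minute records at
50 Hz (up to ~350 beats per record), 20 seeded runs for stage-1
statistics and 3 seeded 5-minute runs per stage-2 condition, 10⁴
samples for LMS system identification, 10⁵ random histogram pairs for
the divergence properties, and 1,000 random buffers for the exact
brute-force Hampel comparison.

## Known limitations

- At 50 Hz sampling the QRS complex spans only ~2 samples; detection
  localization is exact on the synthetic template but will be coarser
  on real recordings.
- The MHEALTH reader defaults to chest ECG lead 1 (the dataset has
  two); the lead is configurable.
- The 50/60 Hz notch cannot operate at 50 Hz sampling (Nyquist); it
  logs and passes through.
- The segment filter presumes a usable R-peak; when the QRS itself is
  destroyed for many consecutive beats, segmentation and estimation
  degrade together.
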