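# Methods

This note documents the models, numerical choices and limitations behind
`ssvepauth`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model of the synthetic EEG

Each channel c of the generator's output is

    x_c[t] = g_noise,c · ( pink_c[t] + α_c[t] + line_c[t] )
           + g_ssvep,c · ( ssvep[t] + distractors[t] )

with

- **ssvep**: Σ_{h=1..H} A·d^(h−1)·sin(2π·h·f·t/fs + φ_h), harmonic decay
  d ∈ (0, 1] (default 0.55), phases φ_h drawn once per segment and shared
  across channels (the evoked response is spatially coherent up to gain).
  Phases are random rather than locked to a stimulus clock because CCA with
  paired sine/cosine references is phase-invariant.
- **pink**: 1/f^β background (default β = 1), produced by driving the
  truncated-AR approximation of the fractional integrator
  H(z) = (1 − z⁻¹)^(−β/2) (128 taps) with per-channel white noise through a
  stateful IIR filter. The filter state is carried across blocks, so
  streaming 30-sample blocks and synthesizing one long segment give
  bit-identical samples — the property the streaming decision engine's
  reproducibility rests on. An FFT-shaping generator would not compose
  across chunks and was rejected for that reason.
- **α**: a sinusoid at 10 Hz (amplitude default 4, per-channel random
  phase), standing in for the endogenous alpha rhythm that motivates
  keeping stimulation frequencies away from 10–15 Hz.
- **line**: 50 Hz interference (default amplitude 1, per-channel phase).
- **distractors**: optional sinusoids at the two non-target frequencies of
  the active set, default amplitude 0. The real stimulus keeps the
  non-target boxes flickering, but their leakage into occipital EEG under
  fixation is not quantified anywhere we could anchor to, so pure fixation
  is the default and the leakage is a config switch.

**SNR definition and calibration.** `snr_db` is the power of the SSVEP
fundamental (A²/2) over the expected pink-noise power in a ±1 Hz band
around the fundamental. The narrowband definition matches what FBCCA is
sensitive to. A is computed analytically from the AR filter's transfer
function integrated over the band — not from the realized noise — because
an open-ended stream's realized power is unknowable when the amplitude
must be fixed. The property suite checks the realized SNR of a 120 s
segment lands within ±1 dB of the target. Alpha and line components are
deliberately excluded from the SNR denominator: they are structured
interferers, not background noise.

Units are nominal microvolts; all amplitudes are relative, and nothing in
the pipeline depends on the absolute scale (CCA is scale-invariant).

## Filtering

All filters are Butterworth designs in second-order sections: front end =
band-stop 48–52 Hz then band-pass 2–60 Hz (order 4, fs 600 Hz), sub-bands
2–60 / 12–60 / 20–60 Hz (low set) and 35–60 Hz (high set). Application is
zero-phase forward–backward (`sosfiltfilt`) with a fixed 27-sample even
reflective pad — fixed, rather than scipy's shape-dependent default, so a
given buffer filters identically everywhere. Zero-phase filtering is
possible because the engine re-filters the whole buffer snapshot at every
evaluation; a causal mode exists behind a flag for strictly streaming use.
Buffers must exceed the pad length; the 300-sample minimum window always
does. The front end applies notch before band-pass; for LTI filters the
order is irrelevant, it is fixed only for reproducibility.

The filter-bank size is wholly configuration-driven (3 + 1 bands as
shipped); nothing hard-codes a band count.

## FBCCA numerics

The first canonical correlation is computed by orthogonal decomposition:
row-center both sets, take thin SVDs, and the largest singular value of
U_xᵀU_y is ρ. Singular values below 1e−10 of the largest are truncated,
and constant rows raise a degenerate-input error, so near-rank-deficient
buffers fail loudly instead of returning a spurious ρ = 1. The test suite
pins this implementation against an explicit covariance-block
generalized-eigenvalue oracle to 1e−8.

Reference bases are cached per (frequency, H, fs, length); each sub-band's
buffer basis is computed once per evaluation and reused across the three
candidate frequencies.

**Fusion scale.** Combined scores default to the weighted sum of *raw*
correlations (not squared), matching the system description this package
follows; the squared variant of the wider FBCCA literature is available as
`combine_squared=True`. The margin threshold's 0.2–0.5 calibration range
is meaningful on the raw scale. With a single sub-band the weight is 1, so
low- and high-set margins are directly comparable.

**Ties** in `select_target` break toward the lower frequency-list index,
deterministically.

## Decision engine

Evaluation happens exactly once per ingested 30-sample block (20 Hz), on
the block grid rather than a wall clock, making offline replays
bit-reproducible. The 0.5 s gaze-shift window after a decision consumes
and discards incoming blocks — the stimulus keeps flickering while the
user re-fixates, so acquisition does not pause. The same single 0.5 s
window also stands in for the feedback-display interval between digits,
whose real duration is not specified anywhere authoritative; completion
times therefore include 7 × 0.5 s of inter-digit pauses. There is no
per-digit timeout by default (real trials can run for hundreds of
seconds); an opt-in guard exists.

After an incorrect decision the *session* advances to the next digit; the
engine itself only ever reports what it decided.

## Calibration

A greedy search mirroring the operator procedure: sweep thresholds
0.20–0.50 in 0.05 steps at the current minimum window; if none reaches the
target accuracy on the calibration digits, extend the window by 30 samples
and repeat; stop at 100% or budget exhaustion and return the best setting
found. The number of calibration digits (9) and the step sizes are
documented assumptions exposed in `CalibConfig`. Cohort runs use the fixed
defaults (0.30 / 300) rather than per-subject calibration; the sampled
population is strong enough that calibration mostly returns them, and
keeping the engine fixed makes cohort comparisons cleaner.

## In-silico cohort

21 subjects, each drawn deterministically from a master seed: narrowband
SNR uniform in −2…+6 dB, per-channel SSVEP gains 0.7–1.3, noise gains
0.8–1.2, harmonic decay 0.4–0.7, alpha amplitude 2–6, line amplitude
0.5–2. These ranges are chosen to produce the qualitative regime reported
for such systems — high accuracy, single-electrode conditions slower and
more variable — while spanning from occasional errors to ceiling; no
measured SNR distribution exists to anchor them, so the cohort's absolute
accuracies and times are properties of the simulator, not reproductions of
human data. The per-subject table of the original 21-participant study
ships as `data/reference_cohort.csv`, and its per-condition means are the
arithmetic the acceptance checks reproduce; its printed SDs are *not*
reproducible from the per-subject values (they appear to have been
computed across trials rather than subjects), so only means are asserted.
Counterbalancing (odd subjects start high-frequency) is recorded as
metadata; the simulator has no fatigue model, so order cannot affect
results.

Statistical summaries use the sample SD (n−1) and Student-t 95% CIs across
subjects.

## Problem sizes

The shipped defaults run the full cohort (21 × 4 × 4 × 8 digits) in a few
minutes on one CPU. Stochastic property checks use 300 digits for the
chance-level control and 24 seeded digits per SNR level (−9…+3 dB, the
range over which accuracy climbs from near-chance to ceiling) for the
monotonicity check, with common random numbers across levels to sharpen
the comparison.

## Known limitations

- The generator is a phenomenological forward model, not biophysics: no
  volume conduction, blinks, EMG, non-stationarity, or inter-digit
  transient dynamics. Passing tests show the decoding chain is correct and
  well-behaved under the assumed signal structure, not that it would reach
  any particular accuracy on human EEG.
- Class selection at chance is not exactly uniform: measured over 2,000
  noise-only digits, the low set selects its three classes at roughly
  0.375/0.350/0.275 under 1/f noise (the lowest frequency's harmonics sit
  where pink noise has most power), and the high set is more skewed
  (≈0.21/0.46/0.33) because 36 Hz sits on the 35 Hz sub-band edge and the
  45 Hz reference spans a non-integer number of cycles in a 300-sample
  window. This is a structural property of the published filter layout and
  frequency placement, not of the decision logic; the 300-digit chance
  control on the low set sits within the 99% binomial band of uniform.
- EDF interchange is not implemented (no writer available in the
  dependency set); EEG I/O is CSV + JSON sidecar.
- Security properties of the authentication scheme (spoofing resistance,
  replay) are out of scope; this package is about the signal path.
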