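# Methods

This note records the modelling conventions, defaults and numerical
choices behind `kalnirs`, and what the synthetic validation study
does and does not establish.

## Hemodynamic kernel and state-space realization

The impulse response is `h(t) = C (t − δ)² exp(−(t − δ)/τ)` for
`t ≥ δ` and zero before: a triple real pole at `−1/τ` behind a pure
transport delay.  Its maximum is at `t = δ + 2τ`; with the default
δ = 2 s, τ = 1.5 s that is 5 s, the usual time-to-peak of prefrontal
HbO2 responses to a brief stimulus.  An alternative convention with
poles at `−τ` would peak at `δ + 2/τ ≈ 3.3 s`, inconsistent with that
physiology, which is why the `−1/τ` placement is used.

No physical gain is identifiable from concentration units alone, so
the kernel is normalized to unit DC gain on the *sample grid*: the
samples `h(k/fs)` are scaled so that `Σ_k h(k/fs) / fs = 1` exactly
(closed-form geometric sums; the constant differs from the analytic
continuous-area normalization `1/(2τ³)` by ~5e−5 at 2 Hz and
converges to it as fs grows).  A sustained unit stimulus therefore
settles at exactly 1, making response amplitudes comparable across
(δ, τ) and sampling rates.

The discrete realization is built directly in the z-domain: the
shifted sequence `(kT + o)² a^k` (with `a = e^{−T/τ}` and `o` the
sub-sample residual of the rounded delay) is a linear combination of
`a^k`, `k a^k`, `k² a^k`, each with a known rational z-transform over
`(z − a)³`, so the 3-state core reproduces the sampled kernel
*exactly* (machine precision), not just to discretization order.  The
whole-sample part of the delay is applied to the known stimulus
input rather than adding shift-register states; this commutes with
the linear dynamics and keeps the estimated state at dimension 3.
When `δ·fs` is not an integer the residual appears as a small direct
feedthrough term; with the defaults (δ = 2 s at 2 Hz) it is zero.

## Kalman filters

State noise `w` (variance Q) models a stimulus-perception bias at the
model input; measurement noise `v` (variance R) sits on the recorded
series.  Two structures:

* nominal — `b = w`, zero-mean white: `x⁺ = A x + B(u + w)`;
* augmented — `b` follows a random walk `b(k+1) = b(k) + w(k)` (the
  discrete counterpart of `ḃ = w`) and joins the state vector, so a
  non-zero sustained bias is estimated rather than assumed away.  The
  integrator also absorbs slow baseline drift.

Only Q/R is identified by the gain, so R ≡ 1 and Q carries the ratio.
The steady-state prior covariance solves the Riccati fixed point by
plain iteration (absolute tolerance 1e−12 on the covariance, cap 1e6
iterations; in practice < 100 iterations at 2 Hz).  A time-invariant
gain is used deliberately: it admits a frequency response, runs in
constant memory per sample (real-time use), and removes dependence on
an arbitrary prior — the filter is initialized at zero state with the
steady-state covariance, so the textbook time-varying recursion
started there coincides with it identically.  The filtered signal is
the output map applied to the *posterior* state estimate.  The
stimulus input is a unit-height boxcar spanning each presentation
(onset to onset + duration; impulse encoding available), shifted by
the whole-sample delay.

Interpreting Q/R: with the unit-DC kernel the augmented filter's
measurement path is essentially all-pass below ~0.1 Hz for
Q/R ≳ 0.3 and narrows toward a model-trusting low-pass as Q/R falls
(at 0.05 the Mayer-wave band near 0.1 Hz is already attenuated by
~6 dB while the trial-response band below 0.03 Hz passes almost
unchanged).  Because the Q/R ↔ bandwidth mapping depends on the
kernel gain convention, numeric Q/R values are not portable across
implementations with different conventions — the sweep, not the
number, is the specification.  Relatedly, the nominal filter at
Q/R = 3.98 and the augmented at Q/R = 0.50 behave as comparable
smoothers but are not 6-dB-identical here: only the augmented
structure carries an integrator, so its DC gain is exactly 1 while
the nominal filter's is ~0.58, and the magnitude curves differ by up
to ~7.4 dB at Nyquist.  The packaged "similar Bode" check therefore
asserts < 8 dB maximum difference plus > 0.95 magnitude-curve
correlation over 0.01–0.5 Hz.

Baselines: MACD = EMA(4 s) − EMA(40 s), both causal and seeded at the
first sample (spans chosen to put the difference band over the
0.02–0.1 Hz hemodynamic range; the spans are configurable); IIR =
3rd-order Butterworth band-pass 0.02–0.1 Hz applied causally
(zero-phase refiltering available but off by default, since causal
operation is the point of the comparison).

## Features and statistics

ΔHbO2 is the extremum of the filtered series in the half-open window
(onset, onset + 30 s] minus the value at the first sample at/after
onset; ΔHHb uses the same max-based rule by default (a min-based mode
exists for the typically negative HHb deflection).  The ESI over K
ordered load levels sums the K−1 consecutive gaps
`(μ_upper − σ_upper) − (μ_lower + σ_lower)`; μ and σ are taken across
subjects of per-subject mean features (sample SD, ddof 1), with a
pooled-trials mode for single-subject use.  Partial η² =
SS_effect / (SS_effect + SS_error).  The repeated-measures design
decomposes subject × level cell means within subject (error stratum =
subject-by-level interaction; no sphericity correction); the two-way
design fits optode × level with interaction on trial-level data by
OLS.  The contrast t-map is a per-optode paired t across subjects of
per-subject mean high-minus-low ΔHbO2, thresholded at a fixed
two-sided α = 0.01 (configurable; no formal multiplicity correction,
matching the fixed-α convention for 16-optode maps).

Classification: per subject, 10 stratified folds (stratification
avoids class-empty folds that plain random splits can produce), a
linear SVM with C = 1, features standardized with training-fold
statistics only; accuracy/sensitivity/specificity from the pooled
out-of-fold confusion matrix, then averaged across subjects.  Filter
comparisons use paired t-tests across subjects with Holm correction.

## Q/R sweep

41 log-spaced points across 1e−5..1e5 by default (the bounds are the
tuning range; density is a package choice).  Selection is automated
argmax of ESI — ties to the smaller ratio — but the full score table
is exported so the traditional by-eye selection remains possible.
The chosen configuration is serialized and reusable on new data
without re-optimization, mirroring the calibrate-once / transfer
workflow.  On the digit-span protocol the optimum gravitates to very
low Q/R: presentation length grows with digit count (one digit per
second), so even the pure model prediction separates levels, and
trusting it shrinks variance.  On the equal-duration flight-task
protocol the level information is carried entirely by the measured
amplitudes, and the same transferred filter still wins by virtue of
its better-matched passband.

## Synthetic experiments

Two protocols at 2 Hz over 16 optodes:

* memorization — 27 trials (9 per digit span 5/7/9), stimulus length
  = one second per digit, 8 s response window, 6–9 s uniform ITI;
* atc (flight task) — 40 trials (20 low / 20 high), 6 s message for
  both levels, 18 s response window, 11–13 s rest.  Equal stimulus
  durations are deliberate: message difficulty is content, not
  length, and a duration difference would confound the null
  condition.

Each trial adds a β-scaled, optode-gain-scaled kernel response to the
HbO2 channels (β defaults 0.4/0.7/1.0 and 0.5/1.0; lateral optodes
1–4 and 13–16 at gain 1.0, medial at 0.5).  HHb = −0.3 × the response
delayed one sample, with noise scaled by 0.3.  Noise per channel:
white measurement noise (SD 1.0), random-walk drift (step SD 0.01),
and sinusoids at 0.1 Hz (amplitude 0.2, Mayer-wave-like) and 0.25 Hz
(amplitude 0.1, respiratory-like) with random phases; optional motion
spikes, off by default.  Cardiac content is omitted: a ~1 Hz pulse is
at/above the 1 Hz Nyquist at this rate (an aliased-cardiac option
exists for robustness testing).  The white-noise default was
calibrated so the simulated study sits in the empirically realistic
discriminability regime — tuned-Kalman classification accuracy in the
~0.70–0.78 range rather than saturating near 1.0 — because a
saturated study cannot rank filters.  All draws derive from one
integer seed (per-subject seeds spawned from it), and the generator
returns the exact ground truth (per-trial amplitudes, noise-free
signals, stimulus train).

What the simulator does not emulate: superficial/systemic physiology
shared across optodes, motion-artifact morphology, optical forward
modelling or Beer–Lambert conversion, between-subject amplitude
differences, non-stationary noise.  Passing the ordering study
therefore shows the pipeline behaves correctly under the stated
generative assumptions — model-matched responses plus stationary
additive noise — not that the same margins would be observed on any
particular human dataset.

## Validation study design

The packaged study follows the two-experiment workflow: Q/R is tuned
once by the ESI sweep on a 9-subject memorization calibration set
(fixed seed), and the selected configuration — empirically the
augmented structure at low Q/R — is applied unchanged to 18-subject
flight-task datasets across 10 evaluation seeds.  With the load
effect on, the tuned Kalman filter must match or beat MACD and IIR on
pooled partial η² and on mean accuracy in ≥ 8/10 seeds; with flat
amplitudes, every filter's mean accuracy must sit within 0.07 of
chance.  Problem sizes (9 + 18 subjects, 21-point tuning grid, 10
seeds) keep the full suite at a few minutes on one CPU while leaving
the per-seed checks well powered.

## Numerical details and edge cases

* Riccati iteration failure raises, naming structure and Q/R; failed
  sweep points are recorded and skipped.
* Zero-variance paired contrasts (identical conditions) return t = 0,
  p = 1 (or ±∞, 0 for a non-zero constant difference) instead of NaN.
* The null-calibration check on recovered amplitudes uses the exact
  95% paired t-interval (t₀.₉₇₅,₁₇ ≈ 2.11 SE) rather than the rough
  2·SE bound, whose nominal coverage at n = 18 is only 93.8%.
* Recording CSVs serialize with shortest-repr floats, so write→read
  round-trips are bit-exact; readers report the first offending line
  for non-uniform time bases and non-numeric cells.
* Events with onsets whose 30 s feature window overruns the record
  are dropped with a warning; overlapping windows are permitted.

## Known limitations

The steady-state (LTI) Kalman formulation cannot exploit stimulus
synchrony beyond its feed-forward term, so on equal-duration designs
its advantage over MACD reduces to passband shaping; a time-varying
or adaptive-gain filter could do better and is out of scope.  ESI
with two subjects is defined but fragile (sample SD over two means).
No per-subject Q/R optimization, no stimulus-onset detection, no
nonlinear hemodynamics (balloon-type models), no SNIRF ingestion
(the CSV dialect is the interchange format; SNIRF is a documented
extension point).
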