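# Methods

## Signal model and preprocessing

The pipeline treats neurovascular coupling (NVC) as shared slow modulation
between two observables recorded in parallel over many hours: the amplitude
envelope of cortical electrical activity (aEEG, derived from a bipolar
C3–C4 EEG at 256 Hz) and cerebral tissue oxygen saturation (SctO₂, percent,
sampled by the oximeter at 0.21 Hz or 0.03 Hz). Analyses are restricted to
the first 20 h of recording by default (`PipelineConfig.analysis_hours`).

EEG → aEEG chain, in order:

1. **Band-pass 2–15 Hz.** Equiripple linear-phase FIR (Parks–McClellan via
   `scipy.signal.remez`), stopband edges 1 and 20 Hz, 60 dB target. The
   exchange algorithm loses convergence just above the necessary order for
   these narrow transitions, so the design routine estimates the order
   (Herrmann formula), probes downward, and keeps the best design whose
   passband gain is within 5 % and stopband attenuation ≥ 20 dB (achieved:
   ≥ 55 dB at 1 and 20 Hz for fs between 42 and 256 Hz). Filtering is
   zero-phase: the symmetric FIR is applied by FFT convolution and the
   group delay removed.
2. **Envelope.** Full-wave rectification followed by a 0.5-s moving
   average. This is an envelope approximation in the spirit of clinical
   aEEG processing; the exact clinical display compression (semilogarithmic
   amplitude mapping) is *not* applied, because the percentile reduction in
   the next step dominates the result and the downstream coherence is
   invariant to monotone rescaling only approximately — this is a known
   approximation, not a reproduction of any specific toolbox.
3. **Percentile downsampling.** One value per oximeter sampling interval:
   P90 − P10 of envelope samples in non-overlapping, left-aligned windows
   (timestamps at window centers; linear interpolation between order
   statistics). Output length is floor(duration × oximeter rate).
4. **Artifact replacement.** aEEG values > 25 µV, then values deviating
   more than ±5 µV from the least-squares linear trend (fitted on all
   samples, outliers included), are replaced by the nearest *preceding*
   valid value (a leading invalid run takes the first valid value).
   Carry-forward was chosen over interpolation because it is deterministic
   and causal; replacement indices are logged. An all-invalid series is an
   error.
5. **Detrending.** Second-order polynomial least-squares removal.

SctO₂ receives steps 4–5 with the relative rule (±20 % of the linear trend
value — "of trend", not of full-scale range) and the same detrending.

## Wavelet transform coherence

The continuous wavelet transform uses the analytic Morlet wavelet with
center frequency ω₀ = 6 (the conventional default; Fourier period
≈ 1.033 × scale), implemented by FFT convolution with zero-padding to the
next power of two and L2 frequency-domain normalization. Periods lie on a
log-uniform grid at 12 voices per octave (consecutive ratio exactly
2^(1/12)), from 2·dt (or the configured lower limit, 1 min by default when
resolvable) to min(400 min, half the record).

Coherence:

    R² = |S(W_xy / s)|² / ( S(|W_x|² / s) · S(|W_y|² / s) )

The 1/s weighting and the two-stage smoothing S follow the standard
Torrence–Webster construction: per-scale Gaussian smoothing in time with
standard deviation equal to the scale (implemented by FFT convolution with
an edge-renormalized truncated kernel) and a boxcar over 12 voices (one
octave) along the scale axis, also edge-renormalized so constants pass
through unchanged. Values may exceed 1 by at most 1e−6 (then clipped);
larger overshoots raise. Pixels where both signals have zero local power
get R² = 0 with a logged warning. Without smoothing the normalization
cancels exactly and R² ≡ 1; a test asserts this degeneracy as a
correctness check of the normalization.

The cone of influence (COI) is the e-folding boundary of the Morlet
envelope: at distance τ from the nearer record edge, periods above
1.033·τ/√2 are boundary-contaminated. COI pixels are *included* in all
statistics; each significant cluster reports the fraction of its pixels
inside the COI for interpretation.

Maps from subjects with different oximeter rates are brought onto a common
cohort grid by bilinear interpolation in (time, log-period). Extrapolation
is forbidden; periods a coarsely sampled subject cannot resolve are marked
missing (NaN) and excluded pixel-wise downstream (a pixel enters the group
t-map only with ≥ 2 covering subjects per group).

## Cluster-based permutation inference

Pixelwise independent-samples t (pooled variance, df = nA + nB − 2); the
cluster-forming threshold is the one-tailed p < 0.05 quantile of t. Supra-
threshold pixels form clusters under 4-connectivity (time- or scale-
adjacent; conservative and standard for time-frequency maps), scored by
summed t. The null is the distribution of the *maximum* cluster mass over
random relabelings of subjects with group sizes preserved (default 1000;
seeded, deterministic), and per-cluster p = (1 + k)/(1 + N) so p is never
0 and is floored at 1/(N + 1). The primary tail is "group A > group B"
(non-cooled above cooled); a two-sided display map (probit-transformed t,
a z-statistic) is produced regardless. The period extent of the largest
significant cluster — and, as an alternative reading, the union envelope
of all significant clusters — defines the coupling band, reported in
minutes and mHz (f = 1000/(60·period)).

## Trajectory statistics

Per subject, the band-mean R² at each time column gives an NVC trajectory.
Observations are thinned to an hourly grid (nearest map column per whole
hour of recording time; recording time, not time of life, is the model's
clock). The linear mixed-effects model is

    nvc ~ group + time + group:time,  random intercept per subject (REML)

with group coded reference = A (non-cooled), indicator = 1 for B, so a
negative group coefficient means lower coupling in the cooled group.
Random intercepts only — a sensitivity hook for random slopes is not
fitted by default. Marginal between-group contrasts at hours 0–6 are the
linear identity `β_group + h·β_interaction` with variance from the
coefficient covariance; raw Wald p-values are Bonferroni-multiplied by the
number of evaluation points (7). A one-tailed pooled-variance two-sample
t-test compares per-subject means over the 0–6 h recording window (the
window is configurable; 0–6 h is the clinically decisive span). Residual
skewness/kurtosis and a Shapiro p on a subsample are reported as
normality diagnostics; no robust alternative is fitted.

## Synthetic cohorts

`nvcoh.simulate` generates the ground-truth test bed:

- **Modulator** m(t): Gaussian white noise brick-wall filtered to the
  coupling period band (default 25–60 min), standardized. Band-limited
  noise rather than a drifting oscillator, so cluster recovery is probed
  across the whole band, not at one period. With ~14–28 independent
  spectral bins in a 10–20 h record, independent modulators still show
  single-pair sample correlations up to ~0.4; the mean over many pairs is
  ~0.13.
- **EEG**: unit-RMS 2–15 Hz noise carrier × (1 + 0.5·κ·m(t)), scaled to
  15 µV RMS (envelope in the 10–50 µV regime). κ ∈ [0, 1] is the group's
  coupling strength. Neonatal EEG morphology (tracé alternant, seizures)
  is deliberately not modelled; envelope-level coupling is what the
  method measures.
- **SctO₂**: 70 % baseline + 3 %·κ·m(t − lag) + AR(1) noise (coefficient
  0.8, stationary sd 2 %), clipped to the oximeter's working range
  [15, 95] % — a floor/ceiling nonlinearity the pipeline must tolerate.
  The default lag is 0 s (the coherence magnitude ignores phase);
  configurable.
- **Artifacts**: Poisson-timed events adding a one-oximeter-interval
  high-amplitude EEG burst (pushing the downsampled aEEG above 25 µV) and
  an SctO₂ step exceeding 20 % of the local trend; ground-truth times are
  recorded.
- **Seeds**: one master seed; per-subject generators derive from the
  entropy tuple (master, group code, subject index), so cohorts are
  bit-reproducible and subjects independent.

What passing tests on this generator do *not* show: robustness to real
neonatal EEG state changes, oximeter dropouts longer than the artifact
model, hemodynamic transfer-function dynamics (the simulated coupling is
instantaneous and linear), or inter-subject variability beyond independent
noise draws.

## Numerical and design choices

- Percentile windows with a non-integer sample ratio (256/0.21 Hz) use
  per-window index boundaries floor(k·fs_in/fs_out), giving windows of two
  lengths batched for speed; results equal the per-window oracle exactly.
- Quadratic detrending leaks a sinusoid into the polynomial basis at
  ~0.95/cycles of its amplitude; at the coupling band's ≥ 20 cycles per
  record this is ≤ 5 % and spectrally far from the band.
- The t-map sets t = 0 (with a warning) at zero-pooled-variance pixels.
- The z display map clips the t CDF away from {0, 1} to keep the probit
  finite.
- Determinism: every stochastic step (simulation, permutations) takes an
  explicit seed; identical config + seed reproduces byte-identical
  numbers.
- EDF is written by a minimal built-in encoder (1-s records, int16,
  per-channel symmetric physical range) and read through MNE; round-trip
  error is bounded by the quantization step.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own desk-scale defaults: unit and property tests
use 2.5–12 h records with a 42–64 Hz EEG carrier (the coupling structure
is invariant to carrier rate once the 2–15 Hz band is resolvable);
statistical calibration runs 100 global-null cohorts at n = 8 + 8 with 200
permutations on a reduced grid; recovery runs 10 cohorts at n = 10 + 10,
12 h; mixed-model recovery runs 100 cohorts at the clinical group sizes
(29 + 28) with 20 hourly points. `scripts/acceptance.py` analyzes one
29 + 28 cohort, 12 h at 64 Hz, 200 permutations.

## Known limitations

- The aEEG envelope stage approximates clinical aEEG (no semilogarithmic
  compression); absolute coherence levels may differ from chains that
  compress first, though band-level contrasts are robust in simulation.
- Coherence leaks across scales by roughly the wavelet bandwidth: a
  coupling difference confined to 25–60 min yields significant clusters
  extending somewhat beyond that band (visible in the worked example).
- The LME's independence-of-residuals assumption is optimistic for
  band-mean coherence series, which are smooth in time; hourly thinning
  mitigates but does not remove autocorrelation.
- 0.03-Hz subjects cannot resolve periods below ~67 min; their maps enter
  the common grid with missing short-period rows, thinning coverage
  exactly where the 25–60 min band lives.
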