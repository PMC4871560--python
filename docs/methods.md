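# Methods

`pupilfir` analyses pupil-size recordings from equiluminant cognitive
experiments: the screen luminance never changes, so pupil fluctuations
are driven by cognitive events (here, auditory tones), by ocular events
(blinks and microsaccades, which transiently change effective retinal
illumination), and by slow arousal-linked drift. The toolkit separates
these contributions and characterises each one parametrically.

## Signal model

The recorded pupil size is modelled as

    y(t) = sum_e  a_e * k_{type(e)}(t - t_e)  +  tonic(t)  +  noise(t)

where the sum runs over all events `e` (two sound types, blinks,
saccades), `k_c` is the impulse response ("kernel") of event type `c`,
`a_e` a per-event amplitude, and `tonic(t)` a slow baseline drift.
Blinks anchor their kernel at the blink **offset** (the reopening of
the eye, when the retinal-illumination transient occurs); saccade
event times are tracker-reported offsets already.

## Preprocessing

1. **Blink interpolation.** Samples from 150 ms before blink onset to
   150 ms after blink offset are replaced by the straight line joining
   the nearest valid neighbours; touching windows are merged, windows
   clipped by a recording edge hold the nearest valid value, and any
   residual short dropout is repaired the same way with zero padding.
2. **Band-pass** 0.02–4 Hz (third-order Butterworth) yields the phasic
   signal; **low-pass** below 0.02 Hz yields the tonic signal. All
   filtering is zero-phase (forward–backward second-order sections), so
   kernel timing carries no filter lag. The band edges are fixed by the
   standard recipe: 4 Hz because the pupil itself low-passes its
   inputs, 0.02 Hz to split drift from event-locked responses.
3. **Normalization:** each condition segment is demeaned and divided by
   one standard deviation per session (computed on the session's
   concatenated band-passed signal) so amplitudes are comparable across
   conditions; output is in z-units.
4. **Resampling** to 10 Hz by averaging non-overlapping blocks; output
   timestamps sit at block centres. Non-integer rate ratios fall back
   to linear interpolation.

## FIR deconvolution

Event-locked responses are estimated as free per-lag coefficients over
a window of −0.5 to 5 s around each event (55 lags at 10 Hz; 220
columns for four event types). The design matrix holds staggered
indicator columns — entry (i, (c, j)) counts the type-`c` events whose
time plus lag `j` rounds to sample `i` — and the ordinary least-squares
solution `h = (XᵀX)⁻¹Xᵀy` estimates all kernels jointly, unmixing
overlapping responses. `numpy.linalg.lstsq` supplies the minimum-norm
solution when the design is rank-deficient (a warning is emitted above
condition number 1e10). Estimated kernels are low-passed at 4 Hz
(zero-phase, order 3) and baselined by subtracting their mean over the
−0.5–0 s window.

Two deliberate conventions:

* **Event counting.** Two events of one type landing in the same 10 Hz
  bin increment the indicator to 2. With Poisson saccades at 0.8 Hz
  this happens several times per run, and a 0/1 indicator would
  underfit those samples by one full kernel.
* **Drift nuisance basis.** For analyses that skip the band-pass (e.g.
  recovery studies on synthetic data in physical z-units), slow drift
  is estimated jointly with the kernels through an intercept-plus-DCT
  cosine basis per run (default cutoff 0.08 Hz). A zero-phase high-pass
  instead imprints a shallow undershoot around every response that
  survives baseline subtraction and biases kernel estimates by a few
  hundredths of a z-unit; joint estimation does not. The 0.08 Hz
  cutoff spans a drift with a time constant of tens of seconds while
  staying well below the response band (~0.2–1 Hz).

**Variance partition.** The contribution of event type `c` is the
variance of its fitted component `X_c h_c`, normalised by the sum over
types. Cross-covariance terms between types are excluded so fractions
are non-negative and sum to one; total R² of the fit is reported
separately.

## Kernel models

* Gamma form: `gain · x^(k−1) e^(−x/θ) / (θ^k Γ(k))` — the gain scales
  the *normalised* density and therefore equals the signed response
  area. Under this reading the two canonical parameterizations agree:
  the blink-negative peak is ≈ −0.77 z in both, and the gamma mode
  (k−1)·θ = 0.844 s reproduces the Erlang time-to-peak printed for the
  same component.
* Erlang form: `s · x^n e^(−n·x/x_max)`, parameterized by its peak time
  `x_max` directly.
* The biphasic blink response is a double gamma (negative then positive
  component, with the negative mode constrained to precede the
  positive one).

Canonical parameter sets for the auditory, blink (two components) and
saccade responses ship with the package (`canonical_kernels`), in both
parameterizations.

**Fitting** uses `scipy.optimize.least_squares` on non-negative lags
with a fixed set of deterministic moment-based starting points (peak
position sets θ via the mode relation; the trapezoidal area seeds the
gain; four shape values 2/5/8/15 seed k), so fits are bit-for-bit
reproducible. Double-gamma fits run extra starts seeded from the
canonical blink components, with sign and mode-ordering constraints;
starts whose solution violates the ordering are discarded. All-zero
input short-circuits to a zero-gain fit flagged degenerate.

**Nuisance cleaning** builds one regressor per ocular event type by
convolving the event impulse train with the corresponding canonical
(or fitted) kernel truncated at 6 s — beyond which the canonical curves
are under 1% of peak — adds an intercept, solves OLS, and returns the
residual signal plus the fitted amplitudes. A coefficient of 1 means
the recording expresses the canonical amplitude.

**Tonic decay** is fitted as `A·e^(−t/τ) + C`, initialised from
first/last-segment means and a log-linear slope. Because the tonic
signal comes from a 0.02 Hz zero-phase filter whose edge transients
span tens of seconds, fits can trim a caller-chosen margin (10 s in
the bundled workflows) from both ends; per-run tonic traces also carry
low-passed event-stream fluctuations, so precise τ estimates come from
fitting the across-run average trace (or the median of many per-run
fits), not a single run.

## Statistics

**Cluster-based permutation tests** control family-wise error across
kernel lags: per-lag t statistics (one-sample against zero, or on
paired differences) are thresholded at the two-sided t critical value
for p < 0.05 with n−1 degrees of freedom; contiguous suprathreshold
lags form clusters with mass = summed t; the null distribution of the
maximum |mass| comes from sign-flip permutations (default 1000, seeded,
reproducible); `p = (1 + #{null ≥ observed}) / (1 + n_perm)`. Cluster
threshold and permutation count are package defaults — standard for
the method but not dictated by any external source. A small-variance
guard (1e-12) keeps zero-variance lags finite.

**Tonic median split.** Tonic level at each event is the mean of the
low-passed signal over −0.5–0 s before the event, z-scored per run.
Sound events are partitioned at the median (ties to the low side; an
all-equal degenerate case falls back to event-order parity and is
flagged), both halves are deconvolved in a single design that retains
the blink/saccade nuisance columns, and amplitudes are summarised as
the kernel mean over 0.5–2.5 s — a window bracketing the canonical
auditory peak at ≈1.3 s — unless the caller supplies another window.

## Synthetic sessions

The generator reproduces the study structure so every stage can be
validated against ground truth:

* **Sounds:** intervals either Gaussian (mean 3 s, sd 0.4 s — "fixed
  timing") or 1.5 s + Exponential(1.5 s) ("random timing", flat hazard,
  same mean); identities either alternating ("known") or a Markov
  chain with 40% transition probability ("unknown"); 150 s runs by
  default, the 2×2 of these conditions defining a session.
* **Ocular events:** independent Poisson processes, saccades at 0.8 Hz
  and blinks at 0.11 Hz; blink durations uniform 0.1–0.3 s; saccade
  amplitudes log-normal with mode e^(μ−σ²) ≈ 0.29° < 1° (microsaccades).
* **Signal:** events convolved with the canonical kernels (evaluated
  at exact continuous event times, so a single-event session reproduces
  the canonical curve to machine precision), plus an exponential tonic
  decay (amplitude 1 z, τ = 60 s — a slow drift over the ~2.5 min run,
  consistent with the observed settling over the first minutes of a
  recording), plus white Gaussian noise (sd 0.1 z at the 1 kHz raw
  rate). A 1/f noise option is deliberately absent; the band-pass
  shapes the white noise.
* **Dropout:** samples during each blink ±20 ms are zeroed and marked
  invalid — the artifact the interpolation stage must repair. Ground
  truth (events, clean trace, tonic, per-component signals, per-event
  amplitudes) is stored before corruption.
* **Tonic–phasic coupling:** event amplitudes scale as
  `1 − β·tonic_z(t_event)` with `tonic_z` the z-scored tonic level
  across the run's events. β defaults to 0 so the baseline generator is
  assumption-free; β = 0.5 reproduces a median-split effect of the kind
  seen in real data.
* **Subjects:** a simulated subject runs all four conditions with three
  idiosyncratic factors drawn once per subject — response gain
  (log-normal, unit mean, CV 25%), response latency (log-normal, unit
  mean, CV 10%, area-preserving time scaling), and a smooth additive
  shape perturbation (sine series over 0–6 s, sd 0.02 z). Pupil
  response amplitude and timing vary this much between people; without
  such variability a simulated group's standard error collapses to
  estimator noise and group-level statistics become meaningless.

All randomness flows from explicit seeds; identical (spec, seed) pairs
produce byte-identical sessions.

### What recovery tests can and cannot show

A 10 Hz FIR analysis of events at continuous times cannot recover the
point values of a continuous kernel: block averaging and event-time
rounding each smear the kernel with a 0.1 s boxcar, jointly a 0.2 s
triangle. `expected_recovered_kernel` computes this measurement-
operator image (including the 4 Hz post-filter, baseline subtraction
and, for group averages, the latency-factor mixture), and recovery
tests compare against it. Within the blink interpolation window
(lags below ~0.2 s after blink offset) the data are synthesized lines,
so the blink kernel there is unknowable by construction and excluded
from coverage checks. The generator also shares its kernel shapes with
the analysis defaults, so recovery tests validate the estimation
machinery, not the empirical correctness of the canonical shapes; and
white noise plus the three subject factors understate the richness of
real between-subject and within-session variability.

## Problem sizes in the bundled studies

The recovery workflows use eight 300 s noise-free runs (two per
condition) for gain recovery — averaging across conditions mirrors how
the canonical fits pool conditions and averages out single-run timing
jitter, which otherwise leaves gain errors up to ~0.03 — and 38
simulated subjects × four 150 s runs for the group study. Cluster-test
calibration uses 200 null datasets of 15 subjects × 55 lags with 1000
permutations each.

## Known limitations

* Interpolated blink windows overwrite ~0.3–0.6 s of signal per blink;
  kernel content there is unrecoverable (as in any pipeline using this
  repair).
* Quasi-periodic designs (fixed 3 s intervals with alternating
  identities) make sound-kernel columns nearly collinear; single-run
  estimates slosh mass between the two sound kernels. Randomised
  timing conditions and multi-run stacking restore identifiability.
* The exponential-decay τ from a single 150 s run has large variance;
  see the tonic-decay note above.
* Gaze-position effects (foreshortening, saccade-endpoint luminance)
  are out of scope; the event tables carry saccade amplitudes but no
  endpoints.
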