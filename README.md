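# pupilfir

FIR deconvolution and gamma-kernel modelling of event-related pupil
responses.

In cognitive pupillometry the pupil-size trace mixes the responses the
experimenter cares about (here: responses to auditory events under
constant luminance) with much larger responses to blinks and
(micro)saccades — ocular events that transiently change effective
retinal illumination — riding on a slow, arousal-linked tonic drift.
`pupilfir` is a toolkit for separating and characterising these
contributions. It is written for psychophysiologists analysing
eye-tracker pupil recordings and for methodologists studying the
pipeline itself: every stage can be run against synthetic sessions with
full ground truth.

## Method at a glance

The phasic (0.02–4 Hz band-passed, z-scored, 10 Hz) pupil signal *y* is
modelled by finite-impulse-response (FIR) deconvolution: a design
matrix *X* of staggered indicator columns — one column per lag in a
−0.5 to 5 s window around each event, for each event type — and the
least-squares solution

    h = (XᵀX)⁻¹ Xᵀ y

jointly estimates the full response time course of every event type,
unmixing overlapping responses. With four event types at 10 Hz, *X* has
220 columns, 55 per kernel.

Estimated kernels are summarised by gamma-family fits:

    gamma:   k(x) = gain · x^(k−1) e^(−x/θ) / (θ^k Γ(k))
    Erlang:  k(x) = s · x^n e^(−n·x / x_max)         (peaks at x_max)

with a double-gamma mixture (negative then positive component) for the
biphasic blink response. Canonical fitted parameter sets for the
auditory, blink and saccade responses are built in
(`pupilfir.canonical_kernels`), as are the recommended convolution-GLM
nuisance cleaning (regress canonical blink/saccade responses out of a
recording and analyse the residuals), cluster-based permutation tests
over kernel lags, tonic-level extraction with exponential-decay
fitting, and a tonic median-split analysis of the tonic–phasic
interaction. See `docs/methods.md` for the full model description.

## Worked example

Simulate one 300 s session with the study's event statistics (sounds
every ~3 s, saccades at 0.8 Hz, blinks at 0.11 Hz, tonic drift, noise,
blink dropout), deconvolve, and fit the canonical kernel families:

```python
import pupilfir as pf
from pupilfir.workflows import estimate_kernels, fit_component_gains

spec = pf.ExperimentSpec(run_duration=300.0, seed=7,
                         subject_gain_cv=0, subject_latency_cv=0,
                         subject_shape_sd=0)
ts, truth = pf.simulate_session(spec, 7)

est = estimate_kernels([(ts, truth.events)])
print(f"deconvolution R^2 = {est.r_squared:.3f}")
for name, g in fit_component_gains(est).items():
    print(f"fitted gain {name:15s} {g:+.3f}")
```

prints

```
deconvolution R^2 = 0.993
fitted gain auditory        +0.275
fitted gain blink_negative  -0.577
fitted gain blink_positive  +0.514
fitted gain saccade         -0.177
```

The generating gains were +0.3, −0.604, +0.419 and −0.175: a single
noisy run recovers the auditory and saccade responses well, while the
two blink components — whose shapes overlap — trade off some amplitude
against each other at this run length (averaging runs, as
`recover_canonical_gains` does, removes the discrepancy). R² ≈ 0.99
reflects that most of the phasic variance is event-locked, the bulk of
it driven by the ocular events rather than the sounds —
`pupilfir.variance_partition` quantifies exactly that.

The same pipeline is available from the shell:

```
pupilfir simulate --seed 7 --out-dir session/
pupilfir run --seed 7 --out-dir results/          # simulate + full pipeline
pupilfir preprocess --samples s.tsv --events e.tsv \
    --out-phasic phasic.tsv --out-tonic tonic.tsv
pupilfir deconvolve --phasic phasic.tsv --events e.tsv --out kernels.tsv
pupilfir fit-kernels --kernels kernels.tsv --out params.json
pupilfir clean --phasic phasic.tsv --events e.tsv --out residuals.tsv
pupilfir stats cluster --kernels-dir subjects/ --types sound_high \
    --perms 1000 --seed 7 --out clusters.json
```

All exchange formats are tab-separated text with one header line;
configuration is YAML/JSON mirroring the dataclasses.

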