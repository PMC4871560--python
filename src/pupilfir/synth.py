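"""Synthetic pupillometry sessions with full ground truth.

The generator emulates the structure of an equiluminant auditory
pupillometry run: two sound types whose timing is either quasi-regular
(Gaussian intervals) or memoryless (shifted-exponential intervals) and
whose identity either alternates or follows a 40%-transition Markov
chain; blinks and (micro)saccades as independent Poisson processes
(defaults 0.11 Hz and 0.8 Hz); event-locked responses built from the
canonical kernel shapes; a slow exponentially decaying tonic drift;
additive white Gaussian noise; and, optionally, blink-induced sample
dropout for the interpolation stage to repair.

Every random draw flows from explicit seeds, so identical
``(spec, seed)`` pairs produce byte-identical sessions, and the returned
:class:`GroundTruth` stores the uncorrupted components so each pipeline
stage can be checked against what it should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .core import EventTable, PupilTimeSeries, RunMetadata, ValidationError
from .kernels import (
    ExponentialDecay,
    PerturbedKernel,
    TimeScaledKernel,
    canonical_kernels,
)

__all__ = [
    "ExperimentSpec",
    "expected_recovered_kernel",
    "GroundTruth",
    "generate_sound_events",
    "generate_ocular_events",
    "synthesize",
    "simulate_session",
    "simulate_subject",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of a synthetic run.

    Defaults reproduce the study conditions: 150 s runs, mean sound
    interval 3 s (sd 0.4 s when timing is fixed; 1.5 s + Exp(1.5 s) when
    random), identity alternating or a Markov chain with transition
    probability 0.4, saccades at 0.8 Hz, blinks at 0.11 Hz with uniform
    0.1–0.3 s durations, log-normal saccade amplitudes whose mode lies
    below one degree (microsaccades), a tonic drift decaying with a
    60 s time constant from 1 z-unit, and white noise of 0.1 z-units at
    the 1 kHz raw rate.  ``beta`` scales phasic gain by the z-scored
    tonic level at event time (0 = no tonic-phasic coupling).

    ``gain_scale`` multiplies every kernel amplitude in this run; it is
    how between-subject amplitude variability enters (see
    :func:`simulate_subject`, which draws one factor per subject from a
    log-normal with coefficient of variation ``subject_gain_cv`` — a
    typical spread for pupil response amplitudes across people).
    """

    condition: RunMetadata = field(default_factory=RunMetadata)
    run_duration: float = 150.0
    interval_mean: float = 3.0
    interval_sd: float = 0.4
    interval_shift: float = 1.5
    transition_probability: float = 0.4
    saccade_rate: float = 0.8
    blink_rate: float = 0.11
    blink_duration_range: tuple[float, float] = (0.1, 0.3)
    saccade_lognorm_mu: float = -1.0
    saccade_lognorm_sigma: float = 0.5
    kernel_set: str = "table1"
    tonic_amplitude: float = 1.0
    tonic_tau: float = 60.0
    tonic_offset: float = 0.0
    beta: float = 0.0
    noise_sd: float = 0.1
    dropout: bool = True
    raw_rate: float = 1000.0
    gain_scale: float = 1.0
    latency_scale: float = 1.0
    subject_gain_cv: float = 0.25
    subject_latency_cv: float = 0.10
    subject_shape_sd: float = 0.02
    shape_perturb_seed: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.run_duration <= self.interval_mean:
            raise ValidationError("run_duration must exceed the mean sound interval")
        for name in ("saccade_rate", "blink_rate", "raw_rate", "interval_mean"):
            if getattr(self, name) < 0 or (name in ("raw_rate",) and getattr(self, name) <= 0):
                raise ValidationError(f"{name} must be positive")
        mode = np.exp(self.saccade_lognorm_mu - self.saccade_lognorm_sigma ** 2)
        if mode >= 1.0:
            raise ValidationError(
                "saccade amplitude model must have its mode below 1 degree "
                f"(got {mode:.3f})"
            )

    def kernels(self) -> Mapping[str, object]:
        base = dict(canonical_kernels(self.kernel_set))
        if self.shape_perturb_seed is not None and self.subject_shape_sd > 0:
            n_terms = 4
            for i, name in enumerate(("auditory", "blink", "saccade")):
                rng = np.random.default_rng([self.shape_perturb_seed, i])
                coeffs = tuple(
                    rng.normal(0.0, self.subject_shape_sd / np.sqrt(n_terms),
                               size=n_terms)
                )
                base[name] = PerturbedKernel(base[name], coeffs)
        if self.latency_scale != 1.0:
            base = {k: TimeScaledKernel(v, self.latency_scale)
                    for k, v in base.items()}
        return base

    def tonic_model(self) -> ExponentialDecay:
        return ExponentialDecay(self.tonic_amplitude, self.tonic_tau, self.tonic_offset)


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from one synthetic session."""

    events: EventTable
    true_kernels: dict[str, np.ndarray]
    lags: np.ndarray
    tonic: np.ndarray
    clean: np.ndarray
    components: dict[str, np.ndarray]
    amplitudes: dict[str, np.ndarray]
    spec: ExperimentSpec


def generate_sound_events(spec: ExperimentSpec, seed) -> EventTable:
    """Draw sound event times and identities for one run.

    Fixed timing draws intervals from N(mean, sd) (floored at 50 ms);
    random timing draws ``shift + Exp(mean - shift)``, giving a flat
    hazard beyond the shift and the same mean interval.  Identities
    alternate high/low when identity is known, and follow a Markov chain
    with the spec's transition probability when unknown.
    """
    rng = np.random.default_rng(seed)
    times = []
    t = 0.0
    while True:
        if spec.condition.condition_timing == "fixed":
            iv = max(rng.normal(spec.interval_mean, spec.interval_sd), 0.05)
        else:
            iv = spec.interval_shift + rng.exponential(spec.interval_mean - spec.interval_shift)
        t += iv
        if t >= spec.run_duration:
            break
        times.append(t)
    types = []
    current = "sound_high"
    for i in range(len(times)):
        if i > 0:
            if spec.condition.condition_identity == "known":
                current = "sound_low" if current == "sound_high" else "sound_high"
            else:
                if rng.random() < spec.transition_probability:
                    current = "sound_low" if current == "sound_high" else "sound_high"
        types.append(current)
    if not times:
        return EventTable.empty()
    return EventTable.from_arrays(times, types, run_id=spec.condition.session_id)


def generate_ocular_events(spec: ExperimentSpec, seed) -> EventTable:
    """Blink and saccade times as independent Poisson processes.

    Blinks carry uniform durations, saccades log-normal amplitudes;
    events within 0.5 s of the run end are dropped so their responses
    stay inside the recording.
    """
    rng = np.random.default_rng(seed)
    horizon = spec.run_duration - 0.5

    def poisson_times(rate: float) -> np.ndarray:
        if rate <= 0:
            return np.empty(0)
        n_max = int(rate * spec.run_duration * 3 + 20)
        gaps = rng.exponential(1.0 / rate, size=n_max)
        t = np.cumsum(gaps)
        return t[t < horizon]

    bt = poisson_times(spec.blink_rate)
    st = poisson_times(spec.saccade_rate)
    lo, hi = spec.blink_duration_range
    blink_dur = rng.uniform(lo, hi, size=bt.size)
    sacc_amp = rng.lognormal(spec.saccade_lognorm_mu, spec.saccade_lognorm_sigma,
                             size=st.size)
    blinks = EventTable.from_arrays(bt, "blink", durations=blink_dur,
                                    run_id=spec.condition.session_id) \
        if bt.size else EventTable.empty()
    saccades = EventTable.from_arrays(st, "saccade", amplitudes=sacc_amp,
                                      run_id=spec.condition.session_id) \
        if st.size else EventTable.empty()
    return blinks.concat(saccades)


_KERNEL_SUPPORT = 6.0  # s; canonical curves are < 1% of peak beyond this

# analysis lag grid on which true kernels are reported
_LAG_WINDOW = (-0.5, 5.0)
_LAG_RATE = 10.0


def synthesize(
    spec: ExperimentSpec,
    sound_events: EventTable,
    ocular_events: EventTable,
    noise_seed=None,
) -> tuple[PupilTimeSeries, GroundTruth]:
    """Assemble the raw signal and its ground truth from event tables.

    The clean signal is the sum over events of the event type's kernel,
    anchored at the event's anchor time (blink offset for blinks) and
    scaled by ``1 - beta * tonic_z(t_event)``, plus the tonic drift.
    White Gaussian noise (``noise_sd``) is added at the raw rate; if
    ``dropout`` is set, samples during each blink (± 20 ms) are zeroed
    and marked invalid — the artifact the interpolation stage repairs.
    """
    rate = spec.raw_rate
    n = int(round(spec.run_duration * rate))
    t_grid = np.arange(n) / rate
    tonic_curve = spec.tonic_model()(t_grid)

    events = sound_events.concat(ocular_events)
    if len(events) and events.df["time_s"].max() >= spec.run_duration:
        raise ValidationError("event times must lie inside the run duration")
    kern = spec.kernels()
    type_to_kernel = {
        "sound_high": kern["auditory"],
        "sound_low": kern["auditory"],
        "blink": kern["blink"],
        "saccade": kern["saccade"],
    }

    # z-scored tonic level at event time, shared across all events of the run
    tonic_model = spec.tonic_model()
    all_times = events.df["time_s"].to_numpy()
    if all_times.size > 1 and spec.beta != 0:
        tv = tonic_model(all_times)
        sd = tv.std()
        tonic_z = (tv - tv.mean()) / sd if sd > 0 else np.zeros_like(tv)
    else:
        tonic_z = np.zeros(all_times.size)

    support = int(round(_KERNEL_SUPPORT * rate))
    components = {name: np.zeros(n) for name in type_to_kernel}
    amplitudes: dict[str, list] = {name: [] for name in type_to_kernel}
    anchors = events.anchor_times()
    for row, (etype, t_anchor, z) in enumerate(
        zip(events.df["type"], anchors, tonic_z)
    ):
        kfun = type_to_kernel.get(etype)
        if kfun is None:
            continue
        amp = spec.gain_scale * (1.0 - spec.beta * z)
        amplitudes[etype].append(amp)
        i0 = int(np.ceil((t_anchor) * rate - 1e-9))
        i1 = min(i0 + support, n)
        if i0 >= n:
            continue
        tt = t_grid[i0:i1] - t_anchor
        components[etype][i0:i1] += amp * kfun(tt)

    clean = tonic_curve + sum(components.values())
    rng = np.random.default_rng(spec.seed if noise_seed is None else noise_seed)
    raw = clean + (rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0)

    valid = np.ones(n, dtype=bool)
    if spec.dropout:
        for _, row in events.df[events.df["type"] == "blink"].iterrows():
            lo = int(np.floor((row["time_s"] - 0.02) * rate))
            hi = int(np.ceil((row["time_s"] + row["duration_s"] + 0.02) * rate))
            lo, hi = max(lo, 0), min(hi, n)
            raw[lo:hi] = 0.0
            valid[lo:hi] = False

    lags = _LAG_WINDOW[0] + np.arange(
        int(round((_LAG_WINDOW[1] - _LAG_WINDOW[0]) * _LAG_RATE))
    ) / _LAG_RATE
    true_kernels = {name: k(lags) for name, k in type_to_kernel.items()}
    truth = GroundTruth(
        events=events,
        true_kernels=true_kernels,
        lags=lags,
        tonic=tonic_curve,
        clean=clean,
        components=components,
        amplitudes={k: np.asarray(v) for k, v in amplitudes.items()},
        spec=spec,
    )
    ts = PupilTimeSeries(raw, rate, 0.0, valid, units_tag="zscored")
    return ts, truth


def simulate_session(
    spec: ExperimentSpec, seed: int | None = None
) -> tuple[PupilTimeSeries, GroundTruth]:
    """Generate one complete session from a single master seed.

    Sound events, ocular events and noise each get an independent stream
    derived from ``seed`` (``spec.seed`` when omitted).
    """
    base = spec.seed if seed is None else seed
    sounds = generate_sound_events(spec, [base, 0])
    ocular = generate_ocular_events(spec, [base, 1])
    return synthesize(spec, sounds, ocular, noise_seed=[base, 2])


def simulate_subject(
    spec: ExperimentSpec,
    subject_seed: int | list,
    conditions: tuple[RunMetadata, ...] | None = None,
) -> list[tuple[PupilTimeSeries, GroundTruth]]:
    """Simulate one subject: a shared amplitude factor, one run per condition.

    Subjects differ in how strongly and how quickly their pupil
    responds: an amplitude factor (log-normal, unit mean, coefficient of
    variation ``spec.subject_gain_cv``) scales every kernel gain, and a
    latency factor (log-normal, unit mean, cv ``spec.subject_latency_cv``)
    stretches every kernel in time (area-preserving), and a smooth
    additive shape perturbation (sd ``spec.subject_shape_sd`` z-units)
    gives each subject an idiosyncratic response shape.  All are drawn
    once per subject and applied to all of the subject's runs.  By
    default the four conditions of the 2x2 timing/identity design are
    run once each.
    """
    if conditions is None:
        conditions = tuple(
            RunMetadata(t, i)
            for t in ("fixed", "random") for i in ("known", "unknown")
        )
    seed_list = subject_seed if isinstance(subject_seed, list) else [subject_seed]
    rng = np.random.default_rng(seed_list + [17])

    def lognormal_unit_mean(cv: float) -> float:
        if cv <= 0:
            return 1.0
        sigma = np.sqrt(np.log(1.0 + cv ** 2))
        return float(rng.lognormal(-0.5 * sigma ** 2, sigma))

    gain = lognormal_unit_mean(spec.subject_gain_cv)
    latency = lognormal_unit_mean(spec.subject_latency_cv)
    perturb = int(rng.integers(0, 2**31 - 1)) if spec.subject_shape_sd > 0 else None
    out = []
    for ci, cond in enumerate(conditions):
        run_spec = replace(spec, condition=cond,
                           gain_scale=spec.gain_scale * gain,
                           latency_scale=spec.latency_scale * latency,
                           shape_perturb_seed=perturb)
        out.append(simulate_session(run_spec, seed_list + [ci]))
    return out


def expected_recovered_kernel(
    kernel,
    lags: np.ndarray,
    rate: float = 10.0,
    lowpass: float = 4.0,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
    latency_cv: float = 0.0,
) -> np.ndarray:
    """What an unbiased 10 Hz FIR analysis recovers for a continuous kernel.

    A kernel estimated from block-averaged samples with event times
    rounded to the analysis grid is the continuous curve convolved with
    a triangular window of half-width ``1/rate`` (block averaging x
    rounding jitter), then low-passed and baselined exactly like the
    estimates.  With ``latency_cv`` > 0 the expectation additionally
    averages over the log-normal between-subject latency factors, which
    is what a group mean across subjects estimates.
    """
    from scipy import signal as _signal

    from .kernels import TimeScaledKernel

    lags = np.asarray(lags, dtype=float)

    def smear(k) -> np.ndarray:
        u = np.linspace(-1.0 / rate, 1.0 / rate, 41)
        w = 1.0 - np.abs(u) * rate
        w /= w.sum()
        return np.array([np.sum(w * k(l + u)) for l in lags])

    if latency_cv > 0:
        sigma = np.sqrt(np.log(1.0 + latency_cv ** 2))
        nodes, weights = np.polynomial.hermite_e.hermegauss(15)
        factors = np.exp(-0.5 * sigma ** 2 + sigma * nodes)
        weights = weights / weights.sum()
        sm = sum(
            wi * smear(TimeScaledKernel(kernel, float(fi)))
            for wi, fi in zip(weights, factors)
        )
    else:
        sm = smear(kernel)
    if lowpass < rate / 2:
        sos = _signal.butter(3, lowpass, btype="lowpass", fs=rate, output="sos")
        sm = _signal.sosfiltfilt(sos, sm)
    base = (lags >= baseline_window[0]) & (lags < baseline_window[1])
    return sm - sm[base].mean()
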