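"""Preprocessing of raw pupil recordings.

A raw recording is turned into two signals:

* the **phasic** signal — blink-interpolated, band-pass filtered
  (0.02–4 Hz, third-order Butterworth, zero-phase), normalized to z-units
  and resampled to 10 Hz — carries the fast event-locked responses that
  the deconvolution stage models;
* the **tonic** signal — blink-interpolated and low-pass filtered below
  0.02 Hz — carries the slow baseline drift linked to arousal state.

The pipeline order is fixed: interpolate -> band-pass -> normalize ->
resample for the phasic branch, interpolate -> low-pass for the tonic
branch.  All filtering is zero-phase (forward-backward), so event-locked
kernel timing is not biased by filter lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .core import (
    DegenerateSignalError,
    EventTable,
    PupilTimeSeries,
    ValidationError,
)

__all__ = [
    "PreprocessConfig",
    "detect_blinks",
    "interpolate_blinks",
    "bandpass_phasic",
    "extract_tonic",
    "normalize",
    "resample_to",
    "tonic_at_events",
    "run_preprocessing",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing pipeline.

    Defaults implement the standard recipe: linear interpolation from
    150 ms before blink onset to 150 ms after blink offset, a 0.02–4 Hz
    third-order Butterworth band-pass for the phasic signal, a 0.02 Hz
    low-pass for the tonic signal, and resampling to 10 Hz.
    """

    interp_pad_before: float = 0.150
    interp_pad_after: float = 0.150
    band_low: float = 0.02
    band_high: float = 4.0
    filter_order: int = 3
    tonic_cutoff: float = 0.02
    target_rate: float = 10.0
    baseline_window: tuple[float, float] = (-0.5, 0.0)

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValidationError("need 0 < band_low < band_high")
        if self.interp_pad_before < 0 or self.interp_pad_after < 0:
            raise ValidationError("interpolation pads must be >= 0")
        if self.filter_order < 1:
            raise ValidationError("filter_order must be >= 1")
        if self.target_rate <= 0 or self.tonic_cutoff <= 0:
            raise ValidationError("rates and cutoffs must be > 0")
        if self.band_high >= self.target_rate / 2:
            raise ValidationError(
                "band_high must stay below the target-rate Nyquist frequency"
            )


def detect_blinks(ts: PupilTimeSeries, min_gap: float = 0.05) -> EventTable:
    """Detect blinks as maximal runs of invalid samples lasting >= ``min_gap``.

    This is a fallback for recordings without tracker-provided blink
    events; tracker-supplied blink tables bypass this step.
    """
    if not ts.valid.any():
        raise DegenerateSignalError("recording contains no valid samples")
    invalid = ~ts.valid
    padded = np.concatenate(([False], invalid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    onsets, durations = [], []
    for i0, i1 in zip(starts, stops):
        dur = (i1 - i0) / ts.sample_rate
        if dur >= min_gap:
            onsets.append(ts.start_time + i0 / ts.sample_rate)
            durations.append(dur)
    if not onsets:
        return EventTable.empty()
    return EventTable.from_arrays(onsets, "blink", durations=durations)


def _merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for a, b in sorted(windows):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def interpolate_blinks(
    ts: PupilTimeSeries,
    blinks: EventTable,
    cfg: PreprocessConfig | None = None,
) -> PupilTimeSeries:
    """Linearly interpolate blink gaps (plus padding) out of the signal.

    Each blink defines a window from ``onset - interp_pad_before`` to
    ``offset + interp_pad_after``; overlapping or touching windows are
    merged, and the samples inside each window are replaced by the
    straight line joining the nearest valid boundary samples.  Windows
    that run past a recording edge hold the nearest valid value instead.
    Any remaining short runs of invalid samples (brief tracker dropouts)
    are interpolated by the same rule with zero padding.  All repaired
    samples are marked valid.
    """
    cfg = cfg or PreprocessConfig()
    rate = ts.sample_rate
    n = len(ts)
    out = ts.samples.copy()
    valid = ts.valid.copy()

    windows: list[tuple[float, float]] = []
    for _, row in blinks.df.iterrows():
        onset = row["time_s"]
        dur = row["duration_s"] if np.isfinite(row["duration_s"]) else 0.0
        if onset < ts.start_time - 1e-9 or onset > ts.end_time + 1e-9:
            raise ValidationError("blink time outside the recording extent")
        windows.append((onset - cfg.interp_pad_before, onset + dur + cfg.interp_pad_after))
    # residual invalid runs not covered by a declared blink: zero padding
    invalid = ~valid
    padded = np.concatenate(([False], invalid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        windows.append(
            (ts.start_time + i0 / rate, ts.start_time + (i1 - 1) / rate)
        )

    for t0, t1 in _merge_windows(windows):
        i0 = int(np.ceil((t0 - ts.start_time) * rate - 1e-9))
        i1 = int(np.floor((t1 - ts.start_time) * rate + 1e-9))
        i0, i1 = max(i0, 0), min(i1, n - 1)
        if i0 > i1:
            continue
        left, right = i0 - 1, i1 + 1
        if left < 0 and right > n - 1:
            raise DegenerateSignalError("blink window covers the entire recording")
        if left < 0:  # hold nearest valid value at the left edge
            out[i0 : i1 + 1] = out[right]
        elif right > n - 1:
            out[i0 : i1 + 1] = out[left]
        else:
            out[i0 : i1 + 1] = np.interp(
                np.arange(i0, i1 + 1), [left, right], [out[left], out[right]]
            )
        valid[i0 : i1 + 1] = True
    return PupilTimeSeries(out, rate, ts.start_time, valid, ts.units_tag)


def _require_valid(ts: PupilTimeSeries, op: str) -> None:
    if not ts.valid.all():
        raise ValidationError(f"{op} requires a fully valid (interpolated) signal")


def _sos(order: int, freqs, btype: str, fs: float):
    return signal.butter(order, freqs, btype=btype, fs=fs, output="sos")


def bandpass_phasic(ts: PupilTimeSeries, cfg: PreprocessConfig | None = None) -> PupilTimeSeries:
    """Zero-phase band-pass (default 0.02–4 Hz, order 3) -> phasic signal."""
    cfg = cfg or PreprocessConfig()
    _require_valid(ts, "bandpass_phasic")
    if ts.duration < 3.0 / (2 * np.pi * cfg.band_low):
        warnings.warn(
            "record is shorter than ~3 time constants of the high-pass corner; "
            "edge effects may dominate",
            stacklevel=2,
        )
    sos = _sos(cfg.filter_order, [cfg.band_low, cfg.band_high], "bandpass", ts.sample_rate)
    return ts.with_samples(signal.sosfiltfilt(sos, ts.samples))


def extract_tonic(ts: PupilTimeSeries, cfg: PreprocessConfig | None = None) -> PupilTimeSeries:
    """Zero-phase low-pass (default 0.02 Hz, order 3) -> tonic signal."""
    cfg = cfg or PreprocessConfig()
    _require_valid(ts, "extract_tonic")
    sos = _sos(cfg.filter_order, cfg.tonic_cutoff, "lowpass", ts.sample_rate)
    return ts.with_samples(signal.sosfiltfilt(sos, ts.samples))


def normalize(
    segments: Sequence[PupilTimeSeries],
    sessions: Sequence[str] | None = None,
) -> list[PupilTimeSeries]:
    """Demean each condition segment; divide by one std per session.

    Each segment is demeaned individually (per condition), but every
    segment of a session is divided by the same standard deviation — that
    of the session's concatenated signal — so amplitudes stay comparable
    across the conditions of a session.
    """
    if sessions is None:
        sessions = ["session0"] * len(segments)
    if len(sessions) != len(segments):
        raise ValidationError("need one session label per segment")
    for seg in segments:
        if len(seg) < 2:
            raise ValidationError("each segment needs at least 2 samples")
    divisor: dict[str, float] = {}
    for sess in set(sessions):
        pooled = np.concatenate(
            [seg.samples for seg, s in zip(segments, sessions) if s == sess]
        )
        sd = float(np.std(pooled))
        if sd == 0:
            raise DegenerateSignalError(f"session {sess!r} has zero variance")
        divisor[sess] = sd
    out = []
    for seg, sess in zip(segments, sessions):
        z = (seg.samples - seg.samples.mean()) / divisor[sess]
        out.append(seg.with_samples(z, valid=seg.valid.copy(), units_tag="zscored"))
    return out


def resample_to(ts: PupilTimeSeries, target_rate: float) -> PupilTimeSeries:
    """Resample to ``target_rate`` by block averaging (anti-aliased upstream).

    When the input rate is an integer multiple of the target, samples are
    averaged within non-overlapping blocks and the output timestamps sit
    at the block centres.  Otherwise the signal is linearly interpolated
    onto the target grid.
    """
    if target_rate <= 0:
        raise ValidationError("target_rate must be > 0")
    ratio = ts.sample_rate / target_rate
    n_int = int(round(ratio))
    if abs(ratio - n_int) < 1e-9 and n_int >= 1:
        if n_int == 1:
            return ts.with_samples(ts.samples.copy(), valid=ts.valid.copy())
        n_blocks = len(ts) // n_int
        if n_blocks == 0:
            raise ValidationError("record shorter than one resampling block")
        block = ts.samples[: n_blocks * n_int].reshape(n_blocks, n_int)
        return PupilTimeSeries(
            block.mean(axis=1),
            target_rate,
            start_time=ts.start_time + (n_int - 1) / (2 * ts.sample_rate),
            units_tag=ts.units_tag,
        )
    new_times = ts.start_time + np.arange(int(ts.duration * target_rate)) / target_rate
    return PupilTimeSeries(
        np.interp(new_times, ts.times, ts.samples),
        target_rate,
        start_time=ts.start_time,
        units_tag=ts.units_tag,
    )


def tonic_at_events(
    tonic: PupilTimeSeries,
    events: EventTable,
    window: tuple[float, float] = (-0.5, 0.0),
    per_run: bool = True,
) -> np.ndarray:
    """Mean tonic level in ``window`` around each event, z-scored per run.

    Returns one value per event row, NaN for events whose window has no
    overlap with the recording (those events are excluded from z-scoring).
    Windows partially outside the recording are clamped to the available
    samples.  A run in which all values are identical yields all-zero
    scores with a warning.
    """
    if window[0] >= window[1]:
        raise ValidationError("window start must precede window end")
    t = tonic.times
    raw = np.full(len(events), np.nan)
    for i, et in enumerate(events.df["time_s"].to_numpy()):
        lo, hi = et + window[0], et + window[1]
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            # clamp: nearest sample if the window grazes the recording edge
            if hi <= tonic.start_time or lo >= tonic.end_time:
                continue  # no overlap at all -> excluded
            sel = np.array([np.argmin(np.abs(t - (lo + hi) / 2))])
        raw[i] = float(np.mean(tonic.samples[sel]))
    out = np.full_like(raw, np.nan)
    groups = events.df["run_id"].to_numpy() if per_run else np.zeros(len(events))
    for run in np.unique(groups):
        sel = (groups == run) & np.isfinite(raw)
        if not sel.any():
            continue
        vals = raw[sel]
        sd = vals.std()
        if sd == 0:
            warnings.warn(f"degenerate tonic values in run {run!r}; scores set to 0",
                          stacklevel=2)
            out[sel] = 0.0
        else:
            out[sel] = (vals - vals.mean()) / sd
    return out


def run_preprocessing(
    raw: PupilTimeSeries,
    blinks: EventTable,
    cfg: PreprocessConfig | None = None,
    *,
    session_id: str = "session0",
) -> tuple[PupilTimeSeries, PupilTimeSeries]:
    """Full fixed-order pipeline; returns ``(phasic, tonic)``.

    Phasic branch: interpolate -> band-pass -> normalize -> resample.
    Tonic branch: interpolate -> low-pass (kept at the raw rate).
    """
    cfg = cfg or PreprocessConfig()
    clean = interpolate_blinks(raw, blinks, cfg)
    band = bandpass_phasic(clean, cfg)
    (norm,) = normalize([band], [session_id])
    phasic = resample_to(norm, cfg.target_rate)
    tonic = extract_tonic(clean, cfg)
    return phasic, tonic
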