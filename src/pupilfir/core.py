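"""Shared domain types for pupillometry time-series analysis.

The toolkit works on two in-memory containers: :class:`PupilTimeSeries`, a
uniformly sampled pupil-size signal with a validity mask, and
:class:`EventTable`, a timestamped table of typed events (sounds, blinks,
saccades).  Time is measured in seconds, floating point, zero-based at the
start of the recording; sample *i* of a series lives at
``start_time + i / sample_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PupilError",
    "FormatError",
    "SamplingRateError",
    "DegenerateSignalError",
    "FitError",
    "ValidationError",
    "PupilTimeSeries",
    "EventTable",
    "RunMetadata",
    "SOUND_TYPES",
    "OCULAR_TYPES",
]

SOUND_TYPES = ("sound_high", "sound_low")
OCULAR_TYPES = ("blink", "saccade")


class PupilError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PupilError):
    """A file or table does not match the expected layout."""


class SamplingRateError(PupilError):
    """Sample spacing is missing, non-positive or too irregular."""


class DegenerateSignalError(PupilError):
    """A signal has no usable variance or no valid samples."""


class FitError(PupilError):
    """A nonlinear fit failed from every starting point."""


class ValidationError(PupilError):
    """Arguments violate a documented precondition."""


@dataclass
class PupilTimeSeries:
    """Uniformly sampled pupil-size signal.

    Parameters
    ----------
    samples:
        Pupil size per sample, in recorder arbitrary units (``units_tag ==
        "raw"``) or z-units after normalization (``units_tag == "zscored"``).
    sample_rate:
        Sampling rate in Hz, > 0.
    start_time:
        Time of the first sample in seconds.
    valid:
        Boolean mask, same length as ``samples``; False marks lost samples
        (blinks, tracker dropouts).  Defaults to all-valid.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    valid: np.ndarray | None = None
    units_tag: str = "raw"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise SamplingRateError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.valid is None:
            self.valid = np.ones(self.samples.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.samples.shape:
            raise ValidationError("valid mask must have the same length as samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def with_samples(
        self,
        samples: np.ndarray,
        *,
        sample_rate: float | None = None,
        start_time: float | None = None,
        valid: np.ndarray | None = None,
        units_tag: str | None = None,
    ) -> "PupilTimeSeries":
        """Return a copy with replaced fields (mask defaults to all-valid)."""
        return PupilTimeSeries(
            samples=np.asarray(samples, dtype=float),
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
            start_time=self.start_time if start_time is None else start_time,
            valid=valid,
            units_tag=self.units_tag if units_tag is None else units_tag,
        )

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (round-to-nearest)."""
        return int(round((t - self.start_time) * self.sample_rate))


_EVENT_COLUMNS = ["time_s", "type", "duration_s", "amplitude_deg", "run_id"]


@dataclass
class EventTable:
    """Timestamped, typed events (sounds, blinks, saccades, custom labels).

    Thin wrapper around a :class:`pandas.DataFrame` with the columns
    ``time_s, type, duration_s, amplitude_deg, run_id``.  Rows are kept
    sorted by time within each type; optional attributes are NaN when
    absent.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "time_s" not in df.columns or "type" not in df.columns:
            raise FormatError("event table requires time_s and type columns")
        for col, default in (
            ("duration_s", np.nan),
            ("amplitude_deg", np.nan),
            ("run_id", "run0"),
        ):
            if col not in df.columns:
                df[col] = default
        df["time_s"] = pd.to_numeric(df["time_s"], errors="raise").astype(float)
        df["type"] = df["type"].astype(str)
        df["duration_s"] = pd.to_numeric(df["duration_s"], errors="coerce").astype(float)
        df["amplitude_deg"] = pd.to_numeric(df["amplitude_deg"], errors="coerce").astype(float)
        df["run_id"] = df["run_id"].fillna("run0").astype(str)
        neg_dur = df["duration_s"].dropna() < 0
        neg_amp = df["amplitude_deg"].dropna() < 0
        if neg_dur.any() or neg_amp.any():
            raise ValidationError("durations and amplitudes must be >= 0")
        # stable sort keeps file order among simultaneous events
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
        self.df = df[_EVENT_COLUMNS]

    @classmethod
    def from_arrays(
        cls,
        times: Sequence[float],
        types: Sequence[str] | str,
        durations: Sequence[float] | None = None,
        amplitudes: Sequence[float] | None = None,
        run_id: str | Sequence[str] = "run0",
    ) -> "EventTable":
        times = np.asarray(times, dtype=float)
        if isinstance(types, str):
            types = [types] * times.size
        data = {"time_s": times, "type": list(types)}
        if durations is not None:
            data["duration_s"] = np.asarray(durations, dtype=float)
        if amplitudes is not None:
            data["amplitude_deg"] = np.asarray(amplitudes, dtype=float)
        data["run_id"] = [run_id] * times.size if isinstance(run_id, str) else list(run_id)
        return cls(pd.DataFrame(data))

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame({c: pd.Series(dtype=float if c not in ("type", "run_id") else str)
                                 for c in _EVENT_COLUMNS}))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def types(self) -> list[str]:
        """Event-type labels in order of first appearance."""
        return list(dict.fromkeys(self.df["type"]))

    def times_of(self, event_type: str) -> np.ndarray:
        return self.df.loc[self.df["type"] == event_type, "time_s"].to_numpy()

    def select(self, event_types: Iterable[str]) -> "EventTable":
        wanted = set(event_types)
        return EventTable(self.df[self.df["type"].isin(wanted)].reset_index(drop=True))

    def concat(self, other: "EventTable") -> "EventTable":
        return EventTable(pd.concat([self.df, other.df], ignore_index=True))

    def anchor_times(self, blink_at_offset: bool = True) -> np.ndarray:
        """Per-row times at which each event anchors its pupil response.

        Blink responses are time-locked to the reopening of the eye, so the
        blink anchor is onset + duration when a duration is recorded; every
        other type (including saccades, whose recorded time is already the
        offset) anchors at its listed time.
        """
        t = self.df["time_s"].to_numpy(copy=True)
        if blink_at_offset:
            is_blink = (self.df["type"] == "blink").to_numpy()
            dur = np.nan_to_num(self.df["duration_s"].to_numpy(), nan=0.0)
            t[is_blink] += dur[is_blink]
        return t

    def with_anchor_times(self, blink_at_offset: bool = True) -> "EventTable":
        """Copy of the table with ``time_s`` replaced by anchor times."""
        df = self.df.copy()
        df["time_s"] = self.anchor_times(blink_at_offset)
        return EventTable(df)


_TIMING = ("fixed", "random")
_IDENTITY = ("known", "unknown")


@dataclass(frozen=True)
class RunMetadata:
    """Condition labels for one run of the 2x2 predictability design."""

    condition_timing: str = "fixed"
    condition_identity: str = "known"
    session_id: str = "session0"
    experiment_version: int = 1

    def __post_init__(self) -> None:
        if self.condition_timing not in _TIMING:
            raise ValidationError(f"condition_timing must be one of {_TIMING}")
        if self.condition_identity not in _IDENTITY:
            raise ValidationError(f"condition_identity must be one of {_IDENTITY}")
        if self.experiment_version not in (1, 2):
            raise ValidationError("experiment_version must be 1 or 2")
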