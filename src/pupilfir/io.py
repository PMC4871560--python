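"""Readers and writers for the toolkit's delimited-text exchange formats.

All files are tab-separated with a one-line header.  Numeric columns are
written with 12 significant digits so a write/read round trip is lossless
to better than 1e-9 relative.

Formats
-------
samples TSV
    ``time_s, pupil, gaze_x (optional), gaze_y (optional), valid (0/1,
    optional)``.
events TSV
    ``time_s, type, duration_s (optional), amplitude_deg (optional),
    run_id``.
kernels TSV
    first column ``lag_s``, then one column per event type.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    EventTable,
    FormatError,
    PupilTimeSeries,
    SamplingRateError,
    ValidationError,
)

__all__ = [
    "read_samples",
    "write_samples",
    "read_events",
    "write_events",
    "read_kernels",
    "write_kernels",
]

_FLOAT_FMT = "%.12g"

#: default mapping from logical fields to column names in a samples file
DEFAULT_SAMPLES_DIALECT: Mapping[str, str] = {
    "time": "time_s",
    "pupil": "pupil",
    "valid": "valid",
}


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc


def read_samples(
    path: str | os.PathLike,
    dialect: Mapping[str, str] | None = None,
    spacing_tol: float = 0.01,
) -> PupilTimeSeries:
    """Read a pupil sample stream from a TSV file.

    The sample rate is inferred as the reciprocal of the median
    inter-sample interval; spacing deviating from the median by more than
    ``spacing_tol`` (relative) raises :class:`SamplingRateError`.  Samples
    whose pupil value is missing or zero are marked invalid, as is any row
    with ``valid == 0`` when a validity column is present.
    """
    dia = dict(DEFAULT_SAMPLES_DIALECT)
    if dialect:
        dia.update(dialect)
    df = _read_table(path)
    for key in ("time", "pupil"):
        if dia[key] not in df.columns:
            raise FormatError(f"missing required column {dia[key]!r} in {path}")
    t = pd.to_numeric(df[dia["time"]], errors="coerce").to_numpy(dtype=float)
    if np.isnan(t).any():
        raise FormatError(f"unparseable time values in {path}")
    if t.size < 2:
        raise SamplingRateError("need at least 2 samples to infer a sample rate")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise SamplingRateError("time column must be strictly increasing")
    if np.max(np.abs(dt - med)) > spacing_tol * med:
        raise SamplingRateError(
            f"sample spacing deviates more than {spacing_tol:.0%} from the median"
        )
    pupil = pd.to_numeric(df[dia["pupil"]], errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(pupil) & (pupil != 0.0)
    if dia.get("valid") in df.columns:
        valid &= df[dia["valid"]].to_numpy() != 0
    return PupilTimeSeries(
        samples=np.nan_to_num(pupil, nan=0.0),
        sample_rate=1.0 / med,
        start_time=float(t[0]),
        valid=valid,
    )


def write_samples(ts: PupilTimeSeries, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "time_s": ts.times,
            "pupil": ts.samples,
            "valid": ts.valid.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events(path: str | os.PathLike) -> EventTable:
    """Read an event table; rows come back sorted by time within type."""
    df = _read_table(path)
    if df.empty and "time_s" in df.columns and "type" in df.columns:
        return EventTable.empty()
    if "time_s" not in df.columns or "type" not in df.columns:
        raise FormatError(f"event file {path} needs time_s and type columns")
    bad = pd.to_numeric(df["time_s"], errors="coerce").isna()
    if bad.any():
        raise FormatError(f"unparseable time_s values in {path}")
    return EventTable(df)


def write_events(events: EventTable, path: str | os.PathLike) -> None:
    events.df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_kernels(estimates, path: str | os.PathLike) -> None:
    """Write kernel estimates as a kernels TSV (lag column + one per type).

    ``estimates`` is any object with ``lags`` (array, seconds) and
    ``kernels`` (ordered mapping of event type to array) attributes, e.g.
    :class:`pupilfir.deconvolve.KernelEstimates`.
    """
    kernels = dict(estimates.kernels)
    if not kernels:
        raise ValidationError("cannot write an empty kernel set")
    lags = np.asarray(estimates.lags, dtype=float)
    data = {"lag_s": lags}
    for name, values in kernels.items():
        values = np.asarray(values, dtype=float)
        if values.shape != lags.shape:
            raise ValidationError(f"kernel {name!r} does not match the lag axis")
        data[name] = values
    try:
        pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    except OSError as exc:  # distinct from validation failures above
        raise IOError(f"could not write kernels to {path}: {exc}") from exc


def read_kernels(path: str | os.PathLike):
    """Read a kernels TSV back into a :class:`KernelEstimates`."""
    from .deconvolve import KernelEstimates

    df = _read_table(path)
    if "lag_s" not in df.columns or df.shape[1] < 2:
        raise FormatError(f"kernel file {path} needs a lag_s column and one kernel")
    lags = df["lag_s"].to_numpy(dtype=float)
    if lags.size < 2:
        raise FormatError("kernel file has fewer than 2 lags")
    step = float(np.median(np.diff(lags)))
    kernels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "lag_s"}
    return KernelEstimates(lags=lags, kernels=kernels, rate=1.0 / step)
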