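"""Finite impulse-response (FIR) deconvolution of event-locked responses.

The phasic pupil signal *y* is modelled as a sum of event-locked kernels.
For each event type a staggered set of indicator columns — one column per
lag in a window around the event, ones at the sample times that lag
implies — forms the design matrix *X*, and the ordinary least-squares
solution ``h = (X'X)^-1 X'y`` simultaneously estimates the full response
time course of every type.  Because all types are estimated jointly,
overlapping responses (e.g. a blink shortly after a tone) are unmixed by
the regression rather than contaminating trial averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EventTable, PupilTimeSeries, ValidationError, DegenerateSignalError

__all__ = [
    "DesignMatrix",
    "KernelEstimates",
    "GroupKernels",
    "build_design_matrix",
    "dct_drift_basis",
    "stack_designs",
    "solve_fir",
    "postprocess_kernels",
    "variance_partition",
    "group_average",
]


@dataclass
class DesignMatrix:
    """Staggered 0/1 indicator design for FIR estimation.

    ``values`` is T x (E*L) with E event types in declared order and
    L = (window end - window start) * rate lags per type, lags ascending.
    Entries count the events hitting a (sample, lag) cell, so they are 0
    or 1 except when two events of a type fall in the same sample bin.
    """

    values: np.ndarray
    event_types: list[str]
    window: tuple[float, float]
    rate: float
    start_time: float = 0.0
    #: optional slow-drift nuisance columns (intercept + DCT cosines),
    #: estimated jointly with the kernels and then discarded
    nuisance: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_lags(self) -> int:
        return self.values.shape[1] // len(self.event_types)

    @property
    def lags(self) -> np.ndarray:
        """Lag axis in seconds, half-open ``[start, end)``."""
        return self.window[0] + np.arange(self.n_lags) / self.rate

    def block(self, event_type: str) -> np.ndarray:
        """Column block (view) belonging to one event type."""
        i = self.event_types.index(event_type)
        L = self.n_lags
        return self.values[:, i * L : (i + 1) * L]


@dataclass
class KernelEstimates:
    """Per-event-type FIR kernels on a common lag axis, plus diagnostics."""

    lags: np.ndarray
    kernels: dict[str, np.ndarray]
    rate: float
    residual_variance: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        if self.lags.size >= 2 and not np.all(np.diff(self.lags) > 0):
            raise ValidationError("lag axis must be strictly increasing")
        for name, k in self.kernels.items():
            if np.asarray(k).shape != self.lags.shape:
                raise ValidationError(f"kernel {name!r} length does not match lags")

    @property
    def event_types(self) -> list[str]:
        return list(self.kernels)


def build_design_matrix(
    events: EventTable,
    n_samples: int,
    rate: float,
    window: tuple[float, float] = (-0.5, 5.0),
    event_types: list[str] | None = None,
    start_time: float = 0.0,
    drift_cutoff: float | None = None,
) -> DesignMatrix:
    """Build the staggered indicator design matrix.

    For an event at time *t* and lag ``lag_j = window[0] + j/rate``, row
    ``round((t + lag_j - start_time) * rate)`` of that type's j-th column
    is incremented when it falls inside ``[0, n_samples)``; rows outside
    are simply not set (edge truncation).  Event-to-sample mapping rounds to
    the nearest sample.  Columns are ordered by event type (declared
    order) then ascending lag.  With the standard window (-0.5 to 5 s at
    10 Hz) and four event types this yields 220 columns, 55 per kernel.

    ``drift_cutoff`` (Hz) attaches an intercept + cosine drift basis as
    nuisance columns, removing slow drift jointly with the kernel
    estimation instead of by filtering.
    """
    if n_samples <= 0:
        raise ValidationError("n_samples must be > 0")
    if window[0] >= window[1]:
        raise ValidationError("window start must precede window end")
    if event_types is None:
        event_types = events.types
    if not event_types:
        raise ValidationError("no event types to model")
    nuisance = dct_drift_basis(n_samples, rate, drift_cutoff) if drift_cutoff else None
    L = int(round((window[1] - window[0]) * rate))
    X = np.zeros((n_samples, len(event_types) * L))
    for c, etype in enumerate(event_types):
        times = events.times_of(etype)
        if times.size == 0:
            warnings.warn(f"event type {etype!r} has no events; zero column block",
                          stacklevel=2)
            continue
        base = np.round((times + window[0] - start_time) * rate).astype(int)
        for j in range(L):
            rows = base + j
            ok = (rows >= 0) & (rows < n_samples)
            # accumulate so two events sharing a sample count twice
            np.add.at(X[:, c * L + j], rows[ok], 1.0)
    return DesignMatrix(X, list(event_types), tuple(window), rate, start_time, nuisance)


def dct_drift_basis(n_samples: int, rate: float, cutoff: float = 0.02) -> np.ndarray:
    """Intercept plus cosine drift regressors up to ``cutoff`` Hz.

    The discrete-cosine set spans frequencies k / (2 T) for
    k = 1 .. floor(2 T cutoff); estimating it jointly with the FIR
    removes slow drift without the baseline undershoot a high-pass
    filter would imprint on event-locked responses.
    """
    T = n_samples / rate
    k_max = int(np.floor(2 * T * cutoff))
    t = np.arange(n_samples)
    cols = [np.ones(n_samples)]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / n_samples))
    return np.column_stack(cols)


def stack_designs(designs: list[DesignMatrix]) -> DesignMatrix:
    """Vertically stack per-run designs sharing columns (multi-run solve).

    Runs are modelled as independent recordings: rows are concatenated,
    kernels stay shared, each run's edge truncation is preserved, and
    per-run nuisance columns become a block-diagonal set so drift is
    removed run by run.  The matching signal is the concatenation of the
    runs' samples.
    """
    first = designs[0]
    for d in designs[1:]:
        if d.event_types != first.event_types or d.window != first.window \
                or d.rate != first.rate:
            raise ValidationError("stacked designs must share types, window and rate")
    values = np.vstack([d.values for d in designs])
    nuisance = None
    if any(d.nuisance is not None for d in designs):
        total_rows = values.shape[0]
        total_cols = sum(0 if d.nuisance is None else d.nuisance.shape[1]
                         for d in designs)
        nuisance = np.zeros((total_rows, total_cols))
        r = c = 0
        for d in designs:
            nr = d.values.shape[0]
            if d.nuisance is not None:
                nc = d.nuisance.shape[1]
                nuisance[r : r + nr, c : c + nc] = d.nuisance
                c += nc
            r += nr
    return DesignMatrix(
        values, list(first.event_types), first.window, first.rate,
        first.start_time, nuisance,
    )


def solve_fir(X: DesignMatrix, y: PupilTimeSeries | np.ndarray) -> KernelEstimates:
    """Least-squares FIR solve; minimum-norm when the design is deficient.

    Returns the per-type kernels unpacked from the concatenated solution
    vector, with residual variance and R-squared as diagnostics.  A design
    with condition number above 1e10 triggers a rank warning and the
    minimum-norm solution is returned.
    """
    yv = y.samples if isinstance(y, PupilTimeSeries) else np.asarray(y, dtype=float)
    if yv.size != X.n_samples:
        raise ValidationError(
            f"signal length {yv.size} does not match design rows {X.n_samples}"
        )
    full = X.values if X.nuisance is None \
        else np.column_stack([X.values, X.nuisance])
    h_full, _, rank, sv = np.linalg.lstsq(full, yv, rcond=None)
    cond = sv[0] / sv[-1] if sv.size and sv[-1] > 0 else np.inf
    if rank < full.shape[1] or cond > 1e10:
        warnings.warn(
            f"rank-deficient or ill-conditioned design (cond={cond:.3g}); "
            "minimum-norm solution returned",
            stacklevel=2,
        )
    h = h_full[: X.values.shape[1]]
    resid = yv - full @ h_full
    var_y = float(np.var(yv))
    res_var = float(np.var(resid))
    r2 = 1.0 - res_var / var_y if var_y > 0 else np.nan
    L = X.n_lags
    kernels = {t: h[i * L : (i + 1) * L].copy() for i, t in enumerate(X.event_types)}
    return KernelEstimates(X.lags, kernels, X.rate, residual_variance=res_var, r_squared=r2)


def postprocess_kernels(
    estimates: KernelEstimates,
    lowpass: float = 4.0,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
    order: int = 3,
) -> KernelEstimates:
    """Low-pass (zero-phase) each kernel and subtract its baseline mean.

    The baseline is the mean over ``baseline_window`` (default the 0.5 s
    preceding the event), which must lie inside the kernel window.
    """
    lags = estimates.lags
    sel = (lags >= baseline_window[0]) & (lags < baseline_window[1])
    if not sel.any():
        raise ValidationError("baseline window lies outside the kernel window")
    out = {}
    nyq = estimates.rate / 2
    if lowpass < nyq:
        sos = signal.butter(order, lowpass, btype="lowpass", fs=estimates.rate,
                            output="sos")
        smooth = lambda k: signal.sosfiltfilt(sos, k)
    else:  # cutoff at/above Nyquist: nothing to remove
        smooth = lambda k: k.copy()
    for name, k in estimates.kernels.items():
        ks = smooth(k)
        out[name] = ks - ks[sel].mean()
    return KernelEstimates(
        lags.copy(), out, estimates.rate,
        residual_variance=estimates.residual_variance,
        r_squared=estimates.r_squared,
    )


def variance_partition(
    X: DesignMatrix,
    estimates: KernelEstimates,
    y: PupilTimeSeries | np.ndarray,
) -> tuple[dict[str, float], float]:
    """Fraction of explained variance contributed by each event type.

    The fitted contribution of type *c* is ``X_c h_c``; its variance,
    normalized by the summed variances over all types, gives fractions
    that are non-negative and sum to one (covariance cross-terms between
    types are excluded by construction).  Total R-squared of the full fit
    is returned separately.
    """
    yv = y.samples if isinstance(y, PupilTimeSeries) else np.asarray(y, dtype=float)
    contrib_var = {}
    fitted = np.zeros(X.n_samples)
    for t in X.event_types:
        if t not in estimates.kernels:
            raise ValidationError(f"no kernel estimate for event type {t!r}")
        part = X.block(t) @ estimates.kernels[t]
        fitted += part
        contrib_var[t] = float(np.var(part))
    total = sum(contrib_var.values())
    if total <= 0:
        raise DegenerateSignalError("zero total explained variance; partition undefined")
    fractions = {t: v / total for t, v in contrib_var.items()}
    var_y = float(np.var(yv))
    r2 = 1.0 - float(np.var(yv - fitted)) / var_y if var_y > 0 else np.nan
    return fractions, r2


@dataclass
class GroupKernels:
    """Pointwise group mean and standard error of per-subject kernels."""

    lags: np.ndarray
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_subjects: int


def group_average(estimates: list[KernelEstimates]) -> GroupKernels:
    """Average kernels across subjects; SEM uses the n-1 denominator."""
    if len(estimates) < 2:
        raise ValidationError("group averaging needs at least 2 subjects")
    lags = estimates[0].lags
    for est in estimates[1:]:
        if est.lags.shape != lags.shape or not np.allclose(est.lags, lags):
            raise ValidationError("subjects have mismatched lag axes")
    types = estimates[0].event_types
    mean, sem = {}, {}
    n = len(estimates)
    for t in types:
        stack = np.stack([est.kernels[t] for est in estimates])
        mean[t] = stack.mean(axis=0)
        sem[t] = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return GroupKernels(lags.copy(), mean, sem, n)
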