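"""Group-level inference on kernel time courses.

Cluster-based permutation testing handles the multiple-comparison
problem across kernel lags without parametric assumptions: per-lag t
statistics are thresholded (two-sided), contiguous suprathreshold lags
form clusters whose mass is the summed t, and the observed masses are
compared against the permutation null of the maximum cluster mass
(sign flips for one-sample tests, condition-label swaps — equivalently
sign flips of the paired differences — for paired tests).

The tonic-phasic interaction is probed by a median split: events are
partitioned at the median tonic level and each half is deconvolved
separately, with the ocular nuisance regressors retained in the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import EventTable, PupilTimeSeries, ValidationError
from .deconvolve import (
    KernelEstimates,
    build_design_matrix,
    postprocess_kernels,
    solve_fir,
)

__all__ = [
    "Cluster",
    "ClusterResult",
    "cluster_permutation_test",
    "MedianSplitResult",
    "median_split_by_tonic",
]

_EPS_VAR = 1e-12


@dataclass(frozen=True)
class Cluster:
    lag_start: float
    lag_end: float
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    test_type: str
    n_permutations: int
    seed: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def _t_rows(data_signed: np.ndarray) -> np.ndarray:
    """Row-wise one-sample t across subjects for (n_sub, n_lag) data."""
    n = data_signed.shape[0]
    m = data_signed.mean(axis=0)
    v = data_signed.var(axis=0, ddof=1)
    return m / np.sqrt(np.maximum(v, _EPS_VAR) / n)


def _clusters_from_t(tvals: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Contiguous suprathreshold runs, positive and negative separately."""
    out = []
    for mask in (tvals > thr, tvals < -thr):
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            out.append((i0, i1 - 1, float(tvals[i0:i1].sum())))
    out.sort(key=lambda c: c[0])
    return out


def _max_cluster_mass(T: np.ndarray, thr: float) -> np.ndarray:
    """Per-row maximum |cluster mass| for a (n_perm, n_lag) t matrix."""
    best = np.zeros(T.shape[0])
    for sign in (1.0, -1.0):
        sup = sign * T > thr
        run = np.zeros(T.shape[0])
        for j in range(T.shape[1]):
            run = np.where(sup[:, j], run + np.abs(T[:, j]), 0.0)
            best = np.maximum(best, run)
    return best


def cluster_permutation_test(
    data: np.ndarray,
    data2: np.ndarray | None = None,
    lags: np.ndarray | None = None,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test on subjects x lags data.

    One-sample (``data`` tested against 0) when ``data2`` is None, paired
    otherwise (the test then runs on per-subject differences).  The
    cluster-forming threshold is the two-sided per-lag t critical value
    at ``alpha_cluster`` with n-1 degrees of freedom; cluster mass is the
    summed t within the cluster, and p-values come from the permutation
    null of the maximum |mass|, ``p = (1 + #{null >= obs}) / (1 + n_perm)``.
    """
    data = np.asarray(data, dtype=float)
    test_type = "one_sample"
    if data2 is not None:
        data2 = np.asarray(data2, dtype=float)
        if data2.shape != data.shape:
            raise ValidationError("paired matrices must have identical shapes")
        data = data - data2
        test_type = "paired"
    if data.ndim != 2 or data.shape[0] < 5:
        raise ValidationError("need a subjects x lags matrix with >= 5 subjects")
    n_sub, n_lag = data.shape
    if lags is None:
        lags = np.arange(n_lag, dtype=float)
    thr = float(sps.t.ppf(1 - alpha_cluster / 2, df=n_sub - 1))

    t_obs = _t_rows(data)
    observed = _clusters_from_t(t_obs, thr)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    # t under sign flips: per-lag sum of squares is sign-invariant
    ssq = np.sum(data ** 2, axis=0)
    m = signs @ data / n_sub
    v = (ssq[None, :] - n_sub * m ** 2) / (n_sub - 1)
    T = m / np.sqrt(np.maximum(v, _EPS_VAR) / n_sub)
    null_max = _max_cluster_mass(T, thr)

    clusters = []
    for i0, i1, mass in observed:
        p = float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm))
        clusters.append(Cluster(float(lags[i0]), float(lags[i1]), mass, p))
    return ClusterResult(clusters, test_type, n_perm, seed)


@dataclass
class MedianSplitResult:
    """Kernels re-estimated for below- vs above-median tonic events."""

    low: KernelEstimates
    high: KernelEstimates
    amplitudes: dict[str, tuple[float, float]]
    median: float
    degenerate: bool = False


def median_split_by_tonic(
    events: EventTable,
    tonic_values: np.ndarray,
    phasic: PupilTimeSeries,
    split_types: tuple[str, ...] = ("sound_high", "sound_low"),
    nuisance_types: tuple[str, ...] = ("blink", "saccade"),
    window: tuple[float, float] = (-0.5, 5.0),
    amplitude_window: tuple[float, float] = (0.5, 2.5),
) -> MedianSplitResult:
    """Deconvolve separately for below- and above-median tonic events.

    ``tonic_values`` is aligned with the rows of ``events`` whose type is
    in ``split_types`` (in table order).  Events at exactly the median go
    to the low side.  Both halves are estimated in one joint design that
    retains the nuisance event types, then post-processed (4 Hz low-pass,
    baseline subtraction).  ``amplitudes`` maps each split type to the
    (low, high) mean kernel value over ``amplitude_window`` — by default
    0.5–2.5 s, bracketing the canonical auditory peak.
    """
    df = events.df
    is_split = df["type"].isin(split_types).to_numpy()
    tonic_values = np.asarray(tonic_values, dtype=float)
    if tonic_values.size != int(is_split.sum()):
        raise ValidationError("one tonic value per split-type event is required")
    finite = np.isfinite(tonic_values)
    if finite.sum() < 4:
        raise ValidationError("too few events with tonic values to split")

    degenerate = False
    med = float(np.median(tonic_values[finite]))
    low_mask = tonic_values <= med
    if np.all(low_mask[finite]) or not low_mask[finite].any():
        # all tonic values identical: fall back to event-order parity
        degenerate = True
        low_mask = (np.arange(tonic_values.size) % 2) == 0
        warnings.warn("degenerate tonic values; split by event-order parity",
                      stacklevel=2)

    relabeled = df.copy()
    labels = np.empty(len(df), dtype=object)
    labels[:] = df["type"].to_numpy()
    split_rows = np.flatnonzero(is_split)
    for j, row in enumerate(split_rows):
        side = "low" if low_mask[j] else "high"
        labels[row] = f"{df['type'].iloc[row]}|{side}"
    relabeled["type"] = labels
    relabeled_events = EventTable(relabeled)

    design_types = []
    for t in split_types:
        for side in ("low", "high"):
            name = f"{t}|{side}"
            if (relabeled["type"] == name).sum() < 2:
                warnings.warn(f"{name} has fewer than 2 events; omitted", stacklevel=2)
            else:
                design_types.append(name)
    design_types += [t for t in nuisance_types if t in events.types]

    X = build_design_matrix(
        relabeled_events.with_anchor_times(), len(phasic), phasic.sample_rate,
        window, design_types, phasic.start_time,
    )
    est = postprocess_kernels(solve_fir(X, phasic))

    def side_estimates(side: str) -> KernelEstimates:
        kernels = {
            t: est.kernels[f"{t}|{side}"]
            for t in split_types if f"{t}|{side}" in est.kernels
        }
        for t in nuisance_types:
            if t in est.kernels:
                kernels[t] = est.kernels[t]
        return KernelEstimates(est.lags, kernels, est.rate,
                               residual_variance=est.residual_variance,
                               r_squared=est.r_squared)

    low_est, high_est = side_estimates("low"), side_estimates("high")
    win = (est.lags >= amplitude_window[0]) & (est.lags < amplitude_window[1])
    amplitudes = {}
    for t in split_types:
        if t in low_est.kernels and t in high_est.kernels:
            amplitudes[t] = (
                float(low_est.kernels[t][win].mean()),
                float(high_est.kernels[t][win].mean()),
            )
    return MedianSplitResult(low_est, high_est, amplitudes, med, degenerate)
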