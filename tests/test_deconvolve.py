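"""FIR design construction, least-squares solve, variance partition."""

import numpy as np
import pytest

import pupilfir as pf
from pupilfir.deconvolve import dct_drift_basis, stack_designs


def naive_design(events, n_samples, rate, window, event_types):
    """Reference double-loop construction of the staggered design."""
    L = int(round((window[1] - window[0]) * rate))
    X = np.zeros((n_samples, len(event_types) * L))
    for c, etype in enumerate(event_types):
        for t in events.times_of(etype):
            for j in range(L):
                lag = window[0] + j / rate
                row = int(round((t + lag) * rate))
                if 0 <= row < n_samples:
                    X[row, c * L + j] += 1.0
    return X


class TestDesignMatrix:
    def test_standard_window_has_220_columns(self):
        ev = pf.EventTable.from_arrays(
            [1.0, 2.0, 3.0, 4.0],
            ["sound_high", "sound_low", "blink", "saccade"],
        )
        X = pf.build_design_matrix(ev, 100, 10.0, (-0.5, 5.0),
                                   ["sound_high", "sound_low", "blink", "saccade"])
        assert X.values.shape[1] == 220
        assert X.n_lags == 55
        assert X.lags[0] == pytest.approx(-0.5)
        assert X.lags[-1] == pytest.approx(4.9)

    def test_single_event_staggered_identity(self):
        ev = pf.EventTable.from_arrays([1.0], "sound_high")
        X = pf.build_design_matrix(ev, 20, 10.0, (0.0, 0.3))
        assert X.values.shape[1] == 3
        rows = [np.flatnonzero(X.values[:, j]) for j in range(3)]
        assert [r.size for r in rows] == [1, 1, 1]
        assert [int(r[0]) for r in rows] == [10, 11, 12]

    def test_matches_naive_double_loop(self, rng):
        for _ in range(20):
            n = int(rng.integers(50, 200))
            types = ["a", "b", "c"][: int(rng.integers(1, 4))]
            times, labels = [], []
            for t_ in types:
                k = int(rng.integers(1, 6))
                times += list(rng.uniform(0, n / 10.0, k))
                labels += [t_] * k
            ev = pf.EventTable.from_arrays(times, labels)
            window = (-0.3, 1.2)
            X = pf.build_design_matrix(ev, n, 10.0, window, types)
            assert np.array_equal(X.values, naive_design(ev, n, 10.0, window, types))

    def test_empty_type_warns_and_zero_block(self):
        ev = pf.EventTable.from_arrays([1.0], "a")
        with pytest.warns(UserWarning, match="no events"):
            X = pf.build_design_matrix(ev, 50, 10.0, (0.0, 0.5), ["a", "b"])
        assert not X.block("b").any()

    def test_bad_sizes_rejected(self):
        ev = pf.EventTable.from_arrays([1.0], "a")
        with pytest.raises(pf.ValidationError):
            pf.build_design_matrix(ev, 0, 10.0, (0.0, 0.5))
        with pytest.raises(pf.ValidationError):
            pf.build_design_matrix(ev, 10, 10.0, (0.5, 0.0))


class TestSolveFir:
    def well_posed_instance(self, rng, n=400, types=("a", "b")):
        times, labels = [], []
        for t_ in types:
            times += list(np.sort(rng.uniform(0, n / 10.0 - 2, 8)))
            labels += [t_] * 8
        ev = pf.EventTable.from_arrays(times, labels)
        return pf.build_design_matrix(ev, n, 10.0, (0.0, 1.0), list(types))

    def test_zero_signal_gives_zero_kernels(self, rng):
        X = self.well_posed_instance(rng)
        est = pf.solve_fir(X, np.zeros(X.n_samples))
        for k in est.kernels.values():
            assert np.allclose(k, 0.0)

    def test_noise_free_recovery_exact(self, rng):
        X = self.well_posed_instance(rng)
        h_true = rng.normal(0, 1, X.values.shape[1])
        y = X.values @ h_true
        est = pf.solve_fir(X, y)
        h_hat = np.concatenate([est.kernels[t] for t in X.event_types])
        assert np.abs(h_hat - h_true).max() < 1e-8

    def test_matches_pseudoinverse_oracle(self, rng):
        for _ in range(50):
            X = self.well_posed_instance(rng, n=int(rng.integers(200, 400)))
            y = rng.normal(0, 1, X.n_samples)
            est = pf.solve_fir(X, y)
            h_hat = np.concatenate([est.kernels[t] for t in X.event_types])
            h_ref = np.linalg.pinv(X.values.T @ X.values) @ X.values.T @ y
            assert np.abs(h_hat - h_ref).max() < 1e-8

    def test_linearity(self, rng):
        X = self.well_posed_instance(rng)
        y1 = rng.normal(0, 1, X.n_samples)
        y2 = rng.normal(0, 1, X.n_samples)
        a, b = 2.5, -0.7
        combo = pf.solve_fir(X, a * y1 + b * y2)
        e1, e2 = pf.solve_fir(X, y1), pf.solve_fir(X, y2)
        for t in X.event_types:
            assert np.allclose(
                combo.kernels[t], a * e1.kernels[t] + b * e2.kernels[t], atol=1e-9
            )

    def test_residuals_orthogonal_to_design(self, rng):
        X = self.well_posed_instance(rng)
        y = rng.normal(0, 1, X.n_samples)
        est = pf.solve_fir(X, y)
        h = np.concatenate([est.kernels[t] for t in X.event_types])
        resid = y - X.values @ h
        assert np.abs(X.values.T @ resid).max() < 1e-6 * np.linalg.norm(y)

    def test_rank_deficient_warns_minimum_norm(self):
        ev = pf.EventTable.from_arrays([1.0], "a")
        X = pf.build_design_matrix(ev, 5, 10.0, (0.0, 1.0))  # columns truncated
        with pytest.warns(UserWarning, match="rank-deficient|ill-conditioned"):
            est = pf.solve_fir(X, np.ones(5))
        assert np.isfinite(est.kernels["a"]).all()

    def test_dimension_mismatch_rejected(self, rng):
        X = self.well_posed_instance(rng)
        with pytest.raises(pf.ValidationError):
            pf.solve_fir(X, np.zeros(X.n_samples + 1))

    def test_drift_basis_absorbs_slow_trend(self, rng):
        X = self.well_posed_instance(rng, n=600)
        h_true = rng.normal(0, 1, X.values.shape[1])
        t = np.arange(X.n_samples) / 10.0
        drift = 2.0 * np.exp(-t / 20.0)
        X.nuisance = dct_drift_basis(X.n_samples, 10.0, 0.1)
        est = pf.solve_fir(X, X.values @ h_true + drift)
        h_hat = np.concatenate([est.kernels[tp] for tp in X.event_types])
        assert np.abs(h_hat - h_true).max() < 0.02


class TestPostprocess:
    def make(self, values):
        lags = -0.5 + np.arange(55) / 10.0
        return pf.KernelEstimates(lags, {"a": values}, rate=10.0)

    def test_constant_kernel_becomes_zero(self):
        est = pf.postprocess_kernels(self.make(np.full(55, 3.0)))
        assert np.allclose(est.kernels["a"], 0.0, atol=1e-9)

    def test_smooth_baselined_kernel_nearly_unchanged(self, canonical):
        lags = -0.5 + np.arange(55) / 10.0
        k = canonical["auditory"](lags)
        est = pf.postprocess_kernels(self.make(k))
        assert np.abs(est.kernels["a"] - k).max() < 0.01 * np.abs(k).max() + 5e-3

    def test_baseline_outside_window_rejected(self):
        with pytest.raises(pf.ValidationError):
            pf.postprocess_kernels(self.make(np.zeros(55)),
                                   baseline_window=(-3.0, -2.0))


class TestVariancePartition:
    def test_single_type_full_fraction(self, rng):
        ev = pf.EventTable.from_arrays(np.sort(rng.uniform(0, 30, 10)), "a")
        X = pf.build_design_matrix(ev, 400, 10.0, (0.0, 1.0))
        y = rng.normal(0, 1, 400)
        est = pf.solve_fir(X, y)
        fractions, r2 = pf.variance_partition(X, est, y)
        assert fractions["a"] == pytest.approx(1.0)
        assert 0 <= r2 <= 1

    def test_zero_gain_type_gets_tiny_fraction(self, canonical, rng):
        # signal contains only type-a responses; type-b events present but inert
        ta = np.sort(rng.uniform(1, 25, 8))
        tb = np.sort(rng.uniform(1, 25, 8))
        ev = pf.EventTable.from_arrays(
            np.concatenate([ta, tb]), ["a"] * 8 + ["b"] * 8
        )
        n = 300
        y = np.zeros(n)
        grid = np.arange(n) / 10.0
        for t0 in ta:
            y += canonical["auditory"](grid - t0)
        X = pf.build_design_matrix(ev, n, 10.0, (-0.5, 5.0), ["a", "b"])
        est = pf.solve_fir(X, y)
        fractions, _ = pf.variance_partition(X, est, y)
        assert fractions["b"] < 0.01
        assert sum(fractions.values()) == pytest.approx(1.0)


class TestGroupAverage:
    def lagged(self, values):
        lags = np.arange(len(values)) / 10.0
        return pf.KernelEstimates(lags, {"a": np.asarray(values, float)}, 10.0)

    def test_identical_subjects_zero_sem(self):
        ests = [self.lagged([1.0, 2.0, 3.0])] * 3
        ga = pf.group_average(ests)
        assert np.allclose(ga.sem["a"], 0.0)
        assert np.allclose(ga.mean["a"], [1, 2, 3])

    def test_opposite_kernels_cancel(self):
        ga = pf.group_average([self.lagged([1, -2]), self.lagged([-1, 2])])
        assert np.allclose(ga.mean["a"], 0.0)

    def test_mismatched_lags_rejected(self):
        with pytest.raises(pf.ValidationError):
            pf.group_average([self.lagged([1, 2]), self.lagged([1, 2, 3])])


class TestStackDesigns:
    def test_nuisance_is_block_diagonal(self, rng):
        ev = pf.EventTable.from_arrays([1.0, 3.0], "a")
        d1 = pf.build_design_matrix(ev, 60, 10.0, (0.0, 0.5), drift_cutoff=0.1)
        d2 = pf.build_design_matrix(ev, 80, 10.0, (0.0, 0.5), drift_cutoff=0.1)
        s = stack_designs([d1, d2])
        assert s.values.shape[0] == 140
        n1 = d1.nuisance.shape[1]
        assert np.allclose(s.nuisance[:60, :n1], d1.nuisance)
        assert np.allclose(s.nuisance[:60, n1:], 0.0)
        assert np.allclose(s.nuisance[60:, n1:], d2.nuisance)
        assert np.allclose(s.nuisance[60:, :n1], 0.0)
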