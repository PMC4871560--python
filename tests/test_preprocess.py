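"""Preprocessing: blink repair, filtering, normalization, resampling."""

import numpy as np
import pytest
from scipy import signal

import pupilfir as pf


def series(samples, rate=100.0, valid=None):
    return pf.PupilTimeSeries(np.asarray(samples, float), rate, valid=valid)


class TestDetectBlinks:
    def test_invalid_run_becomes_blink(self):
        valid = np.ones(1000, bool)
        valid[200:320] = False  # 120 ms at 1 kHz
        ts = series(np.ones(1000), 1000.0, valid=valid)
        ev = pf.detect_blinks(ts, min_gap=0.05)
        assert len(ev) == 1
        assert ev.df["duration_s"].iloc[0] == pytest.approx(0.120)
        assert ev.df["time_s"].iloc[0] == pytest.approx(0.200)

    def test_fully_valid_gives_empty_table(self):
        assert len(pf.detect_blinks(series(np.ones(100)))) == 0

    def test_all_invalid_rejected(self):
        ts = series(np.ones(100), valid=np.zeros(100, bool))
        with pytest.raises(pf.DegenerateSignalError):
            pf.detect_blinks(ts)

    def test_injected_dropouts_recovered(self):
        spec = pf.ExperimentSpec(run_duration=60.0, noise_sd=0.0)
        ts, truth = pf.simulate_session(spec, 7)
        blinks = truth.events.select(["blink"])
        detected = pf.detect_blinks(ts, min_gap=0.05)
        assert len(detected) == len(blinks)
        # onsets within one sample of the injected dropout window start
        errs = np.abs(detected.df["time_s"].to_numpy()
                      - (blinks.df["time_s"].to_numpy() - 0.02))
        assert np.all(errs <= 1.5 / ts.sample_rate)


class TestInterpolateBlinks:
    def test_linear_signal_restored_exactly(self):
        t = np.arange(1000) / 100.0
        ts = series(2.0 * t, 100.0)
        blinks = pf.EventTable.from_arrays([4.0], "blink", durations=[0.5])
        out = pf.interpolate_blinks(ts, blinks)
        assert np.allclose(out.samples, 2.0 * t, atol=1e-12)

    def test_touching_windows_merge_into_one_span(self):
        ts = series(np.zeros(1000), 100.0)
        ts.samples[395:425] = 99.0  # garbage the pads must cover
        blinks = pf.EventTable.from_arrays([4.0, 4.2], "blink", durations=[0.05, 0.05])
        out = pf.interpolate_blinks(ts, blinks)
        assert np.allclose(out.samples, 0.0, atol=1e-12)

    def test_edge_window_holds_nearest_value(self):
        ts = series(np.linspace(5, 6, 500), 100.0)
        blinks = pf.EventTable.from_arrays([0.0], "blink", durations=[0.3])
        out = pf.interpolate_blinks(ts, blinks)
        i_end = int((0.3 + 0.15) * 100)
        assert np.allclose(out.samples[: i_end + 1], out.samples[i_end + 1])

    def test_blink_covering_recording_rejected(self):
        ts = series(np.ones(50), 100.0, valid=np.zeros(50, bool))
        blinks = pf.EventTable.from_arrays([0.0], "blink", durations=[0.5])
        with pytest.raises(pf.DegenerateSignalError):
            pf.interpolate_blinks(ts, blinks)

    def test_dropout_repair_bounded_against_clean_truth(self):
        spec = pf.ExperimentSpec(run_duration=120.0, noise_sd=0.0)
        ts, truth = pf.simulate_session(spec, 3)
        out = pf.interpolate_blinks(ts, truth.events.select(["blink"]))
        assert out.valid.all()
        # within interpolated spans the repaired signal stays within the
        # range of the clean trace (lines join on-curve boundary points)
        dev = np.abs(out.samples - truth.clean)
        assert dev.max() < 1.0  # bounded by the blink response excursion


class TestFilters:
    def test_bandpass_preserves_inband_sinusoid(self):
        t = np.arange(0, 300, 0.01)
        ts = series(np.sin(2 * np.pi * 1.0 * t), 100.0)
        out = pf.bandpass_phasic(ts)
        mid = slice(5000, -5000)
        amp = out.samples[mid].max()
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_bandpass_removes_dc(self):
        ts = series(np.full(30000, 7.5), 100.0)
        out = pf.bandpass_phasic(ts)
        assert np.max(np.abs(out.samples[2000:-2000])) < 1e-6 * 7.5

    def test_bandpass_attenuates_10hz_like_butterworth(self):
        t = np.arange(0, 120, 0.001)
        ts = series(np.sin(2 * np.pi * 10.0 * t), 1000.0)
        out = pf.bandpass_phasic(ts)
        # attenuation at least the analytic single-pass order-3 magnitude
        mid = slice(30000, -30000)
        amp = 2 * np.abs(np.dot(out.samples[mid],
                                np.exp(-2j * np.pi * 10 * t[mid]))) / t[mid].size
        assert amp <= 1.0 / np.sqrt(1.0 + (10.0 / 4.0) ** 6)

    def test_tonic_passes_constant(self):
        ts = series(np.full(200000, 4.2), 1000.0)
        out = pf.extract_tonic(ts)
        assert np.allclose(out.samples[5000:-5000], 4.2, atol=1e-6 * 4.2)

    def test_tonic_rejects_1hz(self):
        # long record so the 0.02 Hz filter's edge transients die out
        t = np.arange(0, 600, 0.01)
        ts = series(np.sin(2 * np.pi * t), 100.0)
        out = pf.extract_tonic(ts)
        assert np.abs(out.samples[20000:-20000]).max() < 1e-3

    def test_tonic_tracks_slow_exponential(self):
        t = np.arange(0, 600, 0.01)
        ts = series(np.exp(-t / 120.0), 100.0)
        out = pf.extract_tonic(ts)
        mid = slice(6000, -6000)
        rel = np.abs(out.samples[mid] - ts.samples[mid]) / ts.samples[mid]
        assert rel.max() < 0.05

    def test_zero_phase_no_lag(self):
        t = np.arange(0, 120, 0.01)
        x = np.sin(2 * np.pi * 0.5 * t)
        out = pf.bandpass_phasic(series(x, 100.0))
        xc = signal.correlate(out.samples[2000:-2000], x[2000:-2000], mode="full")
        lag = np.argmax(xc) - (len(x[2000:-2000]) - 1)
        assert abs(lag) <= 1

    def test_phasic_plus_tonic_reconstructs_signal(self, rng):
        # broadband input: slow drift + event responses (no measurement
        # noise, whose super-4 Hz energy belongs to neither band)
        spec = pf.ExperimentSpec(run_duration=150.0, dropout=False, noise_sd=0.0)
        ts, _ = pf.simulate_session(spec, 99)
        phasic = pf.bandpass_phasic(ts)
        tonic = pf.extract_tonic(ts)
        resid = ts.samples - phasic.samples - tonic.samples
        mid = slice(10000, -10000)
        rms = np.sqrt(np.mean(resid[mid] ** 2))
        assert rms < 0.10 * np.sqrt(np.mean(ts.samples[mid] ** 2))


class TestNormalize:
    def test_single_segment_standardized(self, rng):
        seg = series(rng.normal(5, 2, 1000))
        (out,) = pf.normalize([seg], ["s0"])
        assert out.samples.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.samples.std() == pytest.approx(1.0)
        assert out.units_tag == "zscored"

    def test_session_shares_one_divisor(self, rng):
        a = series(rng.normal(5, 1, 1000))
        b = series(rng.normal(-5, 3, 1000))
        oa, ob = pf.normalize([a, b], ["s0", "s0"])
        assert oa.samples.mean() == pytest.approx(0.0, abs=1e-12)
        ratio = ob.samples.std() / oa.samples.std()
        assert ratio == pytest.approx(b.samples.std() / a.samples.std(), rel=1e-9)

    def test_scale_invariance(self, rng):
        segs = [series(rng.normal(0, 1, 500)), series(rng.normal(2, 3, 500))]
        out1 = pf.normalize(segs, ["s", "s"])
        scaled = [s.with_samples(10.0 * s.samples) for s in segs]
        out2 = pf.normalize(scaled, ["s", "s"])
        for o1, o2 in zip(out1, out2):
            assert np.allclose(o1.samples, o2.samples, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(pf.DegenerateSignalError):
            pf.normalize([series(np.ones(10))], ["s"])


class TestResample:
    def test_constant_preserved(self):
        out = pf.resample_to(series(np.full(5000, 3.3), 1000.0), 10.0)
        assert np.allclose(out.samples, 3.3)
        assert out.sample_rate == 10.0

    def test_output_length(self):
        out = pf.resample_to(series(np.zeros(100000), 1000.0), 10.0)
        assert len(out) == 1000

    def test_sinusoid_matches_analytic_at_grid(self):
        t = np.arange(0, 30, 0.001)
        out = pf.resample_to(series(np.sin(2 * np.pi * t), 1000.0), 10.0)
        expected = np.sin(2 * np.pi * out.times)
        assert np.abs(out.samples - expected).max() < 0.02

    def test_non_integer_ratio_uses_interpolation(self):
        t = np.arange(0, 10, 1 / 250.0)
        out = pf.resample_to(series(t.copy(), 250.0), 60.0)
        assert out.sample_rate == 60.0
        assert np.allclose(out.samples, out.times, atol=1e-9)


class TestTonicAtEvents:
    def test_constant_tonic_gives_zero_scores(self):
        tonic = series(np.ones(2000), 100.0)
        ev = pf.EventTable.from_arrays([5.0, 10.0, 15.0], "sound_high")
        with pytest.warns(UserWarning):
            vals = pf.tonic_at_events(tonic, ev)
        assert np.allclose(vals, 0.0)

    def test_ramp_orders_events(self):
        t = np.arange(2000) / 100.0
        tonic = series(t.copy(), 100.0)
        ev = pf.EventTable.from_arrays([5.0, 15.0], "sound_high")
        vals = pf.tonic_at_events(tonic, ev)
        assert vals[1] > vals[0]

    def test_window_means_match_analytic(self):
        # linear tonic: mean over [-0.5, 0) is value at centre t-0.25
        t = np.arange(30000) / 100.0
        tonic = series(0.01 * t, 100.0)
        times = np.array([10.0, 50.0, 120.0, 250.0])
        ev = pf.EventTable.from_arrays(times, "sound_high")
        raw = []
        for et in times:
            sel = (t >= et - 0.5) & (t < et)
            raw.append(0.01 * t[sel].mean())
        raw = np.array(raw)
        expect = (raw - raw.mean()) / raw.std()
        got = pf.tonic_at_events(tonic, ev)
        assert np.allclose(got, expect, atol=1e-3)

    def test_event_without_overlap_excluded(self):
        tonic = series(np.ones(100), 100.0)  # 1 s recording
        ev = pf.EventTable.from_arrays([10.0], "sound_high")
        vals = pf.tonic_at_events(tonic, ev)
        assert np.isnan(vals[0])
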