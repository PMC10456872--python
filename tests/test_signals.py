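"""Signal cleaning, event detection and resampling."""

import numpy as np
import pytest

from barogeo import signals as sig
from barogeo.pipeline import extract_record
from barogeo.simulate import SimConfig, simulate_subject


def _record(**channels):
    fs = channels.pop("fs", 100.0)
    return sig.PhysioRecord({k: np.asarray(v, float) for k, v in channels.items()}, fs=fs)


def _ecg(bpm, duration_s, fs):
    """Template ECG with beats at exactly 60/bpm spacing."""
    t = np.arange(int(duration_s * fs)) / fs
    beat_times = np.arange(0.5, duration_s - 0.2, 60.0 / bpm)
    ecg = np.zeros_like(t)
    for bt in beat_times:
        ecg += np.exp(-0.5 * ((t - bt) / 0.010) ** 2)
    return ecg, beat_times


class TestDetrendAndClean:
    def test_removes_pure_linear_trend(self):
        rec = _record(ecg=np.linspace(1, 5, 200) + np.sin(np.arange(200)))
        out = sig.detrend_and_clean(rec)
        x = out.channels["ecg"]
        # residual has no linear component left
        slope = np.polyfit(np.arange(200), x, 1)[0]
        assert abs(slope) < 1e-10

    def test_spike_replaced_matches_direct_masking(self, rng):
        x = rng.normal(size=500)
        x[250] = 10 * x.std()
        out = sig.detrend_and_clean(_record(ecg=x.copy()))
        # reference: apply the 3-SD rule by direct masking + interpolation
        from scipy.signal import detrend
        y = detrend(x, type="linear")
        bad = np.abs(y - y.mean()) >= 3 * y.std()
        assert bad[250]
        good = ~bad
        expected = y.copy()
        expected[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), y[good])
        np.testing.assert_allclose(out.channels["ecg"], expected, atol=1e-12)
        assert out.n_samples == 500

    def test_degenerate_channel_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            sig.detrend_and_clean(_record(ecg=np.full(100, 3.0)))

    def test_empty_record_errors(self):
        with pytest.raises(ValueError):
            sig.PhysioRecord({"ecg": np.array([])}, fs=100)


class TestDetectRpeaks:
    @pytest.mark.parametrize("bpm,tol_ms", [(60, 10), (80, 10)])
    def test_fixed_rate_ecg(self, bpm, tol_ms):
        fs = 250.0
        ecg, truth = _ecg(bpm, 60, fs)
        times = sig.detect_rpeaks(ecg, fs)
        intervals = np.diff(times) * 1000
        assert np.all(np.abs(intervals - 60000.0 / bpm) < tol_ms)
        # peaks per minute within one beat of the truth
        assert abs(times.size - truth.size) <= 1

    def test_flat_line_errors(self):
        with pytest.raises(ValueError, match="no QRS"):
            sig.detect_rpeaks(np.zeros(1000), 250.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            sig.detect_rpeaks(np.random.default_rng(0).normal(size=100), 250.0)


class TestExtractBbi:
    def test_direct_differencing(self):
        s = sig.extract_bbi(np.array([0.0, 1.0, 2.5]))
        np.testing.assert_allclose(s.values, [1000.0, 1500.0])
        np.testing.assert_allclose(s.timestamps, [1.0, 2.5])

    def test_uniform_peaks(self):
        s = sig.extract_bbi(np.arange(0, 8, 0.8))
        np.testing.assert_allclose(s.values, 800.0)

    def test_too_few_peaks_errors(self):
        with pytest.raises(ValueError):
            sig.extract_bbi(np.array([0.0, 1.0]))


class TestExtractSbpDbp:
    def test_sinusoid_extrema(self):
        fs = 500.0
        t = np.arange(int(fs)) / fs
        bp = 100 + 20 * np.sin(2 * np.pi * t)
        sbp, dbp = sig.extract_sbp_dbp(bp, fs, np.array([0.0, 1.0]))
        assert sbp.values[0] == pytest.approx(120, abs=0.01)
        assert dbp.values[0] == pytest.approx(80, abs=0.01)

    def test_constant_bp(self):
        sbp, dbp = sig.extract_sbp_dbp(np.full(300, 90.0), 100.0, np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(sbp.values, 90.0)
        np.testing.assert_allclose(dbp.values, 90.0)

    def test_beat_window_conservation(self, rng):
        fs = 100.0
        bp = 100 + rng.normal(size=1000)
        peaks = np.sort(rng.uniform(0, 10, size=12))
        sbp, dbp = sig.extract_sbp_dbp(bp, fs, peaks)
        assert len(sbp) == len(dbp)
        assert len(sbp) <= peaks.size - 1


class TestExtractTt:
    def test_quarter_hz_sinusoid(self):
        fs = 50.0
        t = np.arange(int(60 * fs)) / fs
        s = sig.extract_tt(np.sin(2 * np.pi * 0.25 * t), fs)
        # first/last cycles see filter edge effects; all stay close and
        # interior cycles are exact
        np.testing.assert_allclose(s.values, 4.0, atol=0.02)
        np.testing.assert_allclose(s.values[1:-1], 4.0, atol=1e-4)

    def test_constant_flow_errors(self):
        with pytest.raises(ValueError):
            sig.extract_tt(np.full(1000, 2.0), 50.0)


class TestResample:
    def test_linear_interpolation_midpoint(self):
        s = sig.EventSeries("SBP", [10.0, 20.0], [0.0, 2.0])
        out = sig.resample_series(s, 1.0)
        np.testing.assert_allclose(out.values, [10.0, 15.0, 20.0])
        assert out.grid_hz == 1.0

    def test_constant_series_stays_constant(self):
        s = sig.EventSeries("SBP", np.full(100, 7.0), np.arange(100) * 0.9)
        for hz in (1.0, 0.25):
            out = sig.resample_series(s, hz)
            np.testing.assert_allclose(out.values, 7.0, atol=1e-9)

    def test_decimation_length(self):
        s = sig.EventSeries("SBP", np.sin(np.arange(600) * 0.01) + 2, np.arange(600.0))
        one = sig.resample_series(s, 1.0)
        assert len(one) == 600
        quarter = sig.resample_series(one, 0.25)
        assert len(quarter) == 150
        assert quarter.grid_hz == 0.25

    def test_round_trip_uniform_grid(self, rng):
        vals = rng.normal(size=50) + 5
        s = sig.EventSeries("SBP", vals, np.arange(50.0))
        out = sig.resample_series(s, 1.0)
        np.testing.assert_allclose(out.values, vals, atol=1e-9)

    def test_bad_target_errors(self):
        s = sig.EventSeries("SBP", [1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            sig.resample_series(s, 2.0)


class TestEventSeriesInvariants:
    def test_bbi_positivity_enforced(self):
        with pytest.raises(ValueError):
            sig.EventSeries("BBI", [800.0, -5.0], [0.0, 1.0])

    def test_nonmonotone_timestamps_rejected(self):
        with pytest.raises(ValueError):
            sig.EventSeries("SBP", [1.0, 2.0], [1.0, 1.0])


class TestGroundTruthExtraction:
    """Raw-signal round trip: extraction recovers the generator's truth."""

    @pytest.fixture(scope="class")
    @staticmethod
    def extracted():
        cfg = SimConfig(seed=3, duration_s=120.0)
        record, gt = simulate_subject(cfg, "CON", seed=7)
        return extract_record(record), gt, cfg

    def test_bbi_matches_truth(self, extracted):
        series, gt, cfg = extracted
        got = series["BBI"]
        truth_t = gt.beat_times_s[1:]
        # match each detected interval to the nearest true beat (the
        # edge-truncated first beat may be missed by the detector)
        j = np.argmin(np.abs(truth_t[None, :] - got.timestamps[:, None]), axis=1)
        near = np.abs(truth_t[j] - got.timestamps) < 0.1
        assert near.mean() > 0.95
        mae = np.abs(got.values[near] - gt.bbi_ms[j[near]]).mean()
        assert mae < 1000.0 / cfg.fs  # below one raw sample period (ms)

    def test_tt_matches_truth(self, extracted):
        series, gt, _ = extracted
        got = series["TT"]
        assert abs(got.values.mean() - gt.tt_s.mean()) < 0.1

    def test_sbp_matches_injected(self, extracted):
        series, gt, _ = extracted
        got = series["SBP"]
        assert abs(got.values.mean() - gt.params.sbp_set_mmhg) < 2.0


class TestCsvRoundTrip:
    def test_event_series_round_trip(self, tmp_path, subject_series):
        series, _ = subject_series
        path = tmp_path / "events.csv"
        sig.write_event_series_csv(list(series.values()), path, "S1")
        back = sig.read_event_series_csv(path)
        assert set(back["S1"]) == {"BBI", "SBP", "DBP", "TT"}
        np.testing.assert_allclose(back["S1"]["BBI"].values, series["BBI"].values)
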