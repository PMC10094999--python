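"""Resampling, filtering, peak detection and binning."""

import numpy as np
import pytest

from calmdx.errors import ValidationError
from calmdx.trace_analysis import (
    BinnedSeries,
    UniformTrace,
    bandpass,
    bin_series,
    build_peak_raster,
    detect_peaks,
    lowpass,
    pool_roi_bins,
    resample_uniform,
)
from oracles import naive_bin_means, naive_peak_scan


class TestResample:
    def test_constant_trace_preserved(self):
        t = np.arange(100) / 10.0
        out = resample_uniform(np.full(100, 3.0), t, 5.0)
        np.testing.assert_allclose(out.values, 3.0)
        assert out.rate_hz == 5.0 and not out.gap_mask.any()

    def test_pairwise_means(self):
        t = np.arange(20) / 10.0
        vals = np.tile([0.0, 2.0], 10)
        out = resample_uniform(vals, t, 5.0)
        np.testing.assert_allclose(out.values, 1.0)

    def test_irregular_rate_matches_membership_oracle(self):
        rng = np.random.default_rng(4)
        fs = 9.73
        t = np.arange(2000) / fs - 60.0
        vals = rng.normal(size=t.size)
        out = resample_uniform(vals, t, 5.0)
        k_lo = int(np.floor(t[0] * 5.0 + 1e-9))
        want, counts = naive_bin_means(vals, t, 0.2, k_lo, out.values.size)
        np.testing.assert_allclose(out.values, want, rtol=1e-12)

    def test_gap_flagged_not_interpolated(self):
        t = np.concatenate([np.arange(50), np.arange(100, 150)]) / 10.0
        out = resample_uniform(np.ones(100), t, 5.0)
        assert out.gap_mask.sum() == 25  # 5 s gap at 5 Hz
        assert np.isnan(out.values[out.gap_mask]).all()

    def test_upsampling_rejected(self):
        t = np.arange(100) / 5.0
        with pytest.raises(ValidationError):
            resample_uniform(np.zeros(100), t, 10.0)

    def test_mean_preserved_without_gap(self):
        rng = np.random.default_rng(9)
        t = np.arange(1000) / 10.0
        vals = rng.normal(2.0, 1.0, size=1000)
        out = resample_uniform(vals, t, 5.0)
        assert out.values.mean() == pytest.approx(vals.mean(), abs=1e-12)


class TestFilters:
    def test_lowpass_preserves_dc(self):
        tr = UniformTrace(np.full(500, 4.2), 5.0, 0.0)
        out = lowpass(tr, 0.02)
        np.testing.assert_allclose(out.values, 4.2, atol=1e-9)

    def test_lowpass_attenuates_fast_sine(self):
        t = np.arange(5000) / 5.0
        tr = UniformTrace(np.sin(2 * np.pi * 1.0 * t), 5.0, 0.0)
        out = lowpass(tr, 0.02)
        mid = out.values[500:-500]
        assert np.abs(mid).max() < 1.0 / 100

    def test_lowpass_cutoff_above_nyquist_rejected(self):
        tr = UniformTrace(np.zeros(100), 5.0, 0.0)
        with pytest.raises(ValidationError):
            lowpass(tr, 3.0)

    def test_bandpass_removes_dc(self):
        tr = UniformTrace(np.full(2000, 10.0), 10.0, 0.0)
        out = bandpass(tr)
        assert np.abs(out.values).max() < 1e-6

    def test_bandpass_passes_1hz(self):
        t = np.arange(8000) / 10.0
        tr = UniformTrace(np.sin(2 * np.pi * 1.0 * t), 10.0, 0.0)
        out = bandpass(tr)
        mid = out.values[1000:-1000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_bandpass_at_5hz_rate_rejected(self):
        tr = UniformTrace(np.zeros(1000), 5.0, 0.0)
        with pytest.raises(ValidationError, match="native"):
            bandpass(tr, 0.17, 4.5)

    def test_filters_respect_gap_segments(self):
        gap = np.zeros(400, bool)
        gap[150:250] = True
        vals = np.where(gap, np.nan, 1.0)
        tr = UniformTrace(vals, 10.0, 0.0, gap_mask=gap)
        out = lowpass(tr, 0.02)
        assert np.isnan(out.values[gap]).all()
        np.testing.assert_allclose(out.values[~gap], 1.0, atol=1e-6)


class TestDetectPeaks:
    def test_constant_trace_no_peaks(self):
        tr = UniformTrace(np.full(100, 5.0), 10.0, 0.0)
        times, thr = detect_peaks(tr)
        assert times.size == 0 and thr == 5.0

    def test_single_rectangular_excursion(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.1, size=500)
        vals[200:205] += 50.0
        vals[202] += 1.0  # run maximum
        tr = UniformTrace(vals, 10.0, -10.0)
        times, thr = detect_peaks(tr)
        assert times.size == 1
        assert times[0] == pytest.approx(-10.0 + 202 / 10.0)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_run_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=300) + 5 * (rng.random(300) < 0.02)
        tr = UniformTrace(vals, 10.0, 0.0)
        times, thr = detect_peaks(tr)
        idx_want, thr_want = naive_peak_scan(vals)
        assert thr == pytest.approx(thr_want)
        np.testing.assert_allclose(times, idx_want / 10.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            detect_peaks(UniformTrace(np.ones(5), 10.0, 0.0))

    def test_offset_invariance_through_bandpass(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=3000) + 8 * (rng.random(3000) < 0.01)
        a = bandpass(UniformTrace(vals, 10.0, 0.0))
        b = bandpass(UniformTrace(vals + 123.4, 10.0, 0.0))
        ta, _ = detect_peaks(a)
        tb, _ = detect_peaks(b)
        np.testing.assert_allclose(ta, tb)


class TestBinSeries:
    def test_events_in_one_bin(self):
        events = np.array([60.0, 70, 80, 90, 100, 110, 120])  # all in [1,3) min... 5-min bin 0
        out = bin_series(events, 5.0, "peak_count", span_min=(0.0, 20.0))
        np.testing.assert_array_equal(out.values, [7, 0, 0, 0])

    def test_edge_event_goes_to_later_bin(self):
        events = np.array([300.0])  # exactly 5 min
        out = bin_series(events, 5.0, "peak_count", span_min=(0.0, 15.0))
        np.testing.assert_array_equal(out.values, [0, 1, 0])

    def test_constant_trace_bins(self):
        t = np.arange(6000) / 10.0
        tr = resample_uniform(np.full(6000, 4.0), t, 5.0)
        out = bin_series(tr, 5.0, "dff_mean", span_min=(0.0, 10.0))
        np.testing.assert_allclose(out.values, 4.0)

    def test_count_conservation(self):
        rng = np.random.default_rng(8)
        events = rng.uniform(0, 1800, size=137)
        out = bin_series(events, 5.0, "peak_count", span_min=(0.0, 30.0))
        assert out.values.sum() == 137

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            bin_series(np.array([1.0]), 0.0, "peak_count", span_min=(0, 5))


class TestPoolRoiBins:
    def _series(self, vals):
        edges = np.arange(len(vals) + 1) * 5.0
        return BinnedSeries(edges, vals, "dff_mean")

    def test_row_count(self):
        sessions = [
            ("formalin", f"m{m}", {r: self._series([1.0, 2, 3, 4]) for r in range(3)})
            for m in range(2)
        ]
        table = pool_roi_bins(sessions, 5.0)
        assert len(table) == 2 * 3 * 4
        assert set(table.columns) == {"group", "mouse", "roi_id", "bin_start_min", "value"}

    def test_mismatched_grid_rejected(self):
        s1 = ("formalin", "m0", {1: self._series([1.0, 2])})
        bad = BinnedSeries(np.array([0.0, 10.0]), np.array([1.0]), "dff_mean")
        s2 = ("pbs", "m1", {1: bad})
        with pytest.raises(ValidationError):
            pool_roi_bins([s1, s2], 5.0)

    def test_whole_frame_pseudo_roi_excluded(self):
        sessions = [("formalin", "m0", {"w": self._series([1.0, 2])})]
        with pytest.warns(UserWarning, match="'w'"):
            table = pool_roi_bins(sessions, 5.0)
        assert table.empty


class TestPeakRaster:
    def test_global_threshold_shared_across_rois(self):
        rng = np.random.default_rng(21)
        traces = {0: rng.normal(size=2000),
                  1: 5.0 * rng.normal(size=2000)}  # very different scales
        raster = build_peak_raster(traces, native_rate_hz=10.0, t0_s=0.0,
                                   threshold_scope="global")
        thrs = list(raster.thresholds.values())
        assert thrs[0] == thrs[1]
        per_roi = build_peak_raster(traces, native_rate_hz=10.0, t0_s=0.0)
        assert per_roi.thresholds[0] != per_roi.thresholds[1]

    def test_baseline_stat_window(self):
        rng = np.random.default_rng(22)
        vals = rng.normal(size=4000)
        vals[2000:] += 3.0  # post-stim elevation inflates the whole-trace SD
        tr_all = UniformTrace(vals, 10.0, -200.0)
        _, thr_all = detect_peaks(tr_all)
        _, thr_base = detect_peaks(tr_all, stat_window_s=(-200.0, 0.0))
        assert thr_base < thr_all

    def test_total_count_equals_binned_sum(self):
        rng = np.random.default_rng(12)
        traces = {i: rng.normal(size=6000) + 10 * (rng.random(6000) < 0.005)
                  for i in range(3)}
        raster = build_peak_raster(traces, native_rate_hz=10.0, t0_s=0.0)
        total = sum(len(v) for v in raster.peaks.values())
        binned = [bin_series(raster.peaks[i], 5.0, "peak_count", span_min=(0.0, 10.0))
                  for i in raster.peaks]
        assert sum(b.values.sum() for b in binned) == total
        assert raster.span_min == (0.0, pytest.approx(599.9 / 60.0, abs=1e-6))
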