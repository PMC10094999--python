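"""Resampling, filtering, peak detection and binning of %dF/F0 traces.

Peaks are supra-threshold excursions of the bandpass (0.17-4.5 Hz) filtered
trace, with threshold mean + 2 SD; each maximal contiguous run of samples
strictly above threshold contributes exactly one peak, timestamped at the run
maximum.  The bandpass must run at the native frame rate (~10 Hz): at the 5 Hz
visualization resolution the 4.5 Hz band edge would exceed Nyquist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from calmdx.errors import ValidationError

logger = logging.getLogger(__name__)

PEAK_BAND_HZ = (0.17, 4.5)
PEAK_K_SD = 2.0


@dataclass
class UniformTrace:
    """Uniformly sampled trace; gap bins (no native samples, e.g. the removed
    artifact segment) are NaN with gap_mask True, never interpolated."""

    values: np.ndarray
    rate_hz: float
    t0_s: float
    gap_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.shape, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.values.shape:
            raise ValidationError("gap_mask / values length mismatch")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.rate_hz


@dataclass
class PeakRaster:
    """Per-ROI peak times (s) and the per-ROI detection thresholds."""

    peaks: dict
    thresholds: dict
    band_hz: tuple[float, float] = PEAK_BAND_HZ
    span_min: tuple[float, float] | None = None  # analysis window covered

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"roi_id": rid, "peak_time_s": t}
            for rid, times in self.peaks.items()
            for t in times
        ]
        return pd.DataFrame(rows, columns=["roi_id", "peak_time_s"])


@dataclass
class BinnedSeries:
    """Values on contiguous [start, end) bins; a bin edge falls at t=0."""

    bin_edges_min: np.ndarray
    values: np.ndarray
    kind: str  # dff_mean | peak_count | licking_s | serotonin

    def __post_init__(self) -> None:
        self.bin_edges_min = np.asarray(self.bin_edges_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_edges_min.size != self.values.size + 1:
            raise ValidationError("need len(values)+1 bin edges")
        if self.bin_edges_min.size > 1 and not np.all(np.diff(self.bin_edges_min) > 0):
            raise ValidationError("bin edges must be strictly increasing")

    @property
    def bin_starts_min(self) -> np.ndarray:
        return self.bin_edges_min[:-1]


def resample_uniform(
    trace: np.ndarray, native_times: np.ndarray, target_hz: float
) -> UniformTrace:
    """Average a natively sampled trace onto a uniform grid anchored at t=0.

    Bin k covers [k/target_hz, (k+1)/target_hz); its value is the mean of the
    native samples falling inside.  Bins with no samples (inside the removed
    artifact gap) are NaN and flagged in gap_mask.
    """
    trace = np.asarray(trace, dtype=float)
    native_times = np.asarray(native_times, dtype=float)
    if native_times.size < 2 or not np.all(np.diff(native_times) > 0):
        raise ValidationError("native_times must be strictly increasing, length >= 2")
    native_rate = 1.0 / np.median(np.diff(native_times))
    if target_hz > native_rate * (1 + 1e-9):
        raise ValidationError(
            f"target rate {target_hz} Hz exceeds native rate {native_rate:.3f} Hz"
        )
    # tiny bias keeps samples lying exactly on a bin edge in the later bin
    # despite float round-off ([start, end) convention)
    idx = np.floor(native_times * target_hz + 1e-9).astype(np.int64)
    k0, k1 = idx.min(), idx.max()
    n_bins = int(k1 - k0 + 1)
    shifted = idx - k0
    counts = np.bincount(shifted, minlength=n_bins)
    sums = np.bincount(shifted, weights=trace, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        values = sums / counts
    gap = counts == 0
    values[gap] = np.nan
    return UniformTrace(values=values, rate_hz=float(target_hz),
                        t0_s=float(k0 / target_hz), gap_mask=gap)


def _segments(gap_mask: np.ndarray):
    """Yield (start, stop) of maximal contiguous non-gap runs."""
    good = ~gap_mask
    if not good.any():
        return
    edges = np.flatnonzero(np.diff(good.astype(np.int8)))
    starts = [0] if good[0] else []
    starts += [int(e) + 1 for e in edges if good[e + 1]]
    stops = [int(e) + 1 for e in edges if good[e]]
    if good[-1]:
        stops.append(good.size)
    yield from zip(starts, stops)


def _zero_phase(values: np.ndarray, sos: np.ndarray, gap_mask: np.ndarray) -> np.ndarray:
    """Forward-backward filter each contiguous non-gap segment independently."""
    out = np.full_like(values, np.nan, dtype=float)
    for a, b in _segments(gap_mask):
        seg = values[a:b]
        padlen = min(seg.size - 1, 3 * (sos.shape[0] * 2 + 1))
        out[a:b] = signal.sosfiltfilt(sos, seg, padlen=padlen)
    return out


def lowpass(trace: UniformTrace, cutoff_hz: float = 0.02) -> UniformTrace:
    """Zero-phase 2nd-order Butterworth lowpass (visualization path)."""
    nyq = trace.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValidationError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=trace.rate_hz, output="sos")
    return UniformTrace(
        values=_zero_phase(trace.values, sos, trace.gap_mask),
        rate_hz=trace.rate_hz, t0_s=trace.t0_s, gap_mask=trace.gap_mask.copy(),
    )


def bandpass(
    trace: UniformTrace,
    low_hz: float = PEAK_BAND_HZ[0],
    high_hz: float = PEAK_BAND_HZ[1],
) -> UniformTrace:
    """Zero-phase 4th-order Butterworth bandpass for peak detection.

    Must be applied at the native sampling rate: with the standard 0.17-4.5 Hz
    band, a 5 Hz (resampled) trace has Nyquist 2.5 Hz < 4.5 Hz.
    """
    nyq = trace.rate_hz / 2.0
    if high_hz >= 0.98 * nyq:
        raise ValidationError(
            f"bandpass upper edge {high_hz} Hz is at/above 0.98 x Nyquist "
            f"({nyq} Hz at {trace.rate_hz} Hz sampling); apply the bandpass at "
            "the native frame rate, before any 5 Hz resampling"
        )
    if not 0 < low_hz < high_hz:
        raise ValidationError("need 0 < low_hz < high_hz")
    sos = signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=trace.rate_hz,
                        output="sos")
    return UniformTrace(
        values=_zero_phase(trace.values, sos, trace.gap_mask),
        rate_hz=trace.rate_hz, t0_s=trace.t0_s, gap_mask=trace.gap_mask.copy(),
    )


def detect_peaks(filtered: UniformTrace, k_sd: float = PEAK_K_SD,
                 stat_window_s: tuple[float, float] | None = None,
                 threshold: float | None = None):
    """Peaks of a filtered trace: threshold = mean + k_sd * SD over all
    (non-gap) samples; one peak per maximal run of samples strictly above the
    threshold, at the time of the run maximum (first maximum on ties).

    stat_window_s restricts the mean/SD computation to a time range (e.g. the
    pre-stimulation baseline); an explicit `threshold` overrides the per-trace
    statistic entirely (used for a global threshold shared across ROIs).

    Returns (peak_times_s, threshold).
    """
    good = ~filtered.gap_mask & np.isfinite(filtered.values)
    v = filtered.values
    if good.sum() < 10:
        raise ValidationError("trace shorter than 10 valid samples")
    if threshold is None:
        stat = good
        if stat_window_s is not None:
            t = filtered.times_s
            stat = good & (t >= stat_window_s[0]) & (t < stat_window_s[1])
            if stat.sum() < 10:
                raise ValidationError("fewer than 10 valid samples in stat window")
        mu = v[stat].mean()
        sd = v[stat].std(ddof=0)
        threshold = mu + k_sd * sd
    above = good & (v > threshold)
    times = []
    i, n = 0, v.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            run = slice(i, j + 1)
            k = i + int(np.argmax(v[run]))
            times.append(filtered.t0_s + k / filtered.rate_hz)
            i = j + 1
        else:
            i += 1
    return np.asarray(times, dtype=float), float(threshold)


def build_peak_raster(
    traces: dict,
    native_rate_hz: float,
    t0_s: float,
    band_hz: tuple[float, float] = PEAK_BAND_HZ,
    k_sd: float = PEAK_K_SD,
    gap_mask: np.ndarray | None = None,
    threshold_scope: str = "roi",
    stat_window_s: tuple[float, float] | None = None,
) -> PeakRaster:
    """Bandpass each ROI trace at its native rate and detect its peaks.

    threshold_scope "roi" (default) computes mean + k_sd*SD per ROI;
    "global" pools the filtered samples of all ROIs into one shared
    threshold.  stat_window_s optionally restricts the statistic to a time
    range (e.g. the pre-stimulation baseline).
    """
    if threshold_scope not in ("roi", "global"):
        raise ValidationError("threshold_scope must be 'roi' or 'global'")
    filtered = {}
    span = None
    for rid, values in traces.items():
        ut = UniformTrace(values=values, rate_hz=native_rate_hz, t0_s=t0_s,
                          gap_mask=gap_mask)
        filtered[rid] = bandpass(ut, band_hz[0], band_hz[1])
        if span is None:
            span = (ut.t0_s / 60.0, ut.times_s[-1] / 60.0)

    shared = None
    if threshold_scope == "global" and filtered:
        pool = []
        for filt in filtered.values():
            stat = ~filt.gap_mask & np.isfinite(filt.values)
            if stat_window_s is not None:
                t = filt.times_s
                stat &= (t >= stat_window_s[0]) & (t < stat_window_s[1])
            pool.append(filt.values[stat])
        pool = np.concatenate(pool)
        shared = float(pool.mean() + k_sd * pool.std(ddof=0))

    peaks, thresholds = {}, {}
    for rid, filt in filtered.items():
        times, thr = detect_peaks(filt, k_sd=k_sd, stat_window_s=stat_window_s,
                                  threshold=shared)
        peaks[rid] = times
        thresholds[rid] = thr
    return PeakRaster(peaks=peaks, thresholds=thresholds, band_hz=band_hz,
                      span_min=span)


def bin_series(
    data,
    bin_width_min: float,
    kind: str,
    span_min: tuple[float, float] | None = None,
) -> BinnedSeries:
    """Discretize events or a trace onto [start, end) bins aligned at t=0.

    Event arrays (times in s) become per-bin counts; a UniformTrace becomes
    per-bin means (gap samples ignored).  Edge events belong to the later bin.
    A tail shorter than one bin is dropped with a warning.
    """
    if bin_width_min <= 0:
        raise ValidationError("bin width must be positive")
    w = bin_width_min * 60.0
    if isinstance(data, UniformTrace):
        t = data.times_s
        vals = data.values
        good = ~data.gap_mask & np.isfinite(vals)
        t, vals = t[good], vals[good]
        span = (t.min() / 60.0, (t.max() + 1.0 / data.rate_hz) / 60.0) if span_min is None else span_min
        is_events = False
    else:
        t = np.asarray(data, dtype=float)
        vals = None
        if span_min is None:
            if t.size == 0:
                raise ValidationError("event binning needs an explicit span_min")
            span = (t.min() / 60.0, t.max() / 60.0 + 1e-9)
        else:
            span = span_min
        is_events = True

    k_lo = int(np.floor(round(span[0] / bin_width_min, 9)))
    k_hi = int(np.floor(round(span[1] / bin_width_min, 9)))
    if not np.isclose(span[1], k_hi * bin_width_min, atol=1e-9):
        warnings.warn(
            f"span tail beyond {k_hi * bin_width_min} min shorter than one bin; dropped",
            stacklevel=2,
        )
    if k_hi <= k_lo:
        raise ValidationError("span shorter than one bin")
    edges = (np.arange(k_lo, k_hi + 1) * bin_width_min).astype(float)

    idx = np.floor(t / w + 1e-9).astype(np.int64) - k_lo
    inside = (idx >= 0) & (idx < k_hi - k_lo)
    n_bins = k_hi - k_lo
    if is_events:
        values = np.bincount(idx[inside], minlength=n_bins).astype(float)
    else:
        counts = np.bincount(idx[inside], minlength=n_bins)
        sums = np.bincount(idx[inside], weights=vals[inside], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            values = sums / counts
    return BinnedSeries(bin_edges_min=edges, values=values, kind=kind)


def pool_roi_bins(sessions: list, bin_width_min: float) -> pd.DataFrame:
    """Pool per-ROI binned series across mice into a long table.

    `sessions` is a list of (group, mouse_id, {roi_id: BinnedSeries}) tuples;
    the ROI is the statistical unit downstream.  The whole-frame pseudo-ROI
    "w" is excluded (it is not an ROI) with a warning.
    """
    rows = []
    ref_edges = None
    for group, mouse, series in sessions:
        for rid, bs in series.items():
            if rid == "w":
                warnings.warn("whole-frame pseudo-ROI 'w' excluded from pooling",
                              stacklevel=2)
                continue
            if ref_edges is None:
                ref_edges = bs.bin_edges_min
            elif bs.bin_edges_min.shape != ref_edges.shape or not np.allclose(
                    bs.bin_edges_min, ref_edges):
                raise ValidationError(
                    f"session {mouse} ROI {rid}: bin grid differs from the pool"
                )
            if not np.allclose(np.diff(bs.bin_edges_min), bin_width_min):
                raise ValidationError(
                    f"session {mouse}: bin width != {bin_width_min} min"
                )
            for start, val in zip(bs.bin_starts_min, bs.values):
                rows.append({"group": group, "mouse": mouse, "roi_id": rid,
                             "bin_start_min": float(start), "value": float(val)})
    return pd.DataFrame(rows, columns=["group", "mouse", "roi_id", "bin_start_min", "value"])
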