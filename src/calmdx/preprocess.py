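"""Session trimming, light-artifact handling, baselines and %dF/F0.

Each pixel (or ROI-mean) F is normalized against its baseline mean F0 as

    %dF/F0 = (F - F0) / F0 * 100

The last minutes before injection are contaminated by the external light
needed to perform the injection, so the default trim keeps
[-pre_keep, -artifact) and [0, post_keep) minutes and the default baseline
window is the last artifact-free 15 minutes, [-25, -10).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from calmdx.errors import (
    DimensionError,
    NormalizationError,
    RangeError,
    ValidationError,
)
from calmdx.io_formats import SensorVideo, SessionMeta

#: default baseline window (minutes relative to stimulation): the last 15
#: artifact-free minutes before injection.
DEFAULT_BASELINE_WINDOW_MIN = (-25.0, -10.0)


@dataclass(frozen=True)
class TrimSpec:
    """Retention spans in minutes: keep [-pre_keep, -artifact) and [0, post_keep)."""

    pre_keep_min: float = 40.0
    artifact_min: float = 10.0
    post_keep_min: float = 60.0

    def __post_init__(self) -> None:
        if min(self.pre_keep_min, self.artifact_min, self.post_keep_min) < 0:
            raise ValidationError("trim spans must be >= 0")
        if self.artifact_min > self.pre_keep_min:
            raise ValidationError("artifact_min cannot exceed pre_keep_min")


@dataclass
class BaselineImage:
    """Per-pixel mean ADU over the baseline window (houses F0)."""

    f0: np.ndarray
    window_min: tuple[float, float]


@dataclass
class DffVideo:
    """%dF/F0 frame stack (percent units, float)."""

    frames: np.ndarray
    time_s: np.ndarray
    meta: SessionMeta

    def __post_init__(self) -> None:
        if self.frames.shape[0] != self.time_s.shape[0]:
            raise DimensionError("frames / time_s length mismatch")


def trim_session(video: SensorVideo, trimspec: TrimSpec = TrimSpec()) -> SensorVideo:
    """Trim to [-pre_keep, -artifact) and [0, post_keep) minutes.

    The removed artifact gap is recorded in meta.extra["artifact_gap_min"] so
    downstream resampling never interpolates across it.  Idempotent for a
    fixed spec.
    """
    pre_s = trimspec.pre_keep_min * 60.0
    art_s = trimspec.artifact_min * 60.0
    post_s = trimspec.post_keep_min * 60.0
    t = video.time_s
    dt = 1.0 / video.meta.frame_rate_hz
    if t[0] > -pre_s + dt / 2 or t[-1] < post_s - dt - 1e-9:
        raise RangeError(
            f"recording [{t[0]/60:.2f}, {t[-1]/60:.2f}] min cannot cover "
            f"[-{trimspec.pre_keep_min}, {trimspec.post_keep_min}) min"
        )
    keep = ((t >= -pre_s) & (t < -art_s)) | ((t >= 0) & (t < post_s))
    meta = replace(video.meta, extra=dict(video.meta.extra))
    meta.extra["artifact_gap_min"] = [-trimspec.artifact_min, 0.0]
    meta.extra["trim_spec_min"] = [trimspec.pre_keep_min, trimspec.artifact_min,
                                   trimspec.post_keep_min]
    return SensorVideo(frames=video.frames[keep], time_s=t[keep], meta=meta)


def detect_artifact_frames(video: SensorVideo, saturation_fraction: float = 0.5) -> list[int]:
    """Indices of frames where >= saturation_fraction of pixels exceed 0.95 x dtype max.

    Advisory only: actual trimming is time-based (:func:`trim_session`).
    """
    if not 0 < saturation_fraction <= 1:
        raise ValidationError("saturation_fraction must be in (0, 1]")
    thresh = 0.95 * video.dtype_max
    frac = (video.frames > thresh).mean(axis=(1, 2))
    return [int(i) for i in np.nonzero(frac >= saturation_fraction)[0]]


def compute_baseline(
    video: SensorVideo,
    window_min: tuple[float, float] = DEFAULT_BASELINE_WINDOW_MIN,
) -> BaselineImage:
    """Per-pixel arithmetic mean ADU over frames with time in window (F0)."""
    lo, hi = (window_min[0] * 60.0, window_min[1] * 60.0)
    sel = (video.time_s >= lo) & (video.time_s < hi)
    if not sel.any():
        raise RangeError(f"no frames in baseline window {window_min} min")
    f0 = video.frames[sel].mean(axis=0)
    if np.any(f0 == 0):
        rows, cols = np.nonzero(f0 == 0)
        coords = list(zip(rows.tolist(), cols.tolist()))
        raise NormalizationError(
            f"baseline F0 is zero at pixels {coords[:20]}"
            + (" ..." if len(coords) > 20 else "")
        )
    return BaselineImage(f0=f0, window_min=(float(window_min[0]), float(window_min[1])))


def normalize_dff(video: SensorVideo, baseline: BaselineImage) -> DffVideo:
    """Pixel-wise %dF/F0 = (F - F0)/F0 * 100."""
    if baseline.f0.shape != video.shape_hw:
        raise DimensionError(
            f"baseline shape {baseline.f0.shape} != frame shape {video.shape_hw}"
        )
    f0 = baseline.f0.astype(np.float64)
    # in place: broadcasting temporaries triple the memory traffic on long stacks
    dff = video.frames.astype(np.float64)
    dff -= f0
    dff /= f0
    dff *= 100.0
    return DffVideo(frames=dff, time_s=video.time_s.copy(), meta=video.meta)


def roi_trace(
    raw_video: SensorVideo,
    roi_pixels: np.ndarray,
    baseline_window_min: tuple[float, float] = DEFAULT_BASELINE_WINDOW_MIN,
) -> np.ndarray:
    """%dF/F0 trace of one ROI: raw ADU averaged over the ROI per frame, then
    normalized by the ROI's own baseline-window mean.

    roi_pixels is an (N, 2) array of (row, col) indices.
    """
    roi_pixels = np.asarray(roi_pixels)
    if roi_pixels.size == 0:
        raise ValidationError("empty ROI")
    rows, cols = roi_pixels[:, 0], roi_pixels[:, 1]
    h, w = raw_video.shape_hw
    if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
        raise RangeError("ROI pixels outside the frame")
    f = raw_video.frames[:, rows, cols].mean(axis=1, dtype=np.float64)
    lo, hi = baseline_window_min[0] * 60.0, baseline_window_min[1] * 60.0
    sel = (raw_video.time_s >= lo) & (raw_video.time_s < hi)
    if not sel.any():
        raise RangeError(f"no frames in baseline window {baseline_window_min} min")
    f0 = f[sel].mean()
    if f0 == 0:
        raise NormalizationError("ROI baseline mean is zero")
    return (f - f0) / f0 * 100.0


def export_dff_tiff(dff: DffVideo, path) -> None:
    """Write a %dF/F0 stack as 32-bit float multi-page TIFF."""
    import tifffile

    tifffile.imwrite(str(path), dff.frames.astype(np.float32),
                     photometric="minisblack")


def traces_table(traces: dict, time_s: np.ndarray):
    """Long-format table (time_s, roi_id, dff_percent) for CSV export."""
    import pandas as pd

    rows = []
    for rid, vals in traces.items():
        rows.append(pd.DataFrame({"time_s": time_s, "roi_id": rid,
                                  "dff_percent": vals}))
    return pd.concat(rows, ignore_index=True)


def extract_traces(
    raw_video: SensorVideo,
    roiset,
    baseline_window_min: tuple[float, float] = DEFAULT_BASELINE_WINDOW_MIN,
    include_whole_frame: bool = True,
) -> dict:
    """%dF/F0 traces for every ROI in a RoiSet, keyed by roi_id.

    The whole-frame pseudo-ROI is keyed "w" when requested.
    """
    traces = {}
    for roi in roiset.rois:
        traces[roi.roi_id] = roi_trace(raw_video, roi.pixels, baseline_window_min)
    if include_whole_frame and roiset.includes_whole_frame:
        h, w = raw_video.shape_hw
        full = np.argwhere(np.ones((h, w), bool))
        traces["w"] = roi_trace(raw_video, full, baseline_window_min)
    return traces
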