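"""Readers and writers for the three data streams.

Video is a multi-page grayscale TIFF plus a JSON sidecar carrying acquisition
metadata (frame rate, stimulation time, group labels).  Microdialysis samples
and behavior bins are plain CSV tables.  Times are seconds (video) or minutes
(tables) relative to the stimulation event, with t=0 at injection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from calmdx.errors import DimensionError, FormatError, RangeError, ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("formalin", "pbs")
SIDES = ("contralateral", "ipsilateral")


@dataclass
class SessionMeta:
    """Acquisition metadata for one recording session.

    frame_rate_hz is the native sensor rate (9.73-10.68 Hz typical for the
    device, nominally 10 fps); stim_time_s is the injection time on the
    recording clock (seconds from the first frame).
    """

    session_id: str
    frame_rate_hz: float
    stim_time_s: float
    group: str = "formalin"
    side: str = "contralateral"
    region: str = "DRN"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ValidationError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")


@dataclass
class SensorVideo:
    """Raw frame stack (T x H x W integer ADU) with per-frame times.

    time_s is relative to stimulation: the stimulation frame has time >= 0 and
    its predecessor < 0.  Pixel indices are 0-based (row, col), row 0 at the
    sensor top; the device is 120 rows x 40 cols.
    """

    frames: np.ndarray
    time_s: np.ndarray
    meta: SessionMeta

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.frames.ndim != 3:
            raise DimensionError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] != self.time_s.shape[0]:
            raise DimensionError(
                f"{self.frames.shape[0]} frames but {self.time_s.shape[0]} timestamps"
            )
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time_s must be strictly increasing")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise FormatError(f"frames must be integer ADU, got dtype {self.frames.dtype}")
        if self.frames.size and self.frames.min() < 0:
            raise RangeError("pixel values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def dtype_max(self) -> int:
        return int(np.iinfo(self.frames.dtype).max)


@dataclass
class DialysisSample:
    """One microdialysis collection window (minutes relative to stimulation).

    Exactly one of `response` (detector units) or `concentration` (pg/uL) is
    set on read; quantification fills `concentration`.
    """

    window_start_min: float
    window_end_min: float
    response: float | None = None
    concentration: float | None = None
    below_lod: bool = False

    @property
    def width_min(self) -> float:
        return self.window_end_min - self.window_start_min


@dataclass
class BehaviorBin:
    """Licking duration (s) within one 5-min behavior bin."""

    bin_start_min: float
    licking_duration_s: float


SIDECAR_REQUIRED = ("frame_rate_hz", "stim_time_s")


def read_video(path_tiff: str | Path, path_sidecar: str | Path) -> SensorVideo:
    """Read a multi-page TIFF stack plus its JSON sidecar into a SensorVideo.

    Frame times are (frame_index / frame_rate_hz) - stim_time_s.
    """
    path_sidecar = Path(path_sidecar)
    if not path_sidecar.exists():
        raise FormatError(f"sidecar not found: {path_sidecar}")
    with open(path_sidecar) as fh:
        side = json.load(fh)
    missing = [k for k in SIDECAR_REQUIRED if k not in side]
    if missing:
        raise FormatError(f"sidecar {path_sidecar} lacks required keys: {missing}")

    frames = tifffile.imread(str(path_tiff))
    if frames.ndim == 2:  # single page
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path_tiff}: expected single-channel multi-page TIFF, got shape {frames.shape}")
    if frames.dtype not in (np.dtype("uint8"), np.dtype("uint16")):
        raise FormatError(f"{path_tiff}: expected uint8/uint16 pixels, got {frames.dtype}")

    meta = SessionMeta(
        session_id=str(side.get("session_id", Path(path_tiff).stem)),
        frame_rate_hz=float(side["frame_rate_hz"]),
        stim_time_s=float(side["stim_time_s"]),
        group=side.get("group", "formalin"),
        side=side.get("side", "contralateral"),
        region=side.get("region", "DRN"),
        extra={k: v for k, v in side.items() if k not in (
            "session_id", "frame_rate_hz", "stim_time_s", "group", "side", "region")},
    )
    time_s = np.arange(frames.shape[0]) / meta.frame_rate_hz - meta.stim_time_s
    return SensorVideo(frames=frames, time_s=time_s, meta=meta)


def write_video(video: SensorVideo, path_tiff: str | Path, path_sidecar: str | Path) -> None:
    """Write a SensorVideo losslessly (round-trips with :func:`read_video`).

    The sidecar stores the acquisition clock (frame rate and stimulation
    time); time_s is reconstructed from them, so frame times must lie on the
    uniform acquisition grid.
    """
    if video.frames.max(initial=0) > video.dtype_max:
        raise RangeError("pixel values exceed dtype max")
    tifffile.imwrite(str(path_tiff), video.frames, photometric="minisblack")
    side = {
        "session_id": video.meta.session_id,
        "frame_rate_hz": video.meta.frame_rate_hz,
        "stim_time_s": video.meta.stim_time_s,
        "group": video.meta.group,
        "side": video.meta.side,
        "region": video.meta.region,
        **video.meta.extra,
    }
    with open(path_sidecar, "w") as fh:
        json.dump(side, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_dialysis(path_csv: str | Path) -> list[DialysisSample]:
    """Read the microdialysis sample table (15-min windows).

    Columns: window_start_min, window_end_min, and exactly one of
    response / concentration.  Windows must be non-overlapping; output sorted.
    """
    df = pd.read_csv(path_csv)
    required = {"window_start_min", "window_end_min"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path_csv}: missing columns {sorted(required - set(df.columns))}")
    has_resp = "response" in df.columns
    has_conc = "concentration" in df.columns
    if has_resp and has_conc:
        raise FormatError(f"{path_csv}: both response and concentration columns present")
    if not (has_resp or has_conc):
        raise FormatError(f"{path_csv}: need a response or concentration column")
    if df.empty:
        logger.warning("%s: empty dialysis table", path_csv)
        warnings.warn(f"{path_csv}: empty dialysis table", stacklevel=2)
        return []

    df = df.sort_values("window_start_min").reset_index(drop=True)
    starts = df["window_start_min"].to_numpy(float)
    ends = df["window_end_min"].to_numpy(float)
    if np.any(ends <= starts):
        raise ValidationError("dialysis windows must have positive width")
    if np.any(starts[1:] < ends[:-1] - 1e-9):
        raise ValidationError("dialysis windows overlap")

    samples = []
    for i in range(len(df)):
        kw = {"response": float(df["response"][i])} if has_resp else {
            "concentration": float(df["concentration"][i])}
        samples.append(DialysisSample(float(starts[i]), float(ends[i]), **kw))
    return samples


def write_dialysis(samples: list[DialysisSample], path_csv: str | Path) -> None:
    rows = []
    for s in samples:
        row = {"window_start_min": s.window_start_min, "window_end_min": s.window_end_min}
        if s.concentration is not None:
            row["concentration"] = s.concentration
        else:
            row["response"] = s.response
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_csv, index=False)


def read_behavior(path_csv: str | Path) -> list[BehaviorBin]:
    """Read licking durations per contiguous 5-min bin.

    Durations are seconds within a 300-s bin, so values must lie in [0, 300];
    a gap between consecutive bins is a validation error.
    """
    df = pd.read_csv(path_csv)
    required = {"bin_start_min", "licking_duration_s"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path_csv}: missing columns {sorted(required - set(df.columns))}")
    df = df.sort_values("bin_start_min").reset_index(drop=True)
    starts = df["bin_start_min"].to_numpy(float)
    durs = df["licking_duration_s"].to_numpy(float)
    if np.any((durs < 0) | (durs > 300)):
        raise ValidationError("licking_duration_s must lie in [0, 300] s (5-min bins)")
    if starts.size > 1 and not np.allclose(np.diff(starts), 5.0, atol=1e-9):
        raise ValidationError("behavior bins must be contiguous 5-min bins")
    return [BehaviorBin(float(s), float(d)) for s, d in zip(starts, durs)]


def write_behavior(bins: list[BehaviorBin], path_csv: str | Path) -> None:
    pd.DataFrame(
        {"bin_start_min": [b.bin_start_min for b in bins],
         "licking_duration_s": [b.licking_duration_s for b in bins]}
    ).to_csv(path_csv, index=False)
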