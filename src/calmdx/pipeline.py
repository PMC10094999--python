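"""End-to-end orchestration: simulate or load sessions, run every analysis
stage, and write all tables with provenance.

Reruns with the same inputs, config and seed reproduce all CSV outputs
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from calmdx import __version__
from calmdx.errors import CalmdxError, ValidationError
from calmdx.io_formats import read_behavior, read_dialysis, read_video
from calmdx.microdialysis import align_to_bins, fit_calibration, quantify_series, series_table
from calmdx.preprocess import (
    DEFAULT_BASELINE_WINDOW_MIN,
    TrimSpec,
    compute_baseline,
    extract_traces,
    normalize_dff,
    trim_session,
)
from calmdx.roi_detect import (
    AVG_BINARIZE,
    AVG_CLEAN,
    FRAME_BINARIZE,
    FRAME_CLEAN,
    detect_rois,
)
from calmdx.stats import correlate_modalities, per_bin_group_comparison, t_tests
from calmdx.synthetic import SimConfig, simulate_session
from calmdx.trace_analysis import (
    BinnedSeries,
    bin_series,
    build_peak_raster,
    pool_roi_bins,
    resample_uniform,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults.

    kernel 9, sigma 1.5 (frame) / 2.5 (average), footprints 2/3, min area 15,
    band 0.17-4.5 Hz with a 2-SD peak threshold, 5-min imaging bins, 15-min
    dialysis bins, baseline window [-25, -10) min.
    """

    outdir: str = "calmdx_out"
    seed: int = 0
    simulate: bool = True
    groups: dict = field(default_factory=lambda: {"formalin": 3, "pbs": 3})
    input_dirs: list = field(default_factory=list)  # used when simulate=False
    sim_overrides: dict = field(default_factory=dict)
    # preprocessing
    pre_keep_min: float = 25.0
    artifact_min: float = 10.0
    post_keep_min: float = 30.0
    baseline_window_min: tuple = DEFAULT_BASELINE_WINDOW_MIN
    # trace analysis
    resample_hz: float = 5.0
    lowpass_hz: float = 0.02
    band_hz: tuple = (0.17, 4.5)
    k_sd: float = 2.0
    dff_bin_min: float = 5.0
    dialysis_bin_min: float = 15.0

    def content_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _load_session(session_dir: Path):
    """Load one on-disk session bundle (as written by generate_session)."""
    video = read_video(session_dir / "video.tif", session_dir / "video.json")
    dialysis = read_dialysis(session_dir / "dialysis.csv")
    behavior = read_behavior(session_dir / "behavior.csv")
    standards_path = session_dir / "standards.csv"
    standards = None
    if standards_path.exists():
        df = pd.read_csv(standards_path)
        standards = list(zip(df["concentration_pg_ul"], df["response"]))
    return video, dialysis, standards, behavior


def _analyze_session(video, cfg: PipelineConfig):
    """Imaging stages for one session: trim, baseline, dF/F0, ROIs, traces,
    5-min bins and the peak raster (native-rate bandpass)."""
    spec = TrimSpec(cfg.pre_keep_min, cfg.artifact_min, cfg.post_keep_min)
    trimmed = trim_session(video, spec)
    baseline = compute_baseline(trimmed, cfg.baseline_window_min)
    dff = normalize_dff(trimmed, baseline)
    roiset = detect_rois(dff, FRAME_BINARIZE, FRAME_CLEAN, AVG_BINARIZE, AVG_CLEAN)
    traces = extract_traces(trimmed, roiset, cfg.baseline_window_min)

    fs = video.meta.frame_rate_hz
    binned = {}
    native = {}
    for rid, vals in traces.items():
        ut = resample_uniform(vals, trimmed.time_s, fs)
        native[rid] = ut
        binned[rid] = bin_series(ut, cfg.dff_bin_min, kind="dff_mean",
                                 span_min=(-cfg.pre_keep_min, cfg.post_keep_min))
    raster = None
    if cfg.band_hz[1] < 0.49 * fs:
        ref = next(iter(native.values()))
        raster = build_peak_raster(
            {rid: ut.values for rid, ut in native.items()},
            native_rate_hz=fs, t0_s=ref.t0_s, band_hz=cfg.band_hz, k_sd=cfg.k_sd,
            gap_mask=ref.gap_mask,
        )
    else:
        logger.warning("native rate %.2f Hz too low for the %s Hz band; raster skipped",
                       fs, cfg.band_hz)
    return trimmed, roiset, traces, binned, raster


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full multi-modal analysis and write a results directory.

    Outputs per session: ROI table, trace CSV, peak raster CSV, binned dF/F0
    CSV, quantified serotonin CSV.  Pooled outputs: per-bin group comparison,
    cross-modal correlation report, serotonin pre/post test, manifest.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_times = {}

    # ---- gather sessions -------------------------------------------------
    sessions = []  # (group, session_id, video, dialysis, standards, behavior)
    if cfg.simulate:
        t0 = time.time()
        i = 0
        for group, count in cfg.groups.items():
            for k in range(count):
                sim = SimConfig(seed=cfg.seed + i, group=group,
                                session_id=f"{group}{k}",
                                pre_min=cfg.pre_keep_min,
                                artifact_min=cfg.artifact_min,
                                post_min=cfg.post_keep_min,
                                **cfg.sim_overrides)
                if group == "pbs":
                    sim = dataclasses.replace(sim, kappa_serotonin=0.0,
                                              b_acute=0.0, b_infl=0.0)
                bundle = simulate_session(sim, render=True)
                sessions.append((group, sim.session_id, bundle.video,
                                 bundle.dialysis, bundle.standards, bundle.behavior))
                i += 1
        stage_times["simulate"] = time.time() - t0
    else:
        for d in cfg.input_dirs:
            d = Path(d)
            if not (d / "video.tif").exists():
                raise ValidationError(f"missing video.tif in {d}")
            video, dialysis, standards, behavior = _load_session(d)
            sessions.append((video.meta.group, video.meta.session_id,
                             video, dialysis, standards, behavior))
    if not sessions:
        raise ValidationError("no sessions to analyze")

    # ---- per-session imaging + dialysis ----------------------------------
    pooled_input = []
    rasters_by_group: dict[str, list] = {}
    serotonin_by_group: dict[str, list] = {}
    licking_by_group: dict[str, list] = {}
    pre_post = []
    t0 = time.time()
    for group, sid, video, dialysis, standards, behavior in sessions:
        try:
            trimmed, roiset, traces, binned, raster = _analyze_session(video, cfg)
        except CalmdxError as exc:
            raise CalmdxError(f"stage imaging failed for session {sid}: {exc}") from exc
        sdir = out / f"session_{sid}"
        sdir.mkdir(exist_ok=True)
        roiset.to_table().to_csv(sdir / "rois.csv", index=False)
        trace_rows = pd.DataFrame({
            rid: vals for rid, vals in traces.items()
        })
        trace_rows.insert(0, "time_s", trimmed.time_s)
        trace_rows.to_csv(sdir / "traces.csv", index=False)
        if raster is not None:
            raster.to_table().to_csv(sdir / "peaks.csv", index=False)
            rasters_by_group.setdefault(group, []).append(raster)
        pooled_input.append((group, sid, binned))

        # dialysis quantification
        if dialysis:
            needs_quant = any(s.concentration is None for s in dialysis)
            if needs_quant and not standards:
                raise ValidationError(f"session {sid}: responses without standards")
            curve = fit_calibration(standards) if (needs_quant and standards) else None
            series = quantify_series(dialysis, curve)
            series_table(series).to_csv(sdir / "serotonin.csv", index=False)
            ser_bins, base_idx = align_to_bins(series, cfg.dialysis_bin_min)
            serotonin_by_group.setdefault(group, []).append(ser_bins)
            if base_idx is not None and base_idx + 1 < ser_bins.values.size:
                pre_post.append((group, ser_bins.values[base_idx],
                                 ser_bins.values[base_idx + 1]))
        if behavior:
            starts = np.array([b.bin_start_min for b in behavior])
            edges = np.append(starts, starts[-1] + 5.0)
            lick = BinnedSeries(bin_edges_min=edges,
                                values=[b.licking_duration_s for b in behavior],
                                kind="licking_s")
            licking_by_group.setdefault(group, []).append(lick)
    stage_times["sessions"] = time.time() - t0

    # ---- pooled statistics ------------------------------------------------
    t0 = time.time()
    pooled = pool_roi_bins(pooled_input, cfg.dff_bin_min)
    pooled.to_csv(out / "pooled_bins.csv", index=False)
    if set(pooled["group"].unique()) >= {"formalin", "pbs"}:
        comparison = per_bin_group_comparison(pooled)
        comparison.to_csv(out / "group_comparison.csv", index=False)

    corr_rows = []
    for group, rasters in rasters_by_group.items():
        for pair, series_list, width in (
            ("peaks_vs_serotonin", serotonin_by_group.get(group, []), cfg.dialysis_bin_min),
            ("peaks_vs_licking", licking_by_group.get(group, []), cfg.dff_bin_min),
        ):
            if len(series_list) != len(rasters) or not series_list:
                continue
            try:
                r = correlate_modalities(rasters, series_list, width)
            except ValidationError as exc:
                logger.warning("%s %s correlation skipped: %s", group, pair, exc)
                continue
            corr_rows.append({"group": group, "pair": pair, "rho": r.rho,
                              "p": r.p_value, "n_pairs": r.n_pairs})
    if corr_rows:
        pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

    test_rows = []
    for group in {g for g, _, _ in pre_post}:
        pre = [a for g, a, _ in pre_post if g == group]
        post = [b for g, _, b in pre_post if g == group]
        if len(pre) >= 2:
            r = t_tests(pre, post, paired=True)
            test_rows.append({"group": group, "test": r.test, "statistic": r.statistic,
                              "p": r.p_value, "n": r.n1,
                              "zero_variance": r.zero_variance})
    if test_rows:
        pd.DataFrame(test_rows).to_csv(out / "serotonin_pre_post.csv", index=False)
    stage_times["stats"] = time.time() - t0

    manifest = {
        "software": "calmdx",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
        "config": dataclasses.asdict(cfg),
        "n_sessions": len(sessions),
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "total_seconds": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    logger.info("pipeline finished in %.1f s -> %s", time.time() - t_start, out)
    return out
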