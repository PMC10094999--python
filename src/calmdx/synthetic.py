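"""Ground-truthed synthetic sessions: lensless calcium video, serotonin
dialysis series and licking bins with the statistical structure the analysis
assumes.

The nociceptive drive is biphasic: an acute Gaussian bump centered 10 min
after injection (SD 2.5 min) and a smooth inflammatory plateau over 20-40 min,
on top of a baseline population event rate.  Control (PBS) sessions keep the
baseline rate only.  Each active population is a Gaussian blob blurred by a
scattering PSF (single neurons are not resolvable on a lensless sensor);
serotonin concentration per 15-min window is linearly coupled to the event
count in that window; licking follows its own biphasic profile (sharp rise
around 5-10 min, moderate rise after 30 min).  The last pre-injection minutes
are overwritten near sensor saturation to emulate the external light needed
for the injection.

Every stochastic operation is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from calmdx.errors import ValidationError
from calmdx.io_formats import (
    BehaviorBin,
    DialysisSample,
    SensorVideo,
    SessionMeta,
    write_behavior,
    write_dialysis,
    write_video,
)

logger = logging.getLogger(__name__)

ARTIFACT_LEVEL_FRACTION = 0.99  # artifact frames sit at 0.99 x dtype max


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study conditions being emulated.

    Durations are minutes relative to injection.  The default scaled session
    (25 min pre including a 10-min artifact segment, 30 min post) keeps test
    runs small; full 90-min sessions are supported by raising the spans.
    """

    seed: int = 0
    session_id: str = "sim"
    group: str = "formalin"          # formalin | pbs
    side: str = "contralateral"
    # geometry: the sensor is 40 x 120 px (7.5 um/px), long axis vertical
    height: int = 120
    width: int = 40
    dtype: str = "uint16"
    # timing
    frame_rate_hz: float = 10.0
    jitter_frame_rate: bool = False  # sample the native rate in [9.73, 10.68] Hz
    pre_min: float = 25.0
    artifact_min: float = 10.0
    post_min: float = 30.0
    # population geometry
    n_blobs: int = 6
    blob_sigma_px: tuple[float, float] = (1.5, 3.5)
    psf_sigma_px: float = 2.0
    min_blob_separation_px: float = 14.0
    # event model
    r_base_hz: float = 0.05          # baseline event rate per population
    #: spontaneous background firing at r_base throughout the session.  With
    #: False only the stimulus-evoked drive remains (and PBS populations are
    #: silent): together with the sensor-noise flags this yields a fully
    #: deterministic background, which geometric recovery tests need because
    #: the adaptive (scale-invariant) ROI detector responds to %dF/F0
    #: structure of any amplitude, including the faint dips that spontaneous
    #: baseline transients imprint on F0.
    spontaneous: bool = True
    a_acute: float = 6.0             # acute-phase rate multiplier
    a_infl: float = 3.0              # inflammatory-phase rate multiplier
    t_acute_min: float = 10.0
    acute_sd_min: float = 2.5
    t_infl_min: tuple[float, float] = (20.0, 40.0)
    infl_edge_s: float = 60.0
    # indicator kinetics (generator defaults, not claims about the mouse line)
    tau_rise_s: float = 0.1
    tau_decay_s: float = 1.0
    # rendering
    baseline_adu: float = 100.0
    amp_adu: float = 40.0            # per-event peak amplitude at blob center
    drift_amp_adu: float = 2.0
    drift_period_min: float = 20.0
    shot_noise: bool = True
    read_noise_sd_adu: float = 2.0
    # serotonin coupling (pg/uL; kappa in pg/uL per event/s; 0 for control)
    s_base_pg_ul: float = 0.5
    kappa_serotonin: float = 2.0
    serotonin_noise_sd: float = 0.1
    dialysis_window_min: float = 15.0
    # synthetic HPLC assay used to emit detector responses
    assay_slope: float = 120.0       # response units per pg/uL
    assay_intercept: float = 5.0
    # licking behavior (seconds per 5-min bin)
    licking_base_s: float = 10.0
    b_acute: float = 120.0
    b_infl: float = 60.0
    t_lick_acute_min: float = 7.5
    lick_acute_sd_min: float = 2.5
    t_lick_infl_min: tuple[float, float] = (30.0, 50.0)
    licking_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if min(self.r_base_hz, self.a_acute, self.a_infl,
               self.kappa_serotonin) < 0:
            raise ValidationError("rates, multipliers and kappa must be >= 0")
        if not self.tau_decay_s > self.tau_rise_s:
            raise ValidationError("tau_decay must exceed tau_rise")
        if self.group not in ("formalin", "pbs"):
            raise ValidationError("group must be formalin or pbs")

    @property
    def span_s(self) -> tuple[float, float]:
        return (-self.pre_min * 60.0, self.post_min * 60.0)


@dataclass
class SimGroundTruth:
    """Planted structure for recovery tests."""

    blob_masks: list
    blob_centers: list
    blob_sigmas: list
    event_times: list            # per-blob arrays, seconds relative to injection
    kappa: float
    frame_rate_hz: float
    window_counts: np.ndarray | None = None   # events per dialysis window
    serotonin_truth: np.ndarray | None = None  # noiseless concentrations
    licking_truth: np.ndarray | None = None    # noiseless durations per bin
    rate_samples: np.ndarray | None = None     # lambda(t) on the frame grid


@dataclass
class SessionBundle:
    config: SimConfig
    video: SensorVideo
    dialysis: list
    standards: list
    behavior: list
    truth: SimGroundTruth


def _streams(cfg: SimConfig) -> dict:
    """Independent, named random streams so each sub-model is reproducible."""
    root = np.random.SeedSequence(cfg.seed)
    names = ("placement", "events", "render", "dialysis", "licking", "clock")
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _smooth_plateau(t_s: np.ndarray, start_s: float, end_s: float, edge_s: float) -> np.ndarray:
    """Product of two logistic edges: ~1 inside [start, end], ~0 outside."""
    a = 1.0 / (1.0 + np.exp(-(t_s - start_s) / edge_s))
    b = 1.0 / (1.0 + np.exp((t_s - end_s) / edge_s))
    return a * b


def rate_function(cfg: SimConfig):
    """Per-population event rate lambda(t) in Hz (t in seconds from injection).

    formalin: r_base * (1 + a_acute * G(t; t_acute, sd) + a_infl * plateau)
    pbs:      r_base
    """
    def lam(t_s):
        t_s = np.asarray(t_s, dtype=float)
        base = 1.0 if cfg.spontaneous else 0.0
        if cfg.group == "pbs":
            return np.full_like(t_s, base * cfg.r_base_hz)
        g = np.exp(-0.5 * ((t_s - cfg.t_acute_min * 60.0) / (cfg.acute_sd_min * 60.0)) ** 2)
        b = _smooth_plateau(t_s, cfg.t_infl_min[0] * 60.0, cfg.t_infl_min[1] * 60.0,
                            cfg.infl_edge_s)
        return cfg.r_base_hz * (base + cfg.a_acute * g + cfg.a_infl * b)

    return lam


def simulate_events(cfg: SimConfig, rng: np.random.Generator | None = None) -> list:
    """Per-blob event times over the session span, by inhomogeneous-Poisson
    thinning of the biphasic rate.  Deterministic given (config, seed)."""
    rng = _streams(cfg)["events"] if rng is None else rng
    lam = rate_function(cfg)
    t0, t1 = cfg.span_s
    lam_max = cfg.r_base_hz * (1.0 + cfg.a_acute + cfg.a_infl) if cfg.group == "formalin" \
        else cfg.r_base_hz
    events = []
    for _ in range(cfg.n_blobs):
        if lam_max == 0:
            events.append(np.empty(0))
            continue
        n = rng.poisson(lam_max * (t1 - t0))
        cand = np.sort(rng.uniform(t0, t1, size=n))
        keep = rng.uniform(0, lam_max, size=n) < lam(cand)
        events.append(cand[keep])
    return events


def transient_kernel(dt_s: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Unit-peak calcium transient: (1 - e^(-dt/tau_r)) e^(-dt/tau_d), dt >= 0."""
    dt_s = np.asarray(dt_s, dtype=float)
    raw = np.where(dt_s >= 0,
                   (1.0 - np.exp(-np.maximum(dt_s, 0) / cfg.tau_rise_s))
                   * np.exp(-np.maximum(dt_s, 0) / cfg.tau_decay_s),
                   0.0)
    return raw / kernel_peak_value(cfg)


def kernel_peak_time(cfg: SimConfig) -> float:
    """Closed-form time of the kernel maximum: tau_r * ln(1 + tau_d/tau_r)."""
    return cfg.tau_rise_s * np.log(1.0 + cfg.tau_decay_s / cfg.tau_rise_s)


def kernel_peak_value(cfg: SimConfig) -> float:
    tstar = kernel_peak_time(cfg)
    return float((1.0 - np.exp(-tstar / cfg.tau_rise_s)) * np.exp(-tstar / cfg.tau_decay_s))


def events_to_fluorescence(event_times: np.ndarray, cfg: SimConfig,
                           time_grid_s: np.ndarray) -> np.ndarray:
    """Unit-amplitude fluorescence trace: superposition of one transient
    kernel per event (linearity: far-separated events simply add)."""
    trace = np.zeros(time_grid_s.size)
    for ev in np.asarray(event_times, dtype=float):
        i0 = int(np.searchsorted(time_grid_s, ev))
        # kernel support: negligible after ~12 decay constants
        i1 = int(np.searchsorted(time_grid_s, ev + 12.0 * cfg.tau_decay_s))
        if i0 >= trace.size:
            continue
        dt = time_grid_s[i0:i1] - ev
        trace[i0:i1] += (1.0 - np.exp(-dt / cfg.tau_rise_s)) * np.exp(-dt / cfg.tau_decay_s)
    return trace / kernel_peak_value(cfg)


def time_grid(cfg: SimConfig, frame_rate_hz: float | None = None) -> np.ndarray:
    fs = cfg.frame_rate_hz if frame_rate_hz is None else frame_rate_hz
    n = int(round((cfg.pre_min + cfg.post_min) * 60.0 * fs))
    return np.arange(n) / fs - cfg.pre_min * 60.0


def place_blobs(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Random non-overlapping blob centers and widths within the frame."""
    rng = _streams(cfg)["placement"] if rng is None else rng
    sig_lo, sig_hi = cfg.blob_sigma_px
    margin = int(np.ceil(2.0 * sig_hi + cfg.psf_sigma_px))
    centers: list[tuple[float, float]] = []
    sigmas: list[float] = []
    tries = 0
    stale = 0
    while len(centers) < cfg.n_blobs:
        tries += 1
        if tries > 50000:
            raise ValidationError(
                f"cannot place {cfg.n_blobs} blobs with separation "
                f"{cfg.min_blob_separation_px}px in a {cfg.height}x{cfg.width} frame"
            )
        if stale > 200:  # an unlucky early center can block the rest; restart
            centers.clear()
            sigmas.clear()
            stale = 0
        r = rng.uniform(margin, cfg.height - margin)
        c = rng.uniform(margin, cfg.width - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= cfg.min_blob_separation_px ** 2
               for r0, c0 in centers):
            centers.append((float(r), float(c)))
            sigmas.append(float(rng.uniform(sig_lo, sig_hi)))
            stale = 0
        else:
            stale += 1
    return centers, sigmas


def blob_profile(center, sigma_px: float, cfg: SimConfig) -> np.ndarray:
    """Unit-peak PSF-blurred blob image: Gaussian source of width sigma
    convolved with a Gaussian scattering PSF is a Gaussian of combined width."""
    sig_eff = float(np.hypot(sigma_px, cfg.psf_sigma_px))
    rr, cc = np.mgrid[0:cfg.height, 0:cfg.width]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.exp(-0.5 * d2 / sig_eff**2)


def render_video(blob_traces: np.ndarray, cfg: SimConfig,
                 time_grid_s: np.ndarray | None = None,
                 frame_rate_hz: float | None = None,
                 rng_render: np.random.Generator | None = None,
                 rng_placement: np.random.Generator | None = None,
                 ) -> tuple[SensorVideo, SimGroundTruth]:
    """Render blob amplitude traces into a noisy uint sensor stack.

    frame = baseline + sum_b amp * A_b(t) * profile_b + drift + shot noise +
    read noise, clipped to the dtype; frames in [-artifact, 0) min are
    overwritten at 0.99 x dtype max (external-light segment).

    Shot and read noise are drawn as one Gaussian with variance
    (photon count + read_sd^2): at the ~100 ADU operating point of these
    sessions the Poisson law is indistinguishable from its normal limit, and
    a single float32 draw keeps long renders cheap on one core.
    """
    streams = None
    if rng_render is None or rng_placement is None:
        streams = _streams(cfg)
    rng_render = rng_render or streams["render"]
    rng_placement = rng_placement or streams["placement"]
    fs = cfg.frame_rate_hz if frame_rate_hz is None else frame_rate_hz
    t = time_grid(cfg, fs) if time_grid_s is None else np.asarray(time_grid_s)
    blob_traces = np.atleast_2d(np.asarray(blob_traces, dtype=float))  # (B, T)
    if blob_traces.shape[0] != cfg.n_blobs:
        raise ValidationError("one amplitude trace per blob required")
    if blob_traces.shape[1] != t.size:
        raise ValidationError("trace length must match the time grid")

    centers, sigmas = place_blobs(cfg, rng_placement)
    profiles = np.stack([blob_profile(c, s, cfg) for c, s in zip(centers, sigmas)])
    masks = [p >= 0.5 for p in profiles]  # FWHM footprint of each blob
    hw = cfg.height * cfg.width
    prof_flat = profiles.reshape(cfg.n_blobs, hw)

    dtype = np.dtype(cfg.dtype)
    dmax = np.iinfo(dtype).max
    drift = cfg.drift_amp_adu * np.sin(2 * np.pi * t / (cfg.drift_period_min * 60.0))
    amps = cfg.amp_adu * blob_traces.T  # (T, B)

    frames = np.empty((t.size, cfg.height, cfg.width), dtype=dtype)
    chunk = 2048
    read_var = cfg.read_noise_sd_adu**2
    for a in range(0, t.size, chunk):
        b = min(a + chunk, t.size)
        img = amps[a:b] @ prof_flat
        img += (cfg.baseline_adu + drift[a:b])[:, None]
        var = (np.maximum(img, 0.0) if cfg.shot_noise else 0.0) + read_var
        if np.any(var > 0):
            img += np.sqrt(var) * rng_render.standard_normal(
                img.shape, dtype=np.float32)
        np.clip(np.rint(img), 0, dmax, out=img)
        frames[a:b] = img.astype(dtype).reshape(b - a, cfg.height, cfg.width)

    artifact = (t >= -cfg.artifact_min * 60.0) & (t < 0)
    frames[artifact] = dtype.type(int(round(ARTIFACT_LEVEL_FRACTION * dmax)))

    meta = SessionMeta(
        session_id=cfg.session_id,
        frame_rate_hz=fs,
        stim_time_s=cfg.pre_min * 60.0,
        group=cfg.group,
        side=cfg.side,
        extra={"artifact_gap_min": [-cfg.artifact_min, 0.0], "seed": cfg.seed},
    )
    video = SensorVideo(frames=frames, time_s=t, meta=meta)
    truth = SimGroundTruth(
        blob_masks=masks, blob_centers=centers, blob_sigmas=sigmas,
        event_times=[], kappa=cfg.kappa_serotonin, frame_rate_hz=fs,
    )
    return video, truth


def dialysis_windows(cfg: SimConfig) -> np.ndarray:
    """Edges of the 15-min windows fully contained in the session span."""
    w = cfg.dialysis_window_min
    k_lo = -int(np.floor(cfg.pre_min / w + 1e-9))
    k_hi = int(np.floor(cfg.post_min / w + 1e-9))
    return np.arange(k_lo, k_hi + 1) * w


def simulate_dialysis(event_times: list, cfg: SimConfig,
                      rng: np.random.Generator | None = None):
    """Serotonin concentration per 15-min window, linearly coupled to the
    total event count in the window:

        c_k = s_base + kappa * N_k / window_s + noise,  clipped >= 0

    Returns (samples, truth) where truth holds the window counts and the
    noiseless concentrations.
    """
    rng = _streams(cfg)["dialysis"] if rng is None else rng
    edges_min = dialysis_windows(cfg)
    all_events = np.concatenate([np.asarray(e, float) for e in event_times]
                                or [np.empty(0)])
    counts = np.histogram(all_events / 60.0, bins=edges_min)[0]
    window_s = cfg.dialysis_window_min * 60.0
    truth_conc = cfg.s_base_pg_ul + cfg.kappa_serotonin * counts / window_s
    noise = rng.normal(0.0, cfg.serotonin_noise_sd, size=counts.size) \
        if cfg.serotonin_noise_sd > 0 else np.zeros(counts.size)
    conc = np.maximum(truth_conc + noise, 0.0)
    samples = [
        DialysisSample(float(edges_min[i]), float(edges_min[i + 1]),
                       concentration=float(conc[i]))
        for i in range(counts.size)
    ]
    return samples, {"window_counts": counts, "concentration_truth": truth_conc}


def simulate_licking(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Licking duration per post-injection 5-min bin.

    formalin: base + b_acute * G(center; 7.5 min) + b_infl * plateau(30-50 min)
    plus noise, clipped to [0, 300]; pbs: base plus noise.
    """
    rng = _streams(cfg)["licking"] if rng is None else rng
    n_bins = int(np.floor(cfg.post_min / 5.0 + 1e-9))
    starts = np.arange(n_bins) * 5.0
    centers = starts + 2.5
    if cfg.group == "formalin":
        g = np.exp(-0.5 * ((centers - cfg.t_lick_acute_min) / cfg.lick_acute_sd_min) ** 2)
        b = _smooth_plateau(centers * 60.0, cfg.t_lick_infl_min[0] * 60.0,
                            cfg.t_lick_infl_min[1] * 60.0, cfg.infl_edge_s)
        truth = cfg.licking_base_s + cfg.b_acute * g + cfg.b_infl * b
    else:
        truth = np.full(n_bins, cfg.licking_base_s)
    truth = np.clip(truth, 0.0, 300.0)
    noise = rng.normal(0.0, cfg.licking_noise_sd, size=n_bins) \
        if cfg.licking_noise_sd > 0 else np.zeros(n_bins)
    durations = np.clip(truth + noise, 0.0, 300.0)
    bins = [BehaviorBin(float(s), float(d)) for s, d in zip(starts, durations)]
    return bins, {"licking_truth": truth}


def simulate_session(cfg: SimConfig, render: bool = True) -> SessionBundle:
    """Build a complete in-memory session (video + dialysis + behavior +
    ground truth) from one seed.  With render=False the video is skipped
    (trace-level studies)."""
    streams = _streams(cfg)
    fs = cfg.frame_rate_hz
    if cfg.jitter_frame_rate:
        fs = float(streams["clock"].uniform(9.73, 10.68))
    events = simulate_events(cfg, streams["events"])
    grid = time_grid(cfg, fs)
    traces = np.stack([events_to_fluorescence(e, cfg, grid) for e in events]) \
        if cfg.n_blobs else np.zeros((0, grid.size))

    if render:
        video, truth = render_video(traces, cfg, grid, fs,
                                    rng_render=streams["render"],
                                    rng_placement=streams["placement"])
    else:
        centers, sigmas = place_blobs(cfg, streams["placement"])
        profiles = [blob_profile(c, s, cfg) for c, s in zip(centers, sigmas)]
        truth = SimGroundTruth(
            blob_masks=[p >= 0.5 for p in profiles], blob_centers=centers,
            blob_sigmas=sigmas, event_times=[], kappa=cfg.kappa_serotonin,
            frame_rate_hz=fs,
        )
        video = None
    truth.event_times = events
    truth.rate_samples = rate_function(cfg)(grid)

    dialysis, dtruth = simulate_dialysis(events, cfg, streams["dialysis"])
    truth.window_counts = dtruth["window_counts"]
    truth.serotonin_truth = dtruth["concentration_truth"]
    behavior, btruth = simulate_licking(cfg, streams["licking"])
    truth.licking_truth = btruth["licking_truth"]

    standards = [(c, cfg.assay_slope * c + cfg.assay_intercept)
                 for c in (0.50, 1.0, 10.0)]
    return SessionBundle(config=cfg, video=video, dialysis=dialysis,
                         standards=standards, behavior=behavior, truth=truth)


def generate_session(cfg: SimConfig, outdir: str | Path,
                     overwrite: bool = False) -> dict:
    """Write a full session bundle to disk in the package formats.

    Files: video.tif + video.json, dialysis.csv (detector responses),
    standards.csv, behavior.csv, truth.json, manifest.json.  Identical seed
    and config give byte-identical files.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = simulate_session(cfg, render=True)
    paths = {
        "video_tiff": "video.tif", "video_sidecar": "video.json",
        "dialysis_csv": "dialysis.csv", "standards_csv": "standards.csv",
        "behavior_csv": "behavior.csv", "truth_json": "truth.json",
    }
    write_video(bundle.video, outdir / paths["video_tiff"], outdir / paths["video_sidecar"])

    # emit detector responses so the pipeline exercises quantification
    resp_rows = [
        {"window_start_min": s.window_start_min, "window_end_min": s.window_end_min,
         "response": cfg.assay_slope * s.concentration + cfg.assay_intercept}
        for s in bundle.dialysis
    ]
    pd.DataFrame(resp_rows,
                 columns=["window_start_min", "window_end_min", "response"]) \
        .to_csv(outdir / paths["dialysis_csv"], index=False)
    pd.DataFrame(bundle.standards, columns=["concentration_pg_ul", "response"]) \
        .to_csv(outdir / paths["standards_csv"], index=False)
    write_behavior(bundle.behavior, outdir / paths["behavior_csv"])

    truth = bundle.truth
    truth_doc = {
        "blob_centers": truth.blob_centers,
        "blob_sigmas": truth.blob_sigmas,
        "psf_sigma_px": cfg.psf_sigma_px,
        "event_times_s": [np.asarray(e).tolist() for e in truth.event_times],
        "kappa_serotonin": truth.kappa,
        "window_counts": np.asarray(truth.window_counts).tolist(),
        "serotonin_truth_pg_ul": np.asarray(truth.serotonin_truth).tolist(),
        "licking_truth_s": np.asarray(truth.licking_truth).tolist(),
        "frame_rate_hz": truth.frame_rate_hz,
    }
    with open(outdir / paths["truth_json"], "w") as fh:
        json.dump(truth_doc, fh, sort_keys=True)
        fh.write("\n")

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "paths": paths,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"outdir": str(outdir), "paths": paths, "bundle": bundle}


def truth_masks_from_json(path: str | Path, height: int, width: int,
                          psf_sigma_px: float | None = None) -> list:
    """Rebuild the planted blob FWHM masks from a truth.json document."""
    with open(path) as fh:
        doc = json.load(fh)
    psf = doc.get("psf_sigma_px", psf_sigma_px)
    masks = []
    rr, cc = np.mgrid[0:height, 0:width]
    for (r, c), sig in zip(doc["blob_centers"], doc["blob_sigmas"]):
        sig_eff = float(np.hypot(sig, psf))
        prof = np.exp(-0.5 * ((rr - r) ** 2 + (cc - c) ** 2) / sig_eff**2)
        masks.append(prof >= 0.5)
    return masks
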