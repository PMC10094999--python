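# Methods

This note records the models, conventions and numerical choices behind
`calmdx`, and what the synthetic benchmark does and does not establish.

## Data model and time conventions

All times are relative to the stimulation (injection) event: t = 0 at
injection, seconds for video, minutes for sample tables. Frame times are
`frame_index / frame_rate_hz − stim_time_s`, so the stimulation frame is the
first with non-negative time. Pixels are 0-based `(row, col)` with row 0 at
the sensor top; the device geometry is 120 rows × 40 columns (7.5 µm/px).
Native frame rates vary per session (9.73–10.68 Hz, nominally 10 fps) and are
carried in the JSON sidecar; the sensor bit depth is whatever the TIFF dtype
says (uint8/uint16) and is treated as data, not assumption.

Sessions are trimmed to `[−pre_keep, −artifact) ∪ [0, post_keep)` minutes.
The `[−artifact, 0)` segment is removed because the external light required
for the injection saturates the sensor; the gap is recorded in metadata and
every downstream resampling leaves gap bins as NaN with an explicit mask —
values are never interpolated across the gap.

## Normalization

`%ΔF/F0 = (F − F0)/F0 × 100` with F0 the per-pixel arithmetic mean over the
baseline window. Because the nominal 15-min pre-stimulation baseline overlaps
the removed artifact segment, the default window is the last artifact-free
15 minutes, `[−25, −10)`; the window is configurable. A pixel whose F0 is
zero is a hard error naming the pixel — silent NaN propagation would corrupt
ROI means. Two normalization routes exist deliberately: pixel-level (for
images and ROI detection) and ROI-level (ROI-mean raw fluorescence normalized
by the ROI's own baseline mean); downstream statistics use the ROI-level
form. Scaling all raw intensities by a positive gain leaves %ΔF/F0 unchanged.

## ROI detection

Six steps on the post-stimulation %ΔF/F0 frames: per-frame local Gaussian
binarization (kernel 9, σ 1.5) → per-frame cleaning (binary opening with a
2×2 square, then removal of 4-connected components under 15 px) → pixelwise
mean of the binary frames (an occupancy image in [0, 1]) → binarization of
the occupancy image (kernel 9, σ 2.5) → cleaning (3×3, 15 px) → 8-connected
labeling of the surviving forms.

Numerical conventions, fixed so that an independent brute-force composition
reproduces the masks exactly:

- The local threshold is the Gaussian-weighted mean of the exact
  kernel×kernel window (weights truncated there and normalized), compared
  with strict `>` and an additive offset of 0. Borders are reflect-padded
  (edge pixel duplicated).
- "Footprint n" is an n×n square. Because a 2×2 element has no center pixel
  and library origin conventions differ, the opening is computed anchor-free
  as the union of all square translates contained in the mask (pixels outside
  the image are background). This is the set-theoretic definition and is
  origin-independent by construction.
- Cleaning uses 4-connectivity (conservative during area opening); final
  labeling uses 8-connectivity (diagonal forms merge). Both are
  configurable.

The whole-frame pseudo-ROI `w` accompanies every ROI set for visualization
and rasters but is excluded from pooled statistics and correlations.

Detection runs on normalized frames (consistent with the processing order:
normalize, then select ROIs); a raw-intensity route would behave nearly
identically since the threshold is local and relative.

## Traces, filtering, peaks, bins

- Resampling to the 5 Hz visualization grid uses non-overlapping bin means
  anchored at t = 0, half-open `[start, end)` with edge samples assigned to
  the later bin. Empty bins (the artifact gap) stay NaN.
- Filters are zero-phase Butterworth applied forward–backward per contiguous
  non-gap segment: order 2 lowpass at 0.02 Hz (visualization only), order 4
  bandpass 0.17–4.5 Hz for peak detection. The family and order are a design
  choice (flat passband, no phase distortion of peak times); nothing
  downstream is sensitive to the exact roll-off.
- The bandpass must run at the native rate: at 5 Hz the 4.5 Hz edge exceeds
  Nyquist, and the code refuses with an explanatory error rather than
  silently producing an unstable filter.
- Peak threshold: mean + 2·SD of the filtered trace over the whole trimmed
  session (pre + post), per ROI. A global-threshold variant and a
  baseline-only window are available by flag; per-ROI whole-trace is the
  reproducible default. One supra-threshold excursion contributes exactly one
  peak (at the run maximum), so counts do not scale with frame rate.
- Imaging series are discretized to 5-min bins (licking comparisons) and
  15-min bins (dialysis comparisons); a bin edge always falls at t = 0.

## Microdialysis

Calibration is an OLS line `response = slope·concentration + intercept` on
the standards (0.50, 1.0, 10.0 pg/µL by default); the intercept is estimated
rather than forced through the origin because electrochemical detectors carry
baseline offsets (forced-origin and weighting are flags). Quantification
inverts the line; negative concentrations clip to zero with a below-LOD flag
— concentrations are physical. Samples sit on the 15-min grid
(`[−15, 0)` is the pre-stimulation baseline window) at 1 µL/min flow and
10 µL injections.

## Statistics

Two-sided throughout. Mann–Whitney U uses the exact distribution when
`n1·n2 ≤ 400` with tie-free data, else the normal approximation with tie and
continuity corrections. Student t-tests use pooled variance (Welch by flag);
zero-variance comparisons report p = 1 with a flag rather than dividing by
zero. Spearman's ρ is the Pearson correlation of mid-ranks (ties averaged);
the p-value is an exact two-sided permutation enumeration for n ≤ 10 and the
t-approximation above. Per-bin group comparisons are uncorrected by default
(Holm by flag, with a logged note); the ROI is the statistical unit, matching
how such experiments count n. Cross-modal correlations sum peak counts across
ROIs per session per bin and concatenate bin pairs across the sessions of a
group before ranking (a per-session mode is available).

## Synthetic sessions: what is emulated

- **Event model.** Per-population inhomogeneous Poisson with
  `λ(t) = r_base·(1 + a_acute·G(t; 10 min, 2.5 min) + a_infl·B(t; 20–40 min))`
  for formalin (G Gaussian, B a smooth two-logistic plateau with 60 s edges)
  and `λ = r_base` for PBS. Defaults: r_base = 0.05 Hz per population,
  a_acute = 6, a_infl = 3 — a strong acute phase around 10 min and a weaker,
  broader inflammatory phase, consistent with the biphasic formalin
  phenomenology. Events are drawn by thinning; every stream (placement,
  events, render, dialysis, licking) has its own child seed so sub-models are
  independently reproducible.
- **Fluorescence.** Each event adds a unit-peak transient
  `(1 − e^(−Δt/τ_r))·e^(−Δt/τ_d)` with τ_r = 0.1 s, τ_d = 1.0 s — generator
  defaults representative of fast GECI kinetics, not claims about a specific
  indicator. Populations are Gaussian blobs (σ 1.5–3.5 px) blurred by a
  Gaussian scattering PSF (σ 2 px); the ground-truth mask of a blob is its
  FWHM region.
- **Rendering.** `frame = 100 ADU baseline + 40 ADU·amplitude·profile +
  2 ADU sinusoidal drift (20-min period) + noise`, clipped to uint16. Shot
  and read noise (SD 2 ADU) are drawn as a single Gaussian with variance
  `photon count + read²`: at the ~100 ADU operating point the Poisson law is
  indistinguishable from its normal limit, and one float32 draw keeps long
  renders cheap on a single core. The `[−artifact, 0)` segment is overwritten
  at 0.99× dtype max to mimic the injection light.
- **Serotonin.** `c_k = 0.5 + κ·N_k/900 s + N(0, 0.1)` pg/µL per 15-min
  window, clipped at zero, with κ = 2 pg/µL per event/s for coupled sessions
  and κ = 0 for controls. A synthetic linear HPLC response (slope 120,
  intercept 5) turns concentrations into detector responses so the pipeline
  exercises calibration and quantification.
- **Licking.** Per-5-min bin, `base 10 s + 120 s·G(center; 7.5 min, 2.5 min)
  + 60 s·B(center; 30–50 min) + N(0, 5 s)`, clipped to [0, 300].

### What the generator does *not* emulate

- No motion, hemodynamic or photobleaching artifacts; no frame drops.
- Licking is coupled to neural activity only through the shared biphasic
  *shape*, and its inflammatory window (30–50 min) is deliberately offset
  from the activity plateau (20–40 min), as in the formalin-test literature.
  Within-animal co-fluctuation is not modeled, so the recovered
  peaks-vs-licking rank correlation is modest (≈ 0.2–0.3) — unlike the
  serotonin coupling, which is planted at the event level and recovers
  strongly (median ρ ≈ 0.9). Passing tests therefore demonstrate that the
  pipeline *measures* whatever coupling is present, not that licking in real
  animals is weakly coupled.
- Serotonin coupling is a deliberately minimal linear-count model; no
  receptor kinetics or probe dynamics.

### Spontaneous firing and the noiseless recovery condition

`SimConfig.spontaneous` (default True) keeps baseline-rate firing throughout
the session, which real baselines have. For geometric recovery tests the
noiseless condition turns it off along with sensor noise and drift, and this
is essential, not cosmetic: with zero noise, baseline transients inside the
F0 window raise F0 at blob pixels, so every inactive post-stimulation frame
carries a faint, smooth negative %ΔF/F0 dip there. The adaptive threshold is
scale-invariant — it responds to structure of *any* amplitude — so those
dips binarize into large halo rings and dominate the occupancy image,
regardless of generator amplitudes. With realistic noise the dips vanish
below the noise floor and recovery is excellent (Jaccard ≈ 0.75–0.87 per
blob); with a deterministic background it is exact by construction
(Jaccard ≈ 0.64–0.72 against FWHM truth). The lesson for real data: this
detector family assumes fluctuation-dominated backgrounds, which sensors
provide.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own benchmark scale: recovery sessions run 25 min pre
(including the 10-min artifact) + 30 min post at 10 Hz on the full 120×40
sensor; the two-group study uses 3 formalin + 3 PBS sessions per batch, five
batches, at 5 Hz with a 35-min post window (all effect sizes, geometry and
noise at defaults); cross-modal recovery uses ten 3-session groups at the
trace level (events → transients → bandpass → peaks) with 90-min spans.
Full-length 90-min video sessions are supported by raising the spans.

## Known limitations

- The ROI detector has no amplitude floor (offset defaults to 0); on
  noise-free inputs it will segment arbitrarily faint structure (see above).
- Peak counting saturates when transients overlap heavily (rates ≳ 1 Hz per
  population at τ_d = 1 s), compressing counts in the strongest acute bins.
- The exact Spearman permutation p enumerates up to 10! orderings; above
  n = 10 the t-approximation is used.
- `pool_roi_bins` treats ROIs as exchangeable across mice (the field's
  convention for such designs); a mouse-level mixed model is out of scope.
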