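# calmdx

Multi-modal analysis of nociceptive pain recordings that combine three data
streams from one animal: **lensless CMOS calcium-imaging video** of the dorsal
raphe nucleus (DRN), **microdialysis serotonin measurements** from projection
targets (CeA, ACC), and **licking-behavior scores**. The package is aimed at
labs using implantable imaging sensors together with HPLC-based neurochemistry
who need a reproducible path from raw frame stacks and sample tables to the
cross-modal statistics of a formalin-test experiment.

## What it computes

**Normalization.** Every pixel (or ROI mean) `F` is expressed relative to a
pre-stimulation baseline mean `F0`:

    %ΔF/F0 = (F − F0) / F0 × 100

The minutes immediately before the injection are saturated by the external
light needed to perform it, so sessions are trimmed to
`[−40, −10) ∪ [0, 60)` min (configurable) and the default baseline window is
the last artifact-free 15 min, `[−25, −10)`.

**ROI detection.** Active populations appear as blob-like "forms" (the sensor
has no optics; scattering blurs sources). Each post-stimulation %ΔF/F0 frame
is adaptively binarized against its Gaussian-weighted 9×9 neighborhood mean
(σ = 1.5), cleaned by binary opening (2×2) and area opening (≥ 15 px,
4-connected); the binary frames are averaged, re-binarized (9×9, σ = 2.5),
cleaned again (3×3, ≥ 15 px), and the 8-connected components of the result are
the ROIs, alongside a whole-frame pseudo-ROI `w`. The threshold is relative to
the local mean, so the masks are invariant to affine intensity rescaling.

**Peaks.** ROI traces are bandpass filtered (0.17–4.5 Hz, zero-phase
Butterworth, at the native ~10 Hz frame rate) and a peak is one maximal run of
samples above mean + 2 SD, timestamped at the run maximum.

**Serotonin.** An ordinary least-squares calibration line fitted on standard
injections (0.50, 1.0, 10.0 pg/µL) converts detector responses of 15-min
dialysate samples to concentrations; sub-baseline responses clip to 0 with a
below-LOD flag.

**Statistics.** Per-5-min-bin Mann–Whitney U between formalin and PBS ROIs
(the ROI is the statistical unit), paired/unpaired Student t-tests for
pre/post and laterality contrasts, and Spearman rank correlations between
per-bin peak counts and serotonin (15-min bins) or licking (5-min bins),
with exact permutation p-values for n ≤ 10.

**Synthetic sessions.** A fully seeded generator produces all three streams
with ground truth: biphasic nociceptive drive (acute bump at 10 min, SD
2.5 min; inflammatory plateau 20–40 min) on an inhomogeneous-Poisson event
model, GCaMP-like transients rendered as PSF-blurred blobs on a 120×40
sensor with shot/read noise and a saturated pre-injection artifact segment,
serotonin linearly coupled to windowed event counts, and biphasic licking.

## Worked example

```bash
calmdx run --simulate --groups formalin:1 --groups pbs:1 --seed 0 --out demo_out
calmdx report --results demo_out
```

prints:

```
calmdx 0.1.0 seed=0 sessions=2
bins with p<0.05: 4/9
  bin +5 min: U=267.0 p=8.67e-04 (n=13/25 ROIs)
  bin +10 min: U=236.0 p=2.33e-02 (n=13/25 ROIs)
  bin +20 min: U=262.0 p=1.62e-03 (n=13/25 ROIs)
  bin +25 min: U=247.0 p=8.44e-03 (n=13/25 ROIs)
  formalin peaks_vs_serotonin: rho=1.00 p=0.333 n=3
  formalin peaks_vs_licking: rho=0.71 p=0.136 n=6
  pbs peaks_vs_serotonin: rho=1.00 p=0.333 n=3
  pbs peaks_vs_licking: rho=-0.09 p=0.919 n=6
```

Reading: with one simulated session per group, the acute and early
inflammatory bins after injection separate formalin from PBS ROIs (two-sided
Mann–Whitney, 13 formalin vs 25 PBS ROIs; baseline bins do not appear because
they are not significant), and formalin peak counts track licking (ρ = 0.71)
while PBS counts do not. With a single 45-min session there are only 3
serotonin bins, so those ρ values carry no evidence (p = 1/3 is the smallest
attainable); the 3-vs-3 session study in `scripts/acceptance.py` is the
powered version. `demo_out/` contains per-session ROI tables, traces, peak
rasters, quantified serotonin, the pooled bin table, per-bin test results and
a provenance manifest.

The same stages are available as a library:

```python
from calmdx.preprocess import TrimSpec, trim_session, compute_baseline, normalize_dff
from calmdx.roi_detect import detect_rois
from calmdx.synthetic import SimConfig, simulate_session

bundle = simulate_session(SimConfig(seed=0))
video = trim_session(bundle.video, TrimSpec(25, 10, 30))
dff = normalize_dff(video, compute_baseline(video))
rois = detect_rois(dff)          # RoiSet with label image + ROI table
```

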