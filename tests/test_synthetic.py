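"""Generator contracts: determinism, event statistics, kernel shape,
rendering, coupling and clipping."""

import numpy as np
import pytest

from calmdx.synthetic import (
    SimConfig,
    dialysis_windows,
    events_to_fluorescence,
    generate_session,
    kernel_peak_time,
    rate_function,
    simulate_dialysis,
    simulate_events,
    simulate_licking,
    simulate_session,
    time_grid,
)


class TestEvents:
    def test_null_phase_rate_matches_poisson_mean(self):
        """Flat-rate sessions: pooled event count across seeds within 3
        standard errors of r_base * duration."""
        total = 0
        n_seeds = 100
        cfg0 = SimConfig(group="pbs", n_blobs=1, r_base_hz=0.05,
                         pre_min=0.0, artifact_min=0.0, post_min=60.0)
        for seed in range(n_seeds):
            cfg = SimConfig(**{**cfg0.__dict__, "seed": seed})
            total += sum(len(e) for e in simulate_events(cfg))
        expected = n_seeds * 0.05 * 3600
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_zero_rate_no_events(self):
        cfg = SimConfig(group="pbs", r_base_hz=0.0)
        assert all(len(e) == 0 for e in simulate_events(cfg))

    def test_determinism(self):
        cfg = SimConfig(seed=42)
        a = simulate_events(cfg)
        b = simulate_events(cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_biphasic_rate_shape(self):
        cfg = SimConfig(group="formalin")
        lam = rate_function(cfg)
        assert lam(600.0) == pytest.approx(cfg.r_base_hz * (1 + cfg.a_acute), rel=0.01)
        assert lam(1800.0) == pytest.approx(cfg.r_base_hz * (1 + cfg.a_infl), rel=0.05)
        assert lam(-1200.0) == pytest.approx(cfg.r_base_hz, rel=0.01)

    def test_spontaneous_off_silences_baseline(self):
        cfg = SimConfig(group="formalin", spontaneous=False)
        lam = rate_function(cfg)
        assert lam(-1200.0) == pytest.approx(0.0, abs=1e-9)
        assert lam(600.0) > 0
        pbs = SimConfig(group="pbs", spontaneous=False)
        assert all(len(e) == 0 for e in simulate_events(pbs))


class TestFluorescenceKernel:
    def test_no_events_zero_trace(self):
        cfg = SimConfig()
        grid = time_grid(cfg)
        assert not events_to_fluorescence(np.array([]), cfg, grid).any()

    def test_peak_at_analytic_maximum(self):
        cfg = SimConfig(pre_min=0.0, artifact_min=0.0, post_min=1.0,
                        frame_rate_hz=100.0)
        grid = time_grid(cfg)
        trace = events_to_fluorescence(np.array([10.0]), cfg, grid)
        t_peak = grid[np.argmax(trace)] - 10.0
        assert t_peak == pytest.approx(kernel_peak_time(cfg), abs=1.5 / 100)
        assert trace.max() == pytest.approx(1.0, rel=1e-3)  # unit peak

    def test_superposition_of_far_events(self):
        cfg = SimConfig(pre_min=0.0, artifact_min=0.0, post_min=2.0)
        grid = time_grid(cfg)
        single1 = events_to_fluorescence(np.array([10.0]), cfg, grid)
        single2 = events_to_fluorescence(np.array([70.0]), cfg, grid)
        both = events_to_fluorescence(np.array([10.0, 70.0]), cfg, grid)
        np.testing.assert_allclose(both, single1 + single2, atol=1e-12)


class TestRenderVideo:
    def _quiet_cfg(self, **kw):
        base = dict(seed=1, n_blobs=2, height=40, width=24, pre_min=2.0,
                    artifact_min=1.0, post_min=2.0, shot_noise=False,
                    read_noise_sd_adu=0.0, drift_amp_adu=0.0)
        base.update(kw)
        return SimConfig(**base)

    def test_zero_traces_constant_baseline(self):
        from calmdx.synthetic import render_video

        cfg = self._quiet_cfg()
        grid = time_grid(cfg)
        video, _ = render_video(np.zeros((2, grid.size)), cfg, grid)
        live = video.frames[(video.time_s < -60) | (video.time_s >= 0)]
        assert np.all(live == int(cfg.baseline_adu))

    def test_noiseless_pixels_match_analytic_rendering(self):
        from calmdx.synthetic import _streams, blob_profile, render_video

        cfg = self._quiet_cfg()
        grid = time_grid(cfg)
        rng = np.random.default_rng(7)
        traces = rng.uniform(0, 2, size=(2, grid.size))
        streams = _streams(cfg)
        video, truth = render_video(traces, cfg, grid,
                                    rng_render=streams["render"],
                                    rng_placement=streams["placement"])
        profiles = np.stack([blob_profile(c, s, cfg)
                             for c, s in zip(truth.blob_centers, truth.blob_sigmas)])
        expected = cfg.baseline_adu + np.einsum(
            "bt,bhw->thw", cfg.amp_adu * traces, profiles)
        live = (grid < -60) | (grid >= 0)
        np.testing.assert_allclose(
            video.frames[live].astype(float), np.rint(expected[live]), atol=1e-6)

    def test_artifact_segment_saturated(self):
        cfg = self._quiet_cfg()
        bundle = simulate_session(cfg, render=True)
        video = bundle.video
        seg = video.frames[(video.time_s >= -60) & (video.time_s < 0)]
        assert (seg > 0.95 * 65535).mean() >= 0.99

    def test_render_determinism(self):
        cfg = SimConfig(seed=5, n_blobs=2, height=40, width=24,
                        pre_min=2.0, artifact_min=1.0, post_min=2.0)
        a = simulate_session(cfg, render=True).video.frames
        b = simulate_session(cfg, render=True).video.frames
        np.testing.assert_array_equal(a, b)


class TestDialysis:
    def test_uncoupled_noiseless_all_baseline(self):
        cfg = SimConfig(kappa_serotonin=0.0, serotonin_noise_sd=0.0)
        events = simulate_events(cfg)
        samples, truth = simulate_dialysis(events, cfg)
        assert all(s.concentration == pytest.approx(cfg.s_base_pg_ul)
                   for s in samples)

    def test_events_in_first_window_elevate_it_only(self):
        cfg = SimConfig(kappa_serotonin=2.0, serotonin_noise_sd=0.0,
                        pre_min=15.0, post_min=30.0)
        events = [np.array([100.0, 200.0, 700.0])]  # all inside [0, 15) min
        samples, truth = simulate_dialysis(events, cfg)
        concs = [s.concentration for s in samples]
        assert concs[1] > cfg.s_base_pg_ul
        assert concs[0] == pytest.approx(cfg.s_base_pg_ul)
        assert concs[2] == pytest.approx(cfg.s_base_pg_ul)

    def test_event_count_conservation(self):
        cfg = SimConfig(seed=11, pre_min=15.0, post_min=30.0)
        events = simulate_events(cfg)
        _, truth = simulate_dialysis(events, cfg)
        edges = dialysis_windows(cfg)
        inside = sum(
            int(np.sum((e >= edges[0] * 60) & (e < edges[-1] * 60)))
            for e in events
        )
        assert truth["window_counts"].sum() == inside


class TestLicking:
    def test_flat_when_coefficients_zero(self):
        cfg = SimConfig(b_acute=0.0, b_infl=0.0, licking_noise_sd=0.0)
        bins, truth = simulate_licking(cfg)
        assert all(b.licking_duration_s == pytest.approx(cfg.licking_base_s)
                   for b in bins)

    def test_acute_bin_is_global_maximum(self):
        cfg = SimConfig(licking_noise_sd=0.0, post_min=60.0)
        bins, _ = simulate_licking(cfg)
        durations = [b.licking_duration_s for b in bins]
        # acute licking is centered at 7.5 min -> the [5, 10) bin dominates
        assert int(np.argmax(durations)) == 1

    def test_durations_clipped_to_bin_length(self):
        cfg = SimConfig(seed=2, b_acute=500.0, licking_noise_sd=100.0,
                        post_min=60.0)
        bins, _ = simulate_licking(cfg)
        assert all(0.0 <= b.licking_duration_s <= 300.0 for b in bins)


class TestGenerateSession:
    def _small_cfg(self, seed=0):
        return SimConfig(seed=seed, n_blobs=2, height=40, width=24,
                         pre_min=2.0, artifact_min=1.0, post_min=2.0)

    def test_bundle_byte_identical_across_runs(self, tmp_path):
        cfg = self._small_cfg()
        generate_session(cfg, tmp_path / "a")
        generate_session(cfg, tmp_path / "b")
        for name in ("video.tif", "video.json", "dialysis.csv",
                     "standards.csv", "behavior.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_control_group_in_sidecar(self, tmp_path):
        import json

        cfg = SimConfig(**{**self._small_cfg().__dict__, "group": "pbs"})
        generate_session(cfg, tmp_path / "s")
        side = json.loads((tmp_path / "s" / "video.json").read_text())
        assert side["group"] == "pbs"

    def test_collision_without_overwrite(self, tmp_path):
        cfg = self._small_cfg()
        generate_session(cfg, tmp_path / "s")
        with pytest.raises(FileExistsError):
            generate_session(cfg, tmp_path / "s")
        generate_session(cfg, tmp_path / "s", overwrite=True)

    def test_truth_masks_reconstructable(self, tmp_path):
        from calmdx.synthetic import truth_masks_from_json

        cfg = self._small_cfg(seed=4)
        res = generate_session(cfg, tmp_path / "s")
        masks = truth_masks_from_json(tmp_path / "s" / "truth.json",
                                      cfg.height, cfg.width)
        for got, want in zip(masks, res["bundle"].truth.blob_masks):
            np.testing.assert_array_equal(got, want)
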